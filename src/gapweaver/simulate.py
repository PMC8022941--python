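"""Truth-known synthetic datasets exercising every pipeline stage.

A truth genome (telomere arrays, unique sequence, a monomer-array
centromere per chromosome) is degraded into a reference-like assembly with
N-run gaps, truncated telomeres and extracted unplaced contigs.  Donor
contigs, their alignments, linked-read alignments, telomeric reads and
centromere contigs are then derived analytically from the known layout, so
every downstream result can be scored against truth exactly.

Anomalies can be planted: a translocated fill (caught by the collinearity
check), a non-linear homology donor (caught by the shrinkage guard) and an
uncovered fill (caught by linked-read gap support).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np

from ._seq import random_seq, revcomp, roman
from .alignments import AlignmentBlock, write_paf
from .genome_model import Assembly, Edit, PatchLedger, SequenceRecord
from .repeats import TELOMERE_FWD, TELOMERE_REV
from .scaffold_support import OpticalAlignment

log = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    seed: int
    n_chroms: int = 3
    chrom_len: int = 500_000
    n_gaps_per_chrom: int = 6
    gap_len_range: tuple[int, int] = (300, 2000)
    gap_len_distortion: float = 0.0   # relative distortion of N-run lengths
    telomere_len: int = 3_000         # bp per telomere array (multiple of 6)
    monomer_len: int = 186
    hor_period: int = 3
    hor_blocks: int = 30              # higher-order blocks per centromere
    monomer_divergence: float = 0.15  # divergence between block variants
    mask_centromeres: bool = False    # leave an uncloseable centromere gap
    n_chrun_placed: int = 2
    n_chrun_contained: int = 2
    n_chrun_novel: int = 2
    donor_flank: int = 6_000
    read_len: int = 150
    read_depth: int = 25
    molecule_len: int = 40_000
    window: int = 2_000               # linked-read window around each fill
    tel_anchor: int = 12_000
    tel_read_copies: int = 120
    translocated_fills: int = 0
    nonlinear_contigs: int = 0
    uncovered_fills: int = 0
    spacer_len: int = 100

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_chroms", "chrom_len", "n_gaps_per_chrom", "telomere_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TruthGap:
    """One masked interval: its reference N-run and the true fill."""

    chrom: str
    t_start: int      # truth coordinates
    t_end: int
    ref_start: int    # reference (degraded assembly) coordinates
    ref_end: int
    fill: str         # sequence a correct donor supplies (may be anomalous)
    truth_fill: str   # sequence actually removed from the truth genome
    origin: str       # gap | chrun | centromere
    chrun_name: Optional[str] = None
    anomaly: Optional[str] = None  # translocated | nonlinear | uncovered

    @property
    def gap_id(self) -> str:
        return f"{self.chrom}:{self.ref_start}-{self.ref_end}"


@dataclass
class ChromLayout:
    length: int
    tel_len: int
    cen_start: int
    cen_end: int


@dataclass
class TruthGenome:
    assembly: Assembly
    layouts: dict[str, ChromLayout]
    tracks: dict[str, list[tuple[str, int, int]]]
    consensus: str
    variants: list[str]


@dataclass
class SimBundle:
    cfg: SimulationConfig
    truth: TruthGenome
    reference: Assembly
    truth_gaps: list[TruthGap]
    donors: dict[str, str]
    donor_paf: list[AlignmentBlock]
    truth_ledger: PatchLedger
    v5_truth: Assembly
    fill_new_intervals: dict[str, tuple[str, int, int]]
    linked_reads: list[tuple[str, str, str, int, int]]
    read_windows: list[tuple[str, int, int]]
    telomere_reads: dict[str, str]
    telomere_paf: list[AlignmentBlock]
    chrun_contigs: dict[str, str]
    chrun_prior: dict[str, Optional[str]]
    chrun_paf: list[AlignmentBlock]
    fills_paf: list[AlignmentBlock]
    cen_gaps: dict[str, tuple[int, int]]
    cen_contigs: dict[str, str]
    cen_paf: list[AlignmentBlock]
    anomalies: dict[str, str]  # gap_id -> anomaly kind

    def write(self, outdir: Union[str, Path]) -> None:
        """Emit all fixtures as plain-text files."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.truth.assembly.write_fasta(out / "truth.fa")
        self.reference.write_fasta(out / "reference.fa")
        _write_fasta(self.donors, out / "donors.fa")
        _write_fasta(self.telomere_reads, out / "telomere_reads.fa")
        _write_fasta(self.chrun_contigs, out / "chrun_contigs.fa")
        write_paf(self.donor_paf, out / "donors.paf")
        write_paf(self.telomere_paf, out / "telomere_reads.paf")
        write_paf(self.chrun_paf, out / "chrun.paf")
        write_paf(self.fills_paf, out / "fills_vs_independent.paf")
        with open(out / "linked_reads.tsv", "w") as fh:
            for row in self.linked_reads:
                fh.write("\t".join(map(str, row)) + "\n")
        with open(out / "truth_tracks.bed", "w") as fh:
            for track, rows in self.truth.tracks.items():
                for chrom, s, e in rows:
                    fh.write(f"{chrom}\t{s}\t{e}\t{track}\n")
        with open(out / "truth_gaps.tsv", "w") as fh:
            fh.write("gap_id\tchrom\tref_start\tref_end\torigin\tanomaly\n")
            for tg in self.truth_gaps:
                fh.write(
                    f"{tg.gap_id}\t{tg.chrom}\t{tg.ref_start}\t{tg.ref_end}\t"
                    f"{tg.origin}\t{tg.anomaly or '.'}\n"
                )
        with open(out / "config.json", "w") as fh:
            json.dump(asdict(self.cfg), fh, indent=2, default=list)


def _write_fasta(seqs: dict[str, str], path: Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _mutate(rng: np.random.Generator, seq: str, fraction: float) -> str:
    n = len(seq)
    k = int(round(fraction * n))
    pos = rng.choice(n, size=k, replace=False)
    out = list(seq)
    for p in pos:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(3)]
    return "".join(out)


def make_hor_monomers(
    rng: np.random.Generator, consensus: str, period: int, divergence: float
) -> list[str]:
    """Variant monomers A, B, C, ... mutually ~``divergence`` diverged."""
    return [consensus] + [
        _mutate(rng, consensus, divergence) for _ in range(period - 1)
    ]


def make_hor_array(variants: list[str], blocks: int) -> str:
    return "".join(variants) * blocks


def simulate_truth_genome(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> TruthGenome:
    """Deterministic truth genome: telomeres, unique arms, one centromere."""
    rng = rng or np.random.default_rng(cfg.seed)
    consensus = random_seq(rng, cfg.monomer_len)
    variants = make_hor_monomers(rng, consensus, cfg.hor_period, cfg.monomer_divergence)
    cen = make_hor_array(variants, cfg.hor_blocks)
    tel_copies = cfg.telomere_len // 6
    records = []
    layouts: dict[str, ChromLayout] = {}
    tracks: dict[str, list[tuple[str, int, int]]] = {"telomere": [], "centromere": []}
    for i in range(cfg.n_chroms):
        name = f"chr{roman(i + 1)}"
        ltel = TELOMERE_REV * tel_copies
        rtel = TELOMERE_FWD * tel_copies
        body = cfg.chrom_len - 2 * len(ltel) - len(cen)
        if body < 40_000:
            raise ValueError("chrom_len too small for the configured layout")
        u1 = random_seq(rng, body // 2)
        u2 = random_seq(rng, body - len(u1))
        seq = ltel + u1 + cen + u2 + rtel
        cen_start = len(ltel) + len(u1)
        records.append(SequenceRecord(name, seq, "chromosome"))
        layouts[name] = ChromLayout(len(seq), len(ltel), cen_start, cen_start + len(cen))
        tracks["telomere"] += [(name, 0, len(ltel)), (name, len(seq) - len(rtel), len(seq))]
        tracks["centromere"].append((name, cen_start, cen_start + len(cen)))
    return TruthGenome(Assembly(records), layouts, tracks, consensus, variants)


def _plan_gap_positions(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    layout: ChromLayout,
) -> list[int]:
    """Gap start positions (truth coords) within the two unique arms."""
    margin = cfg.donor_flank + 2_500
    gmax = cfg.gap_len_range[1]
    arms = [
        (layout.tel_len, layout.cen_start),
        (layout.cen_end, layout.length - layout.tel_len),
    ]
    k = cfg.n_gaps_per_chrom
    k1 = k // 2
    counts = [k - k1, k1]
    starts = []
    for (lo, hi), n in zip(arms, counts):
        lo, hi = lo + margin, hi - margin - gmax
        if n == 0:
            continue
        if hi <= lo:
            raise ValueError("arm too small for requested gaps")
        step = (hi - lo) // (n + 1)
        if step < cfg.donor_flank + gmax + 1_000:
            raise ValueError("gaps too dense for the donor flank length")
        for j in range(1, n + 1):
            jitter = int(rng.integers(0, max(1, step // 4)))
            starts.append(lo + j * step + jitter)
    return sorted(starts)


@dataclass
class Degraded:
    reference: Assembly
    truth_gaps: list[TruthGap]
    segments: dict[str, list[tuple[int, int, int]]]  # (t_start, t_end, r_start)
    chrun_prior: dict[str, Optional[str]]
    chrun_contigs: dict[str, str]


def degrade_to_reference(
    truth: TruthGenome,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> Degraded:
    """Mask planned intervals to N-runs, truncate telomeres and extract
    unplaced contigs; every masking is recorded for later scoring."""
    rng = rng or np.random.default_rng(cfg.seed + 1)
    d = cfg.gap_len_distortion
    truth_gaps: list[TruthGap] = []
    segments: dict[str, list[tuple[int, int, int]]] = {}
    chrun_prior: dict[str, Optional[str]] = {}
    chrun_contigs: dict[str, str] = {}
    records = []
    chrun_idx = 0
    n_chrun_left = cfg.n_chrun_placed
    for rec in truth.assembly.chromosomes():
        layout = truth.layouts[rec.name]
        masks: list[tuple[int, int, str]] = []  # (t_start, t_end, origin)
        for pos in _plan_gap_positions(rng, cfg, layout):
            g = int(rng.integers(cfg.gap_len_range[0], cfg.gap_len_range[1] + 1))
            origin = "gap"
            if n_chrun_left > 0:
                origin = "chrun"
                n_chrun_left -= 1
            masks.append((pos, pos + g, origin))
        if cfg.mask_centromeres:
            masks.append((layout.cen_start, layout.cen_end, "centromere"))
        masks.sort()
        tel = layout.tel_len
        pieces = []
        segs = []
        cursor = tel
        ref_pos = 0
        for t_s, t_e, origin in masks:
            pieces.append(rec.sequence[cursor:t_s])
            segs.append((cursor, t_s, ref_pos))
            ref_pos += t_s - cursor
            true_fill = rec.sequence[t_s:t_e]
            n_len = max(1, int(round((t_e - t_s) * (1 + rng.uniform(-d, d)))))
            pieces.append("N" * n_len)
            tg = TruthGap(
                rec.name, t_s, t_e, ref_pos, ref_pos + n_len,
                fill=true_fill, truth_fill=true_fill, origin=origin,
            )
            if origin == "chrun":
                name = f"chrUn_{chrun_idx:03d}"
                chrun_idx += 1
                tg.chrun_name = name
                chrun_contigs[name] = true_fill
                chrun_prior[name] = rec.name
            truth_gaps.append(tg)
            ref_pos += n_len
            cursor = t_e
        end = layout.length - tel
        pieces.append(rec.sequence[cursor:end])
        segs.append((cursor, end, ref_pos))
        records.append(SequenceRecord(rec.name, "".join(pieces), "chromosome"))
        segments[rec.name] = segs
    # contained and novel chrUn contigs
    last = truth.assembly.chromosomes()[-1]
    layout = truth.layouts[last.name]
    src = layout.cen_end + cfg.donor_flank // 2
    for j in range(cfg.n_chrun_contained):
        name = f"chrUn_{chrun_idx:03d}"
        chrun_idx += 1
        seq = last.sequence[src + j * 4_000 : src + j * 4_000 + 3_000]
        chrun_contigs[name] = seq
        chrun_prior[name] = last.name
    for j in range(cfg.n_chrun_novel):
        name = f"chrUn_{chrun_idx:03d}"
        chrun_idx += 1
        chrun_contigs[name] = random_seq(rng, 2_000)
        chrun_prior[name] = None
    for name, seq in chrun_contigs.items():
        records.append(SequenceRecord(name, seq, "unplaced"))
    return Degraded(Assembly(records), truth_gaps, segments, chrun_prior, chrun_contigs)


def _t2r(segments: list[tuple[int, int, int]], pos: int) -> int:
    for t_s, t_e, r_s in segments:
        if t_s <= pos <= t_e:
            return r_s + (pos - t_s)
    raise ValueError(f"truth position {pos} is not in an identity segment")


def simulate(cfg: SimulationConfig) -> SimBundle:
    """Run the full simulation pipeline for one config."""
    rng = np.random.default_rng(cfg.seed)
    truth = simulate_truth_genome(cfg, rng)
    deg = degrade_to_reference(truth, cfg, rng)
    reference = deg.reference
    F = cfg.donor_flank

    closable = [tg for tg in deg.truth_gaps if tg.origin in ("gap", "chrun")]
    # plant anomalies on distinct gaps, farthest-from-start first for variety
    anomalies: dict[str, str] = {}
    anomaly_kinds = (
        ["translocated"] * cfg.translocated_fills
        + ["nonlinear"] * cfg.nonlinear_contigs
        + ["uncovered"] * cfg.uncovered_fills
    )
    if len(anomaly_kinds) > len(closable):
        raise ValueError("more anomalies than closable gaps")
    for tg, kind in zip(closable[-len(anomaly_kinds):] if anomaly_kinds else [], anomaly_kinds):
        tg.anomaly = kind
        anomalies[tg.gap_id] = kind

    chrom_names = [r.name for r in truth.assembly.chromosomes()]
    donors: dict[str, str] = {}
    donor_paf: list[AlignmentBlock] = []
    ledger = PatchLedger()
    for idx, tg in enumerate(closable):
        donor_name = f"donor_{idx:03d}"
        chrom_ref_len = len(reference[tg.chrom])
        truth_seq = truth.assembly[tg.chrom].sequence
        if tg.anomaly == "translocated":
            other = chrom_names[(chrom_names.index(tg.chrom) + 1) % len(chrom_names)]
            o_layout = truth.layouts[other]
            o_src = o_layout.cen_end + 3 * F
            wrong = truth.assembly[other].sequence[o_src : o_src + len(tg.truth_fill)]
            tg.fill = wrong
            fwd = truth_seq[tg.t_start - F : tg.t_start] + wrong + truth_seq[tg.t_end : tg.t_end + F]
        elif tg.anomaly == "nonlinear":
            delta = 500
            fwd = (
                truth_seq[tg.t_start - F : tg.t_start]
                + truth_seq[tg.t_end + delta : tg.t_end + delta + F]
            )
        else:
            fwd = truth_seq[tg.t_start - F : tg.t_end + F]
        strand = "+" if idx % 2 == 0 else "-"
        if tg.anomaly == "nonlinear":
            strand = "+"
        donor_seq = fwd if strand == "+" else revcomp(fwd)
        donors[donor_name] = donor_seq
        q_len = len(donor_seq)
        r_gs, r_ge = tg.ref_start, tg.ref_end
        if tg.anomaly == "nonlinear":
            delta = 500
            donor_paf.append(AlignmentBlock(donor_name, q_len, 0, F, "+", tg.chrom,
                                            chrom_ref_len, r_gs - F, r_gs, F, F))
            donor_paf.append(AlignmentBlock(donor_name, q_len, F, 2 * F, "+", tg.chrom,
                                            chrom_ref_len, r_ge + delta, r_ge + delta + F, F, F))
            continue  # no ledger edit: a correct pipeline rejects this donor
        if strand == "+":
            donor_paf.append(AlignmentBlock(donor_name, q_len, 0, F, "+", tg.chrom,
                                            chrom_ref_len, r_gs - F, r_gs, F, F))
            donor_paf.append(AlignmentBlock(donor_name, q_len, q_len - F, q_len, "+",
                                            tg.chrom, chrom_ref_len, r_ge, r_ge + F, F, F))
        else:
            donor_paf.append(AlignmentBlock(donor_name, q_len, q_len - F, q_len, "-",
                                            tg.chrom, chrom_ref_len, r_gs - F, r_gs, F, F))
            donor_paf.append(AlignmentBlock(donor_name, q_len, 0, F, "-", tg.chrom,
                                            chrom_ref_len, r_ge, r_ge + F, F, F))
        ledger.add(Edit(tg.chrom, r_gs, r_ge, tg.fill, donor_name, "gap_fill"))

    v5_truth = ledger.apply(reference)
    fill_new_intervals: dict[str, tuple[str, int, int]] = {}
    edit_to_gap = {id(e): tg for tg in closable for e in ledger.chrom_edits(tg.chrom)
                   if e.start == tg.ref_start and e.end == tg.ref_end}
    for chrom, ns, ne, e in ledger.new_intervals():
        tg = edit_to_gap.get(id(e))
        if tg is not None:
            fill_new_intervals[tg.gap_id] = (chrom, ns, ne)

    linked_reads, read_windows = _simulate_linked_reads(
        cfg, rng, v5_truth, closable, fill_new_intervals
    )
    telomere_reads, telomere_paf = _simulate_telomere_reads(cfg, rng, v5_truth)
    chrun_paf = _simulate_chrun_paf(cfg, deg, ledger, closable, v5_truth)
    fills_paf = _simulate_fills_paf(truth, closable)
    cen_gaps, cen_contigs, cen_paf = _simulate_centromere_contigs(
        cfg, truth, deg, reference
    )
    return SimBundle(
        cfg=cfg, truth=truth, reference=reference, truth_gaps=deg.truth_gaps,
        donors=donors, donor_paf=donor_paf, truth_ledger=ledger,
        v5_truth=v5_truth, fill_new_intervals=fill_new_intervals,
        linked_reads=linked_reads, read_windows=read_windows,
        telomere_reads=telomere_reads, telomere_paf=telomere_paf,
        chrun_contigs=deg.chrun_contigs, chrun_prior=deg.chrun_prior,
        chrun_paf=chrun_paf, fills_paf=fills_paf,
        cen_gaps=cen_gaps, cen_contigs=cen_contigs, cen_paf=cen_paf,
        anomalies=anomalies,
    )


def _simulate_linked_reads(cfg, rng, v5_truth, closable, fill_new_intervals):
    """Barcoded read alignments around each fill, windowed for desk scale."""
    rows: list[tuple[str, str, str, int, int]] = []
    windows: list[tuple[str, int, int]] = []
    rl = cfg.read_len
    for i, tg in enumerate(closable):
        interval = fill_new_intervals.get(tg.gap_id)
        if interval is None:
            continue
        chrom, ns, ne = interval
        L = len(v5_truth[chrom])
        lo = max(0, ns - cfg.window)
        hi = min(L, ne + cfg.window)
        windows.append((chrom, lo, hi))
        span = hi - lo
        # one deterministic tiling molecule guarantees full coverage
        tile_starts = list(range(lo - rl, hi + 1, rl * 2 // 3))
        reads = [(s, s + rl) for s in tile_starts if s >= 0 and s + rl <= L]
        bc0 = f"BX{i:05d}a"
        rid = 0
        for s, e in reads:
            rows.append((f"rd{i}_{rid}", bc0, chrom, s, e))
            rid += 1
        # random molecules bring mean depth up to the configured target
        n_random = max(0, int(cfg.read_depth * span / rl) - len(reads))
        for m in range(2):
            bc = f"BX{i:05d}{'bc'[m]}"
            n = n_random // 2
            starts = rng.integers(max(0, lo - rl), min(hi, L - rl), size=n)
            for s in sorted(map(int, starts)):
                rows.append((f"rd{i}_{rid}", bc, chrom, s, s + rl))
                rid += 1
        if tg.anomaly == "uncovered":
            rows = [
                r for r in rows
                if not (r[2] == chrom and r[3] < ne and r[4] > ns)
            ]
            # flanking reads from one molecule keep the unsupported pattern:
            # alignments outside the gap only
            bc = f"BX{i:05d}a"
            rows.append((f"rd{i}_flankL", bc, chrom, max(0, ns - rl), ns))
            rows.append((f"rd{i}_flankR", bc, chrom, ne, min(L, ne + rl)))
    return rows, windows


def _simulate_telomere_reads(cfg, rng, v5_truth):
    reads: dict[str, str] = {}
    paf: list[AlignmentBlock] = []
    anchor = cfg.tel_anchor
    tail = TELOMERE_FWD * cfg.tel_read_copies
    for rec in v5_truth.chromosomes():
        L = len(rec)
        right = rec.sequence[L - anchor :] + tail
        name = f"telread_{rec.name}_R"
        reads[name] = right
        paf.append(AlignmentBlock(name, len(right), 0, anchor, "+", rec.name,
                                  L, L - anchor, L, anchor, anchor))
        left = TELOMERE_REV * cfg.tel_read_copies + rec.sequence[:anchor]
        lname = f"telread_{rec.name}_L"
        reads[lname] = left
        paf.append(AlignmentBlock(lname, len(left), len(left) - anchor, len(left),
                                  "+", rec.name, L, 0, anchor, anchor, anchor))
    # decoy: telomere-rich but without a unique anchor anywhere
    reads["telread_decoy"] = TELOMERE_FWD * 60 + random_seq(rng, 1_000)
    return reads, paf


def _simulate_chrun_paf(cfg, deg, ledger, closable, v5_truth):
    paf: list[AlignmentBlock] = []
    fill_by_name = {tg.chrun_name: tg for tg in closable if tg.chrun_name}
    for name, seq in deg.chrun_contigs.items():
        q_len = len(seq)
        tg = fill_by_name.get(name)
        if tg is not None and tg.anomaly != "nonlinear":
            # extracted contigs land exactly on their fill interval
            shift = sum(
                e.net for e in ledger.chrom_edits(tg.chrom) if e.end <= tg.ref_start
            )
            ns = tg.ref_start + shift
            paf.append(AlignmentBlock(name, q_len, 0, q_len, "+", tg.chrom,
                                      len(v5_truth[tg.chrom]), ns, ns + q_len,
                                      q_len, q_len))
            continue
        prior = deg.chrun_prior.get(name)
        if prior is None:
            continue  # novel contigs align nowhere
        # contained contigs: locate source on the degraded reference, then lift
        chrom_seq = deg.reference[prior].sequence
        r_pos = chrom_seq.find(seq)
        if r_pos < 0:
            continue
        lifted = ledger.lift(prior, r_pos)
        ns = lifted.pos if lifted.pos is not None else lifted.new_interval[0]
        paf.append(AlignmentBlock(name, q_len, 0, q_len, "+", prior,
                                  len(v5_truth[prior]), ns, ns + q_len,
                                  q_len, q_len))
    return paf


def _simulate_fills_paf(truth, closable):
    """Alignments of each applied fill to the independent (truth) assembly."""
    paf: list[AlignmentBlock] = []
    chrom_names = [r.name for r in truth.assembly.chromosomes()]
    for tg in closable:
        if tg.anomaly == "nonlinear" or not tg.fill:
            continue
        n = len(tg.fill)
        if tg.anomaly == "translocated":
            target = chrom_names[(chrom_names.index(tg.chrom) + 1) % len(chrom_names)]
            o_layout = truth.layouts[target]
            t_s = o_layout.cen_end + 3 * 6_000
        else:
            target = tg.chrom
            t_s = tg.t_start
        paf.append(AlignmentBlock(tg.gap_id, n, 0, n, "+", target,
                                  len(truth.assembly[target]), t_s, t_s + n, n, n))
    return paf


def _simulate_centromere_contigs(cfg, truth, deg, reference):
    """Contigs anchoring to centromere-gap flanks (only when masked)."""
    if not cfg.mask_centromeres:
        return {}, {}, []
    cen_gaps: dict[str, tuple[int, int]] = {}
    for tg in deg.truth_gaps:
        if tg.origin == "centromere":
            cen_gaps[tg.chrom] = (tg.ref_start, tg.ref_end)
    contigs: dict[str, str] = {}
    paf: list[AlignmentBlock] = []
    anchor = 15_000
    chroms = [r.name for r in truth.assembly.chromosomes()]
    for i, chrom in enumerate(chroms):
        layout = truth.layouts[chrom]
        seq = truth.assembly[chrom].sequence
        r_cs, r_ce = cen_gaps[chrom]
        ref_len = len(reference[chrom])
        if i % 3 == 0:  # spanning contig
            c = seq[layout.cen_start - anchor : layout.cen_end + anchor]
            name = f"cen_{chrom}_span"
            contigs[name] = c
            paf.append(AlignmentBlock(name, len(c), 0, anchor, "+", chrom, ref_len,
                                      r_cs - anchor, r_cs, anchor, anchor))
            paf.append(AlignmentBlock(name, len(c), len(c) - anchor, len(c), "+",
                                      chrom, ref_len, r_ce, r_ce + anchor,
                                      anchor, anchor))
        elif i % 3 == 1:  # one-sided contig
            c = seq[layout.cen_start - anchor : layout.cen_start + 5_000]
            name = f"cen_{chrom}_left"
            contigs[name] = c
            paf.append(AlignmentBlock(name, len(c), 0, anchor, "+", chrom, ref_len,
                                      r_cs - anchor, r_cs, anchor, anchor))
        else:  # anchor too short to be retained
            short = 8_000
            c = seq[layout.cen_start - short : layout.cen_start + 5_000]
            name = f"cen_{chrom}_short"
            contigs[name] = c
            paf.append(AlignmentBlock(name, len(c), 0, short, "+", chrom, ref_len,
                                      r_cs - short, r_cs, short, short))
    return cen_gaps, contigs, paf


# ---------------------------------------------------------------------------
# standalone scaffold/optical-map fixtures
# ---------------------------------------------------------------------------

def simulate_scaffold(
    rng: np.random.Generator,
    n_contigs: int = 5,
    contig_len_range: tuple[int, int] = (20_000, 40_000),
    name: str = "scaffold_1",
) -> tuple[SequenceRecord, list[tuple[str, int, int]]]:
    """A scaffold tiled by contigs with recorded boundaries."""
    pieces = []
    boundaries = []
    pos = 0
    for i in range(n_contigs):
        L = int(rng.integers(*contig_len_range))
        pieces.append(random_seq(rng, L))
        boundaries.append((f"{name}_ctg{i}", pos, pos + L))
        pos += L
    return SequenceRecord(name, "".join(pieces), "chromosome"), boundaries


def simulate_optical_alignments(
    rng: np.random.Generator,
    boundaries: list[tuple[str, int, int]],
    chrom: str,
    misjoined: set[str] = frozenset(),
    good_cov: float = 0.95,
    bad_cov: float = 0.30,
) -> list[OpticalAlignment]:
    """Optical contigs covering each assembly contig at the given fraction;
    mis-joined contigs get sub-threshold coverage."""
    out = []
    for i, (name, s, e) in enumerate(boundaries):
        cov = bad_cov if name in misjoined else good_cov
        span = int((e - s) * cov)
        if span < 1:
            continue
        offset = int(rng.integers(0, (e - s) - span + 1))
        out.append(OpticalAlignment(f"opt_{i}", chrom, s + offset, s + offset + span))
    return out
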