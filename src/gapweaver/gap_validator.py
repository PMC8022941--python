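"""Validate closed gaps with an independent assembly and linked-read molecules.

Two independent lines of evidence are computed per closed gap: whether the
fill sequence aligns collinearly (same chromosome) in an independently
assembled genome, and whether barcoded linked-read molecules cover the fill
and anchor on both flanks.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .alignments import AlignmentBlock, filter_collinear
from .genome_model import Assembly

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# collinearity against an independent assembly
# ---------------------------------------------------------------------------

@dataclass
class CollinearityReport:
    labels: dict[str, str]            # fill id -> concordant_chrom | discordant_chrom | unaligned
    n_aligned: int = 0
    n_discordant: int = 0
    fraction_aligned: float = 0.0
    fraction_discordant: float = 0.0  # among aligned


def collinearity_check(
    expected_chrom: Mapping[str, str],
    blocks: Sequence[AlignmentBlock],
    min_identity: float = 0.98,
    min_len: int = 4000,
    homolog_map: Optional[Mapping[str, str]] = None,
) -> CollinearityReport:
    """Label each fill by its best target chromosome in the other assembly.

    ``expected_chrom`` maps fill id -> chromosome the fill was placed on.
    ``homolog_map`` translates that name into the independent assembly's
    naming (identity by default).  Alignments are filtered with the same
    strict collinearity thresholds used genome-wide.
    """
    filtered = filter_collinear(blocks, min_identity, min_len)
    best: dict[str, AlignmentBlock] = {}
    for b in filtered:
        cur = best.get(b.query)
        if cur is None or b.matches > cur.matches:
            best[b.query] = b
    labels = {}
    n_aligned = n_discordant = 0
    for fill_id, chrom in expected_chrom.items():
        b = best.get(fill_id)
        if b is None:
            labels[fill_id] = "unaligned"
            continue
        n_aligned += 1
        homolog = (homolog_map or {}).get(chrom, chrom)
        if b.target == homolog:
            labels[fill_id] = "concordant_chrom"
        else:
            labels[fill_id] = "discordant_chrom"
            n_discordant += 1
    n = len(expected_chrom)
    return CollinearityReport(
        labels=labels,
        n_aligned=n_aligned,
        n_discordant=n_discordant,
        fraction_aligned=n_aligned / n if n else 0.0,
        fraction_discordant=n_discordant / n_aligned if n_aligned else 0.0,
    )


# ---------------------------------------------------------------------------
# linked-read molecules
# ---------------------------------------------------------------------------

ReadRow = tuple[str, str, str, int, int]  # read, barcode, chrom, start, end


@dataclass
class Molecule:
    """A long DNA fragment reconstructed from same-barcode read alignments."""

    barcode: str
    chrom: str
    reads: list[tuple[int, int]]

    @property
    def span(self) -> tuple[int, int]:
        return self.reads[0][0], max(e for _, e in self.reads)


def group_molecules(
    rows: Iterable[ReadRow],
    max_gap_within_molecule: int = 50_000,
) -> tuple[list[Molecule], int]:
    """Cluster barcoded read alignments into molecules.

    Reads sharing a barcode on one chromosome belong to one molecule until
    adjacent reads are more than ``max_gap_within_molecule`` apart, which
    starts a new molecule.  Rows with an empty barcode are skipped and
    counted.
    """
    n_skipped = 0
    grouped: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for read, barcode, chrom, start, end in rows:
        if not barcode or barcode == ".":
            n_skipped += 1
            continue
        grouped.setdefault((barcode, chrom), []).append((start, end))
    molecules = []
    for (barcode, chrom), reads in sorted(grouped.items()):
        reads.sort()
        current = [reads[0]]
        max_end = reads[0][1]
        for r in reads[1:]:
            if r[0] - max_end > max_gap_within_molecule:
                molecules.append(Molecule(barcode, chrom, current))
                current = [r]
                max_end = r[1]
            else:
                current.append(r)
                max_end = max(max_end, r[1])
        molecules.append(Molecule(barcode, chrom, current))
    return molecules, n_skipped


def read_barcoded_tsv(path: Union[str, Path]) -> list[ReadRow]:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            rows.append((f[0], f[1], f[2], int(f[3]), int(f[4])))
    return rows


def read_barcoded_bam(path: Union[str, Path], barcode_tag: str = "BX") -> list[ReadRow]:
    """Extract (read, barcode, chrom, start, end) from a coordinate BAM/SAM."""
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            barcode = aln.get_tag(barcode_tag) if aln.has_tag(barcode_tag) else ""
            rows.append(
                (
                    aln.query_name,
                    str(barcode),
                    aln.reference_name,
                    aln.reference_start,
                    aln.reference_end,
                )
            )
    return rows


@dataclass
class GapSupportCall:
    gap_id: str
    min_depth_in_fill: int
    spanning_molecules: int
    verdict: str  # supported | unsupported


def classify_gap_support(
    fill_interval: tuple[str, int, int],
    rows: Sequence[ReadRow],
    molecules: Sequence[Molecule],
    depth_threshold: int = 1,
    flank: int = 100,
    gap_id: Optional[str] = None,
) -> GapSupportCall:
    """Supported iff every base of the fill plus both flanks reaches the
    depth threshold AND at least one molecule has reads on both flanks."""
    chrom, fs, fe = fill_interval
    if fe - fs < 1:
        raise ValueError("fill interval shorter than 1 bp")
    lo, hi = fs - flank, fe + flank
    depth = np.zeros(hi - lo, dtype=np.int32)
    for _, _, c, s, e in rows:
        if c != chrom or e <= lo or s >= hi:
            continue
        depth[max(s, lo) - lo : min(e, hi) - lo] += 1
    min_depth = int(depth.min()) if depth.size else 0
    spanning = 0
    for m in molecules:
        if m.chrom != chrom:
            continue
        has_left = any(s < fs and e > lo for s, e in m.reads)
        has_right = any(e > fe and s < hi for s, e in m.reads)
        if has_left and has_right:
            spanning += 1
    supported = min_depth >= depth_threshold and spanning >= 1
    return GapSupportCall(
        gap_id=gap_id or f"{chrom}:{fs}-{fe}",
        min_depth_in_fill=min_depth,
        spanning_molecules=spanning,
        verdict="supported" if supported else "unsupported",
    )


def coverage_stats(
    rows: Sequence[ReadRow],
    assembly: Assembly,
    total_reads: Optional[int] = None,
) -> dict[str, float]:
    """Alignment rate and genome-wide mean depth over non-N bases."""
    n_aligned = len(rows)
    total = total_reads if total_reads is not None else n_aligned
    aligned_bases = sum(e - s for _, _, _, s, e in rows)
    size = assembly.non_n_size()
    return {
        "alignment_rate": n_aligned / total if total else 0.0,
        "mean_depth": aligned_bases / size if size else 0.0,
    }
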