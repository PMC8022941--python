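"""Telomere discovery in raw long reads and centromere monomer-array analysis.

Telomeric reads are selected by non-overlapping counts of the conserved
metazoan hexamer (TTAGGG / CCCTAA), anchored to chromosome termini through
unique primary-alignment spans, and merged onto the assembly as end
extensions.  Centromeric arrays are located by scanning contigs for a
monomer consensus on either strand; periodicity of the array (higher-order
repeat structure) is estimated from inter-monomer identities.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from ._seq import revcomp, seq_to_array
from .alignments import AlignmentBlock, unique_anchor_span
from .genome_model import Assembly, Edit

log = logging.getLogger(__name__)

TELOMERE_FWD = "TTAGGG"
TELOMERE_REV = "CCCTAA"


def count_motif(sequence: str, motif: str) -> int:
    """Non-overlapping exact occurrences, case-insensitive, left-to-right."""
    if not motif:
        raise ValueError("motif must be non-empty")
    return sequence.upper().count(motif.upper())


@dataclass
class TelomereCandidate:
    read: str
    motif_count_fwd: int
    motif_count_rev: int
    assigned_end: Optional[tuple[str, str]] = None  # (chrom, 'left'|'right')
    unique_anchor_bp: int = 0


def select_telomeric_reads(
    reads: Mapping[str, str],
    threshold: int = 50,
) -> list[TelomereCandidate]:
    """Reads with strictly more than ``threshold`` motif occurrences on
    either strand."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    out = []
    for name, seq in reads.items():
        fwd = count_motif(seq, TELOMERE_FWD)
        rev = count_motif(seq, TELOMERE_REV)
        if fwd > threshold or rev > threshold:
            out.append(TelomereCandidate(name, fwd, rev))
    return out


def assign_telomere(
    candidate: TelomereCandidate,
    blocks: Sequence[AlignmentBlock],
    chrom_lengths: Mapping[str, int],
    min_unique: int = 10_000,
    end_window: int = 50_000,
) -> TelomereCandidate:
    """Assign a telomeric read to one chromosome end.

    Requires more than ``min_unique`` bp of uniquely aligned read sequence
    within ``end_window`` of a terminus; reads anchoring at more than one
    end are left unassigned.
    """
    primaries = [b for b in blocks if b.query == candidate.read and b.is_primary]
    hits: list[tuple[str, str, int]] = []
    for chrom, length in chrom_lengths.items():
        left = unique_anchor_span(primaries, chrom, 0, min(end_window, length))
        right = unique_anchor_span(
            primaries, chrom, max(0, length - end_window), length
        )
        if left > min_unique:
            hits.append((chrom, "left", left))
        if right > min_unique:
            hits.append((chrom, "right", right))
    if len(hits) == 1:
        chrom, side, span = hits[0]
        candidate.assigned_end = (chrom, side)
        candidate.unique_anchor_bp = span
    else:
        candidate.assigned_end = None
        if len(hits) > 1:
            log.info("%s: ambiguous telomere anchors %s", candidate.read, hits)
    return candidate


def merge_telomere(
    assembly: Assembly,
    candidate: TelomereCandidate,
    read_seq: str,
    blocks: Sequence[AlignmentBlock],
) -> Optional[Edit]:
    """End-extension edit appending the read's unaligned telomeric overhang.

    The aligned anchor is never duplicated and existing chromosome bases are
    never modified; the chromosome grows by exactly the overhang length.
    Returns None when the read has no overhang beyond the terminus.
    """
    if candidate.assigned_end is None:
        raise ValueError("candidate has no assigned end")
    chrom, side = candidate.assigned_end
    length = len(assembly[chrom])
    anchors = [
        b for b in blocks
        if b.query == candidate.read and b.is_primary and b.target == chrom
    ]
    if not anchors:
        return None
    strand = max(anchors, key=lambda b: b.matches).strand
    same = [b for b in anchors if b.strand == strand]
    q_lo = min(b.q_start for b in same)
    q_hi = max(b.q_end for b in same)
    if side == "right":
        overhang = read_seq[q_hi:] if strand == "+" else revcomp(read_seq[:q_lo])
        start = end = length
    else:
        overhang = read_seq[:q_lo] if strand == "+" else revcomp(read_seq[q_hi:])
        start = end = 0
    if not overhang:
        return None
    return Edit(chrom, start, end, overhang, candidate.read, "end_extension")


# ---------------------------------------------------------------------------
# centromere monomer arrays
# ---------------------------------------------------------------------------

@dataclass
class MonomerHit:
    start: int
    end: int
    strand: str
    identity: float


@dataclass
class MonomerArray:
    contig: str
    hits: list[MonomerHit]
    span: int
    monomer_count: int
    hor_period: Optional[int] = None


def _window_identity(seq_arr: np.ndarray, cons_arr: np.ndarray) -> np.ndarray:
    """Identity of the consensus at every start position (vectorised)."""
    m = len(cons_arr)
    n = len(seq_arr) - m + 1
    if n <= 0:
        return np.zeros(0)
    scores = np.zeros(n)
    chunk = 200_000
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        win = np.lib.stride_tricks.sliding_window_view(seq_arr[lo : hi + m - 1], m)
        scores[lo:hi] = (win == cons_arr).mean(axis=1)
    return scores


def find_monomers(
    sequence: str,
    consensus: str,
    min_identity: float = 0.75,
) -> list[MonomerHit]:
    """Non-overlapping local matches to the consensus monomer, either strand.

    A greedy left-to-right scan records a hit whenever the better-strand
    identity at the current position reaches ``min_identity``, then jumps a
    full monomer length.
    """
    if len(consensus) < 50:
        raise ValueError("consensus monomer must be >= 50 bp")
    m = len(consensus)
    seq_arr = seq_to_array(sequence)
    fwd = _window_identity(seq_arr, seq_to_array(consensus))
    rev = _window_identity(seq_arr, seq_to_array(revcomp(consensus)))
    hits: list[MonomerHit] = []
    pos = 0
    n = len(fwd)
    while pos < n:
        f, r = fwd[pos], rev[pos]
        if max(f, r) >= min_identity:
            strand = "+" if f >= r else "-"
            hits.append(MonomerHit(pos, pos + m, strand, float(max(f, r))))
            pos += m
        else:
            pos += 1
    return hits


def monomer_array(
    contig: str,
    sequence: str,
    consensus: str,
    min_identity: float = 0.75,
) -> Optional[MonomerArray]:
    hits = find_monomers(sequence, consensus, min_identity)
    if not hits:
        return None
    span = hits[-1].end - hits[0].start
    return MonomerArray(contig, hits, span, len(hits))


def assign_centromere(
    blocks: Sequence[AlignmentBlock],
    centromere_gaps: Mapping[str, tuple[int, int]],
    min_unique: int = 10_000,
    side_window: int = 50_000,
) -> Optional[tuple[str, str]]:
    """Anchor a centromeric contig to one side of an annotated centromere gap.

    Retained only when more than ``min_unique`` bp align uniquely within the
    side window of exactly one chromosome; anchors flanking both sides of
    one chromosome's gap classify the contig as spanning.
    """
    primaries = [b for b in blocks if b.is_primary]
    per_chrom: dict[str, set[str]] = {}
    for chrom, (gs, ge) in centromere_gaps.items():
        left = unique_anchor_span(primaries, chrom, max(0, gs - side_window), gs)
        right = unique_anchor_span(primaries, chrom, ge, ge + side_window)
        sides = set()
        if left > min_unique:
            sides.add("left_of_gap")
        if right > min_unique:
            sides.add("right_of_gap")
        if sides:
            per_chrom[chrom] = sides
    if len(per_chrom) != 1:
        return None
    chrom, sides = next(iter(per_chrom.items()))
    if sides == {"left_of_gap", "right_of_gap"}:
        return chrom, "spanning"
    return chrom, sides.pop()


def self_identity_matrix(
    sequence: str,
    window: int = 300,
    step: Optional[int] = None,
) -> np.ndarray:
    """Pairwise identity between fixed windows of a sequence.

    The matrix backs dotplot-style rendering of repeat structure; graphics
    themselves are out of scope, only the TSV export is provided.
    """
    step = step or window
    arr = seq_to_array(sequence)
    starts = range(0, len(arr) - window + 1, step)
    wins = np.stack([arr[s : s + window] for s in starts])
    n = len(wins)
    out = np.empty((n, n))
    for i in range(n):
        out[i] = (wins == wins[i]).mean(axis=1)
    return out


def write_identity_matrix(matrix: np.ndarray, path) -> None:
    np.savetxt(path, matrix, fmt="%.4f", delimiter="\t")


def _pair_identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    aa, bb = seq_to_array(a[:n]), seq_to_array(b[:n])
    return float((aa == bb).mean())


@dataclass
class HorResult:
    period: int
    scores: dict[int, float]
    confident: bool


def hor_period(
    monomers: Sequence[str],
    margin: float = 0.02,
    tandem_identity: float = 0.95,
) -> Optional[HorResult]:
    """Dominant higher-order-repeat period of a monomer array.

    score(p) = mean identity between monomer i and monomer i+p over all
    valid i, for p in 1..n//3.  The dominant period must beat score(1) by
    ``margin`` identity; otherwise the array is pure tandem (period 1),
    flagged low-confidence when adjacent-monomer identity is also low.
    Returns None for fewer than 6 monomers (undefined).
    """
    n = len(monomers)
    if n < 6:
        return None
    scores = {}
    for p in range(1, n // 3 + 1):
        vals = [_pair_identity(monomers[i], monomers[i + p]) for i in range(n - p)]
        scores[p] = float(np.mean(vals))
    best = max(scores, key=lambda p: (scores[p], -p))
    if best > 1 and scores[best] - scores[1] > margin:
        return HorResult(best, scores, True)
    return HorResult(1, scores, scores[1] >= tandem_identity)
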