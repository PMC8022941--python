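"""Optical-map support filtering of scaffolded contigs and inversion checks."""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from .genome_model import SequenceRecord

log = logging.getLogger(__name__)


@dataclass
class OpticalAlignment:
    """One optical contig aligned to an assembly interval."""

    optical_contig: str
    chrom: str
    t_start: int
    t_end: int
    collinear: bool = True

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("degenerate optical alignment")


def read_optical_tsv(path: Union[str, Path]) -> list[OpticalAlignment]:
    """Simplified dialect: optical_contig, chrom, start, end, collinear."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            out.append(
                OpticalAlignment(
                    f[0], f[1], int(f[2]), int(f[3]),
                    f[4].strip().lower() in ("1", "true", "yes") if len(f) > 4 else True,
                )
            )
    return out


def read_xmap(path: Union[str, Path]) -> list[OpticalAlignment]:
    """Thin XMAP converter (1-based closed positions -> 0-based half-open).

    Uses XmapEntryID, QryContigID, RefContigID, RefStartPos, RefEndPos and
    Orientation; the alignment cigar is ignored.  Orientation '-' rows are
    normalized so that t_start < t_end.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            qry, ref = f[1], f[2]
            ref_start, ref_end = float(f[5]), float(f[6])
            lo, hi = sorted((ref_start, ref_end))
            out.append(OpticalAlignment(qry, ref, int(lo) - 1, int(hi)))
    return out


def _coverage(intervals: Iterable[tuple[int, int]], lo: int, hi: int) -> int:
    clipped = sorted(
        (max(s, lo), min(e, hi)) for s, e in intervals if s < hi and e > lo
    )
    total = 0
    cur_e = lo
    for s, e in clipped:
        s = max(s, cur_e)
        if e > s:
            total += e - s
            cur_e = e
    return total


def contig_support(
    contig_interval: tuple[str, int, int],
    alignments: Sequence[OpticalAlignment],
) -> tuple[bool, float]:
    """Fraction of a scaffolded contig covered by optical alignments.

    Supported iff >= 50% of the contig length overlaps optical contigs
    (inclusive at exactly 0.5).
    """
    chrom, start, end = contig_interval
    if end <= start:
        raise ValueError("degenerate contig interval")
    covered = _coverage(
        [(a.t_start, a.t_end) for a in alignments if a.chrom == chrom], start, end
    )
    frac = covered / (end - start)
    return frac >= 0.5, frac


def prune_unsupported(
    scaffold: SequenceRecord,
    boundaries: Sequence[tuple[str, int, int]],
    support: Mapping[str, bool],
    spacer_len: int = 100,
) -> tuple[SequenceRecord, list[SequenceRecord]]:
    """Excise unsupported contigs from a scaffold.

    ``boundaries`` (name, start, end) must tile the scaffold.  Each excision
    leaves a single spacer gap; removed contigs come back as unplaced
    records.  Retained contig sequence is never altered.
    """
    cursor = 0
    for name, s, e in boundaries:
        if s != cursor:
            raise ValueError("contig boundaries must tile the scaffold")
        cursor = e
    if cursor != len(scaffold):
        raise ValueError("contig boundaries must tile the scaffold")
    removed: list[SequenceRecord] = []
    pieces: list[str] = []
    pending_excision = False
    for name, s, e in boundaries:
        seq = scaffold.sequence[s:e]
        if support.get(name, False):
            if pending_excision and pieces:
                pieces.append("N" * spacer_len)
            pieces.append(seq)
            pending_excision = False
        else:
            removed.append(SequenceRecord(name, seq, "unplaced"))
            pending_excision = True
    if not any(p.strip("N") for p in pieces):
        raise ValueError(f"{scaffold.name}: all contigs unsupported")
    pruned_seq = "".join(pieces) if removed else scaffold.sequence
    return SequenceRecord(scaffold.name, pruned_seq, scaffold.category), removed


def adjudicate_inversion(
    inversion: tuple[str, int, int],
    alignments: Sequence[OpticalAlignment],
    margin: int = 10_000,
) -> bool:
    """An inversion is supported only when embedded strictly inside one
    collinear optical contig with ``margin`` bp to spare on both sides."""
    chrom, start, end = inversion
    for a in alignments:
        if not a.collinear or a.chrom != chrom:
            continue
        if a.t_start < start - margin and a.t_end > end + margin:
            return True
    return False


def mean_support_fraction(
    contigs: Sequence[tuple[str, int, int]],
    alignments: Sequence[OpticalAlignment],
) -> float:
    """Average optical coverage fraction over contigs (summary statistic)."""
    if not contigs:
        return 0.0
    fracs = [contig_support(c, alignments)[1] for c in contigs]
    return sum(fracs) / len(fracs)
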