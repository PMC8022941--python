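"""Disposition of previously unplaced contigs after gap closing.

Each unplaced contig is either placed within a newly filled gap, contained
elsewhere in the patched assembly, or retained as unplaced; the remainder
is concatenated into a single spacer-separated record.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .alignments import AlignmentBlock, Placement, placement_filter
from .genome_model import SequenceRecord, percentage

log = logging.getLogger(__name__)


@dataclass
class ChrUnDisposition:
    contig: str
    verdict: str  # placed_in_gap | contained | unplaced
    location: Optional[tuple[str, int, int]] = None
    prior_assignment: Optional[str] = None

    def __post_init__(self) -> None:
        if self.verdict == "unplaced" and self.location is not None:
            raise ValueError("unplaced contigs carry no location")


def classify_chrun(
    contig_lengths: Mapping[str, int],
    blocks: Sequence[AlignmentBlock],
    fill_intervals: Sequence[tuple[str, int, int]],
    min_q_frac: float = 0.90,
    max_mismatch: float = 0.02,
    prior_assignments: Optional[Mapping[str, str]] = None,
) -> list[ChrUnDisposition]:
    """Classify unplaced contigs against the patched assembly.

    A contig passing the stringent placement filter whose best location
    overlaps (>= 1 bp) a ledger fill interval is ``placed_in_gap``; passing
    elsewhere is ``contained``; anything else stays ``unplaced``.
    """
    by_query: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        by_query.setdefault(b.query, []).append(b)
    fills_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in fill_intervals:
        fills_by_chrom.setdefault(chrom, []).append((s, e))
    out = []
    for contig in contig_lengths:
        prior = (prior_assignments or {}).get(contig)
        placement = placement_filter(
            by_query.get(contig, []), contig_lengths[contig], min_q_frac, max_mismatch
        )
        if placement is None:
            out.append(ChrUnDisposition(contig, "unplaced", None, prior))
            continue
        loc = (placement.target, placement.t_start, placement.t_end)
        in_fill = any(
            placement.t_start < e and s < placement.t_end
            for s, e in fills_by_chrom.get(placement.target, [])
        )
        verdict = "placed_in_gap" if in_fill else "contained"
        out.append(ChrUnDisposition(contig, verdict, loc, prior))
    return out


def concatenate_unplaced(
    contigs: Sequence[SequenceRecord],
    spacer_len: int = 100,
) -> tuple[SequenceRecord, list[tuple[str, int, int, str]]]:
    """Join unplaced contigs into one record separated by N spacers.

    Returns the concatenated record plus BED rows (chrom, start, end, name)
    locating each contig, which round-trip bit-exactly.
    """
    if not contigs:
        raise ValueError("need at least one contig")
    names = [c.name for c in contigs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate contig names")
    pieces = []
    bed = []
    pos = 0
    for i, c in enumerate(contigs):
        if i:
            pieces.append("N" * spacer_len)
            pos += spacer_len
        pieces.append(c.sequence)
        bed.append(("chrUn", pos, pos + len(c), c.name))
        pos += len(c)
    return SequenceRecord("chrUn", "".join(pieces), "unplaced"), bed


def assignment_concordance(
    dispositions: Sequence[ChrUnDisposition],
) -> tuple[Optional[float], int, int]:
    """Fraction of placed contigs landing on their prior chromosome.

    Returns (percent to one decimal, matching, total); percent is None
    (undefined) when no contig has both a placement and a prior assignment.
    """
    eligible = [
        d for d in dispositions
        if d.location is not None and d.prior_assignment is not None
    ]
    if not eligible:
        return None, 0, 0
    matching = sum(1 for d in eligible if d.location[0] == d.prior_assignment)
    return percentage(matching, len(eligible)), matching, len(eligible)
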