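"""Close or partially close reference gaps with donor contigs.

Donor contigs aligned to the reference (and passing the collinearity filter)
are anchored on the two gap flanks.  A spanning anchor pair yields a fill
candidate; the fill is accepted when its length deviates from the gap length
by at most the configured ratio.  Fills implying removal of flanking
non-N sequence (the mis-ligation signature of small non-linear homologies)
are rejected by the shrinkage guard.  Single-flank anchors extend into the
gap without closing it.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from ._seq import revcomp
from .alignments import AlignmentBlock, filter_collinear
from .genome_model import (
    Assembly,
    Edit,
    GapRecord,
    PatchLedger,
    percentage,
)

log = logging.getLogger(__name__)

OUTCOMES = (
    "closed",
    "partial_left",
    "partial_right",
    "rejected_deviation",
    "rejected_shrinkage",
    "unfilled",
)


@dataclass
class GapFillConfig:
    deviation: float = 1.0        # -a: |fill - gap_len| <= deviation * gap_len
    flank: int = 1000             # anchor window around gap boundaries
    min_identity: float = 0.98    # collinearity filter on donor alignments
    min_len: int = 4000
    max_extension: int = 10**9    # cap on single-anchor partial fills


@dataclass
class AnchorPair:
    """Candidate anchors of one donor contig (one or both flanks)."""

    donor: str
    strand: str
    left: Optional[AlignmentBlock] = None
    right: Optional[AlignmentBlock] = None

    @property
    def spanning(self) -> bool:
        return self.left is not None and self.right is not None

    @property
    def summed_matches(self) -> int:
        return sum(b.matches for b in (self.left, self.right) if b)

    @property
    def summed_identity(self) -> float:
        return sum(b.identity for b in (self.left, self.right) if b)

    @property
    def summed_span(self) -> int:
        return sum(b.target_span for b in (self.left, self.right) if b)


@dataclass
class GapClosure:
    """Outcome of attempting to fill one gap."""

    gap: GapRecord
    outcome: str = "unfilled"
    left_anchor: Optional[AlignmentBlock] = None
    right_anchor: Optional[AlignmentBlock] = None
    fill: Optional[str] = None
    deviation: Optional[float] = None
    raw_span: Optional[int] = None    # reference bases between the anchors
    raw_len: Optional[int] = None     # donor bases between the anchors
    edit: Optional[Edit] = None

    @property
    def fill_len(self) -> int:
        return len(self.fill) if self.fill else 0


def anchor_contigs(
    gap: GapRecord,
    blocks: Sequence[AlignmentBlock],
    flank: int = 1000,
) -> list[AnchorPair]:
    """Pair donor alignments flanking a gap.

    Left anchors end within ``flank`` bp of ``gap.start``; right anchors
    start within ``flank`` bp of ``gap.end``.  Anchors are paired per
    (donor, strand); strand-inconsistent flanks are never paired.
    """
    lefts: dict[tuple[str, str], AlignmentBlock] = {}
    rights: dict[tuple[str, str], AlignmentBlock] = {}
    for b in blocks:
        if b.target != gap.chrom:
            continue
        key = (b.query, b.strand)
        if abs(b.t_end - gap.start) <= flank:
            if key not in lefts or b.matches > lefts[key].matches:
                lefts[key] = b
        if abs(b.t_start - gap.end) <= flank:
            if key not in rights or b.matches > rights[key].matches:
                rights[key] = b
    pairs = []
    for key in sorted(set(lefts) | set(rights)):
        donor, strand = key
        pairs.append(
            AnchorPair(donor, strand, lefts.get(key), rights.get(key))
        )
    return pairs


def close_gap(
    gap: GapRecord,
    pair: AnchorPair,
    donor_seq: str,
    a: float = 1.0,
) -> GapClosure:
    """Fill a gap from a spanning anchor pair.

    The donor sequence between the two anchors (reverse-complemented for
    '-' strand pairs) is trimmed to the exact gap interval so that no non-N
    reference base is ever overwritten.  Anchors out of order on the donor,
    or trims implying deletion of flanking sequence, signal non-linear
    homology and are rejected.
    """
    if not pair.spanning:
        raise ValueError("close_gap requires a spanning pair")
    left, right = pair.left, pair.right
    result = GapClosure(gap=gap, left_anchor=left, right_anchor=right)
    if pair.strand == "+":
        in_order = left.q_end <= right.q_start
        raw = donor_seq[left.q_end : right.q_start] if in_order else ""
        src = f"{pair.donor}:{left.q_end}-{right.q_start}:+"
    else:
        in_order = right.q_end <= left.q_start
        raw = revcomp(donor_seq[right.q_end : left.q_start]) if in_order else ""
        src = f"{pair.donor}:{right.q_end}-{left.q_start}:-"
    result.raw_span = right.t_start - left.t_end
    result.raw_len = len(raw)
    if not in_order:
        result.outcome = "rejected_shrinkage"
        return result
    left_trim = gap.start - left.t_end
    right_trim = right.t_start - gap.end
    if left_trim < 0 or right_trim < 0 or left_trim + right_trim > len(raw):
        # the donor joins the two flanks with too little sequence between
        # them: applying it would delete flanking non-N bases
        result.outcome = "rejected_shrinkage"
        return result
    fill = raw[left_trim : len(raw) - right_trim]
    result.fill = fill
    result.deviation = abs(len(fill) - gap.length) / max(gap.length, 1)
    if result.deviation > a:
        result.outcome = "rejected_deviation"
        return result
    result.outcome = "closed"
    result.edit = Edit(gap.chrom, gap.start, gap.end, fill, src, "gap_fill")
    return result


def extend_gap(
    gap: GapRecord,
    pair: AnchorPair,
    donor_seq: str,
    max_ext: int = 10**9,
) -> GapClosure:
    """Insert a single-anchor donor overhang into the gap from one side.

    The insertion is capped at min(overhang, gap length, ``max_ext``); the
    remainder of the gap stays N and the scaffold never grows.
    """
    if pair.spanning:
        raise ValueError("extend_gap requires a single anchor")
    if pair.left is not None:
        anchor, side = pair.left, "left"
    elif pair.right is not None:
        anchor, side = pair.right, "right"
    else:
        raise ValueError("pair has no anchor")
    result = GapClosure(gap=gap)
    if side == "left":
        result.left_anchor = anchor
        overhang = (
            donor_seq[anchor.q_end :] if pair.strand == "+"
            else revcomp(donor_seq[: anchor.q_start])
        )
        skip = gap.start - anchor.t_end
        if skip < 0 or skip >= len(overhang):
            result.outcome = "unfilled"
            return result
        usable = overhang[skip:]
        k = min(len(usable), gap.length, max_ext)
        fill = usable[:k]
        start, end = gap.start, gap.start + k
        result.outcome = "partial_left"
    else:
        result.right_anchor = anchor
        overhang = (
            donor_seq[: anchor.q_start] if pair.strand == "+"
            else revcomp(donor_seq[anchor.q_end :])
        )
        skip = anchor.t_start - gap.end
        if skip < 0 or skip >= len(overhang):
            result.outcome = "unfilled"
            return result
        usable = overhang[: len(overhang) - skip]
        k = min(len(usable), gap.length, max_ext)
        fill = usable[len(usable) - k :]
        start, end = gap.end - k, gap.end
        result.outcome = "partial_right"
    if k <= 0:
        result.outcome = "unfilled"
        return result
    result.fill = fill
    src = f"{pair.donor}:overhang:{pair.strand}"
    result.edit = Edit(gap.chrom, start, end, fill, src, "gap_fill")
    return result


def shrinkage_guard(
    closures: Sequence[GapClosure],
) -> tuple[list[GapClosure], list[GapClosure]]:
    """Ledger-level guard against fills that remove flanking sequence.

    A fill whose application would shrink the chromosome by more than the
    gap length is relabeled ``rejected_shrinkage`` and excluded.
    """
    accepted, rejected = [], []
    for c in closures:
        bad = False
        if c.outcome == "rejected_shrinkage":
            bad = True
        elif c.outcome == "closed" and c.raw_span is not None and c.raw_len is not None:
            if c.raw_span - c.raw_len > c.gap.length:
                bad = True
        if bad:
            c.outcome = "rejected_shrinkage"
            c.edit = None
            rejected.append(c)
        else:
            accepted.append(c)
    return accepted, rejected


@dataclass
class GapFillResult:
    ledger: PatchLedger
    closures: list[GapClosure]
    report: dict = field(default_factory=dict)


def _rank_pairs(pairs: list[AnchorPair]) -> list[AnchorPair]:
    return sorted(
        pairs,
        key=lambda p: (-p.summed_identity, -p.summed_span, p.donor, p.strand),
    )


def run_gapfill(
    assembly: Assembly,
    gaps: Sequence[GapRecord],
    donors: Mapping[str, str],
    blocks: Sequence[AlignmentBlock],
    config: Optional[GapFillConfig] = None,
) -> GapFillResult:
    """Single-pass gap filling over all gaps; deterministic given its inputs.

    Per gap, spanning anchor pairs are ranked by summed anchor identity,
    then anchor span; an exact tie at the top is rejected and logged.  When
    no spanning pair exists, the best single anchor extends the gap
    partially.  The returned report partitions every gap into
    closed / partial / unfilled / rejected_*.
    """
    cfg = config or GapFillConfig()
    filtered = filter_collinear(blocks, cfg.min_identity, cfg.min_len)
    by_chrom: dict[str, list[AlignmentBlock]] = {}
    for b in filtered:
        by_chrom.setdefault(b.target, []).append(b)

    closures: list[GapClosure] = []
    for gap in gaps:
        pairs = anchor_contigs(gap, by_chrom.get(gap.chrom, []), cfg.flank)
        spanning = _rank_pairs([p for p in pairs if p.spanning])
        singles = _rank_pairs([p for p in pairs if not p.spanning])
        if spanning:
            if (
                len(spanning) > 1
                and spanning[0].summed_identity == spanning[1].summed_identity
                and spanning[0].summed_span == spanning[1].summed_span
                and spanning[0].donor != spanning[1].donor
            ):
                log.warning("%s: tied spanning pairs, leaving unfilled", gap.gap_id)
                closures.append(GapClosure(gap=gap, outcome="unfilled"))
                continue
            best = spanning[0]
            closures.append(close_gap(gap, best, donors[best.donor], cfg.deviation))
        elif singles:
            best = singles[0]
            closures.append(
                extend_gap(gap, best, donors[best.donor], cfg.max_extension)
            )
        else:
            closures.append(GapClosure(gap=gap, outcome="unfilled"))

    accepted, rejected = shrinkage_guard(closures)

    ledger = PatchLedger()
    for c in accepted:
        if c.edit is None:
            continue
        # guard property: filled bases only ever replace N
        locus = assembly[c.edit.chrom].sequence[c.edit.start : c.edit.end]
        if locus.strip("N"):
            raise AssertionError(
                f"{c.gap.gap_id}: fill would overwrite non-N reference bases"
            )
        ledger.add(c.edit)
        c.gap.fill_source = c.edit.fill_source
        c.gap.added_bases = len(c.edit.replacement)
        # status reflects remaining N at the locus, not how it was anchored
        full = c.outcome == "closed" or (
            c.edit.start == c.gap.start
            and c.edit.end == c.gap.end
            and "N" not in c.edit.replacement
        )
        c.gap.status = "closed" if full else "partial"

    counts = {k: 0 for k in OUTCOMES}
    for c in closures:
        counts[c.outcome] += 1
    report = {
        "total": len(closures),
        "closed": counts["closed"],
        "partial": counts["partial_left"] + counts["partial_right"],
        "unfilled": counts["unfilled"],
        "rejected_deviation": counts["rejected_deviation"],
        "rejected_shrinkage": counts["rejected_shrinkage"],
        "bases_added": sum(
            len(c.edit.replacement) for c in closures if c.edit is not None
        ),
        "pct_closed": percentage(counts["closed"], len(closures))
        if closures
        else 0.0,
    }
    return GapFillResult(ledger=ledger, closures=closures, report=report)
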