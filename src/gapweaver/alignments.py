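"""Pairwise alignment parsing, filtering and anchor-span accounting.

PAF (minimap2 dialect) is the native input.  All downstream threshold rules
(collinearity filtering, unique anchor spans, stringent placement) live here
so that every module applies identical alignment semantics.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

log = logging.getLogger(__name__)


@dataclass
class AlignmentBlock:
    """One pairwise alignment record (coordinates 0-based half-open)."""

    query: str
    q_len: int
    q_start: int
    q_end: int
    strand: str
    target: str
    t_len: int
    t_start: int
    t_end: int
    matches: int
    block_len: int
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.q_end <= self.q_start or self.t_end <= self.t_start:
            raise ValueError("degenerate alignment interval")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def identity(self) -> float:
        return self.matches / self.block_len if self.block_len else 0.0

    @property
    def target_span(self) -> int:
        return self.t_end - self.t_start

    @property
    def query_span(self) -> int:
        return self.q_end - self.q_start


class PafResult(list):
    """List of :class:`AlignmentBlock` with a malformed-line counter."""

    def __init__(self, blocks: Iterable[AlignmentBlock] = (), n_skipped: int = 0):
        super().__init__(blocks)
        self.n_skipped = n_skipped


def parse_paf(source: Union[str, Path, Iterable[str]]) -> PafResult:
    """Parse PAF records; malformed lines are skipped with a warning.

    Identity is column 10 / column 11; the primary flag comes from the
    ``tp:A`` tag when present (``tp:A:P`` / absent -> primary).
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return parse_paf(list(fh))
    blocks: list[AlignmentBlock] = []
    skipped = 0
    for line in source:
        line = line.rstrip("\n")
        if not line:
            continue
        f = line.split("\t")
        try:
            if len(f) < 12:
                raise ValueError("fewer than 12 columns")
            primary = True
            for tag in f[12:]:
                if tag.startswith("tp:A:"):
                    primary = tag[5] == "P"
            blocks.append(
                AlignmentBlock(
                    query=f[0], q_len=int(f[1]), q_start=int(f[2]), q_end=int(f[3]),
                    strand=f[4],
                    target=f[5], t_len=int(f[6]), t_start=int(f[7]), t_end=int(f[8]),
                    matches=int(f[9]), block_len=int(f[10]),
                    is_primary=primary,
                )
            )
        except (ValueError, IndexError) as exc:
            skipped += 1
            log.warning("skipping malformed PAF line (%s): %.80s", exc, line)
    return PafResult(blocks, skipped)


def paf_line(b: AlignmentBlock, mapq: int = 60) -> str:
    """Serialize a block as one PAF line (used by the simulator)."""
    tp = "P" if b.is_primary else "S"
    return (
        f"{b.query}\t{b.q_len}\t{b.q_start}\t{b.q_end}\t{b.strand}\t"
        f"{b.target}\t{b.t_len}\t{b.t_start}\t{b.t_end}\t"
        f"{b.matches}\t{b.block_len}\t{mapq}\ttp:A:{tp}"
    )


def write_paf(blocks: Iterable[AlignmentBlock], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(paf_line(b) + "\n")


def filter_collinear(
    blocks: Iterable[AlignmentBlock],
    min_identity: float = 0.98,
    min_len: int = 4000,
) -> list[AlignmentBlock]:
    """Strict thresholds: identity > ``min_identity`` AND target span > ``min_len``."""
    if not (0 < min_identity <= 1):
        raise ValueError("min_identity must be in (0, 1]")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [
        b for b in blocks
        if b.identity > min_identity and b.target_span > min_len
    ]


def _merged_length(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


def unique_anchor_span(
    blocks: Sequence[AlignmentBlock],
    target: str,
    region_start: int,
    region_end: int,
) -> int:
    """Query bases covered by exactly one primary block intersecting the region.

    ``blocks`` are the alignments of a single query.  A query base covered by
    two or more primary alignments anywhere is not unique and contributes 0.
    """
    primaries = [b for b in blocks if b.is_primary]
    if not primaries:
        return 0
    # sweep over query coordinates: multiplicity across ALL primary blocks
    events: list[tuple[int, int]] = []
    for b in primaries:
        events.append((b.q_start, 1))
        events.append((b.q_end, -1))
    in_region = [
        (b.q_start, b.q_end)
        for b in primaries
        if b.target == target and b.t_start < region_end and b.t_end > region_start
    ]
    if not in_region:
        return 0
    bounds = sorted({x for x, _ in events} | {x for iv in in_region for x in iv})
    events.sort()
    span = 0
    depth = 0
    ei = 0
    for i in range(len(bounds) - 1):
        lo, hi = bounds[i], bounds[i + 1]
        while ei < len(events) and events[ei][0] <= lo:
            depth += events[ei][1]
            ei += 1
        if depth != 1:
            continue
        covered = sum(
            max(0, min(hi, e) - max(lo, s)) > 0 for s, e in in_region
        )
        if covered:
            span += hi - lo
    return span


@dataclass
class Placement:
    """Best single-target placement of a query."""

    target: str
    t_start: int
    t_end: int
    aligned_query_bases: int
    mismatch_fraction: float


def placement_filter(
    blocks: Sequence[AlignmentBlock],
    query_len: int,
    min_q_frac: float = 0.90,
    max_mismatch: float = 0.02,
) -> Optional[Placement]:
    """Stringent placement: >= ``min_q_frac`` of the query aligned to a single
    target with a mismatch fraction <= ``max_mismatch`` (both inclusive).

    Block coverage is summed per target (split blocks merged on query
    coordinates).  The mismatch fraction is
    ``(aligned query bases - matches) / aligned query bases``.
    Ties break by most aligned bases, then lowest mismatch, then target name.
    """
    if query_len <= 0:
        raise ValueError("query_len must be positive")
    by_target: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        by_target.setdefault(b.target, []).append(b)
    candidates = []
    for target in sorted(by_target):
        tb = by_target[target]
        aligned = _merged_length([(b.q_start, b.q_end) for b in tb])
        if aligned == 0:
            continue
        matches = min(sum(b.matches for b in tb), aligned)
        mism = (aligned - matches) / aligned
        candidates.append(
            Placement(
                target=target,
                t_start=min(b.t_start for b in tb),
                t_end=max(b.t_end for b in tb),
                aligned_query_bases=aligned,
                mismatch_fraction=mism,
            )
        )
    passing = [
        p for p in candidates
        if p.aligned_query_bases >= min_q_frac * query_len
        and p.mismatch_fraction <= max_mismatch
    ]
    if not passing:
        return None
    passing.sort(key=lambda p: (-p.aligned_query_bases, p.mismatch_fraction, p.target))
    return passing[0]
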