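"""Permutation tests for feature enrichment in sets of genomic segments.

The observed segments (e.g. newly filled gap intervals) are compared with
null draws in which segments of identical lengths are placed uniformly at
random across chromosomes, avoiding excluded intervals.  Statistics are the
count of features intersected or the number of bases overlapped; the
empirical p-value uses the +1 correction and so never returns 0.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

log = logging.getLogger(__name__)

Interval = tuple[str, int, int]


class PlacementError(RuntimeError):
    """Segments could not be placed without overlap."""


def _allowed_runs(
    genome: Mapping[str, int],
    excluded: Sequence[Interval],
) -> list[Interval]:
    """Maximal intervals available for placement after exclusions."""
    excl: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in excluded:
        excl.setdefault(chrom, []).append((s, e))
    runs = []
    for chrom in genome:
        cursor = 0
        for s, e in sorted(excl.get(chrom, [])):
            s, e = max(0, s), min(genome[chrom], e)
            if s > cursor:
                runs.append((chrom, cursor, s))
            cursor = max(cursor, e)
        if genome[chrom] > cursor:
            runs.append((chrom, cursor, genome[chrom]))
    return runs


def shuffle_segments(
    lengths: Sequence[int],
    genome: Mapping[str, int],
    excluded: Sequence[Interval] = (),
    rng: Optional[np.random.Generator] = None,
    allow_overlap: bool = False,
    max_tries: int = 1000,
) -> list[Interval]:
    """Place segments of the given lengths uniformly at random.

    Each segment lands entirely within an allowed run; by default segments
    may not overlap each other (bounded retries, then :class:`PlacementError`).
    The returned placements preserve the input length multiset exactly.
    """
    rng = rng or np.random.default_rng()
    runs = _allowed_runs(genome, excluded)
    if not runs:
        raise PlacementError("no allowed space")
    run_chrom = [r[0] for r in runs]
    run_start = np.array([r[1] for r in runs], dtype=np.int64)
    run_end = np.array([r[2] for r in runs], dtype=np.int64)
    placed: list[Interval] = []
    placed_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for L in lengths:
        if L < 1:
            raise ValueError("segment lengths must be >= 1")
        avail = np.maximum(run_end - run_start - L + 1, 0)
        total = int(avail.sum())
        if total == 0:
            raise PlacementError(f"no run can hold a segment of length {L}")
        cum = np.cumsum(avail)
        ok = False
        for _ in range(max_tries):
            r = int(rng.integers(total))
            ri = int(np.searchsorted(cum, r, side="right"))
            offset = r - (int(cum[ri - 1]) if ri else 0)
            chrom = run_chrom[ri]
            s = int(run_start[ri]) + offset
            e = s + L
            if not allow_overlap and any(
                s < pe and ps < e for ps, pe in placed_by_chrom.get(chrom, [])
            ):
                continue
            placed.append((chrom, s, e))
            placed_by_chrom.setdefault(chrom, []).append((s, e))
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"could not place segment of length {L} after {max_tries} tries"
            )
    return placed


def _merge(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def overlap_count(segments: Sequence[Interval], features: Sequence[Interval]) -> int:
    """Features intersecting (>= 1 bp, half-open) at least one segment."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in segments:
        by_chrom.setdefault(chrom, []).append((s, e))
    for chrom in by_chrom:
        by_chrom[chrom] = _merge(by_chrom[chrom])
    count = 0
    for chrom, s, e in features:
        for ss, se in by_chrom.get(chrom, []):
            if s < se and ss < e:
                count += 1
                break
    return count


def base_overlap(segments: Sequence[Interval], features: Sequence[Interval]) -> int:
    """Bases in segments ∩ union(features); nothing is double counted."""
    seg_by_chrom: dict[str, list[tuple[int, int]]] = {}
    feat_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in segments:
        seg_by_chrom.setdefault(chrom, []).append((s, e))
    for chrom, s, e in features:
        feat_by_chrom.setdefault(chrom, []).append((s, e))
    total = 0
    for chrom, segs in seg_by_chrom.items():
        feats = _merge(feat_by_chrom.get(chrom, []))
        if not feats:
            continue
        fs = np.array([f[0] for f in feats])
        fe = np.array([f[1] for f in feats])
        for s, e in _merge(segs):
            total += int(np.sum(np.maximum(np.minimum(fe, e) - np.maximum(fs, s), 0)))
    return total


_STATISTICS = {"count": overlap_count, "bases": base_overlap}


@dataclass
class EnrichmentResult:
    observed: float
    null_draws: np.ndarray
    p_enriched: float
    p_depleted: float
    direction: str
    n_perm: int
    statistic: str
    seed: Optional[int] = None

    @property
    def p_value(self) -> float:
        return min(self.p_enriched, self.p_depleted)


def permutation_test(
    segments: Sequence[Interval],
    features: Sequence[Interval],
    genome: Mapping[str, int],
    excluded: Sequence[Interval] = (),
    statistic: str = "count",
    n_perm: int = 1000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> EnrichmentResult:
    """Empirical enrichment/depletion test with length-preserving shuffles.

    p_enriched = (1 + #{null >= observed}) / (n_perm + 1); the depletion
    tail uses <=.  Deterministic under a fixed seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    stat = _STATISTICS[statistic]
    rng = rng or np.random.default_rng(seed)
    observed = stat(segments, features)
    lengths = [e - s for _, s, e in segments]
    null = np.empty(n_perm)
    for i in range(n_perm):
        drawn = shuffle_segments(lengths, genome, excluded, rng)
        null[i] = stat(drawn, features)
    p_enr = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    p_dep = (1 + int(np.sum(null <= observed))) / (n_perm + 1)
    return EnrichmentResult(
        observed=float(observed),
        null_draws=null,
        p_enriched=p_enr,
        p_depleted=p_dep,
        direction="enriched" if p_enr <= p_dep else "depleted",
        n_perm=n_perm,
        statistic=statistic,
        seed=seed,
    )
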