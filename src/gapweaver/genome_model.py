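"""Assembly representation, gap detection, patch bookkeeping and contiguity metrics.

An :class:`Assembly` is a named, ordered collection of sequences partitioned
into chromosome scaffolds and unplaced contigs.  Gaps are maximal N-runs
within chromosome scaffolds.  All edits transforming one assembly version
into the next are recorded in a :class:`PatchLedger`, which also provides
coordinate liftover between versions.

Coordinates are 0-based half-open throughout; 1-based conventions appear
only at serialization boundaries that require them.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Union

log = logging.getLogger(__name__)

DEFAULT_UNPLACED_PATTERN = r"^(chrUn|scaffold)"

_GAP_FILL = "gap_fill"
_END_EXTENSION = "end_extension"
_VALID_KINDS = (_GAP_FILL, _END_EXTENSION)

_NON_ACGTN = re.compile(r"[^ACGTN]")


class CoordinateConflictError(ValueError):
    """Raised when ledger edits overlap on a chromosome."""


def clean_sequence(seq: str, name: str = "?") -> str:
    """Uppercase a nucleotide string; non-ACGTN symbols become N (warned)."""
    seq = seq.upper()
    n_bad = len(_NON_ACGTN.findall(seq))
    if n_bad:
        log.warning("%s: %d non-ACGTN symbols treated as N", name, n_bad)
        seq = _NON_ACGTN.sub("N", seq)
    return seq


@dataclass
class SequenceRecord:
    """One named sequence with its placement category."""

    name: str
    sequence: str
    category: str = "chromosome"  # or "unplaced"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.name}: empty sequence")
        if self.category not in ("chromosome", "unplaced"):
            raise ValueError(f"bad category {self.category!r}")

    def __len__(self) -> int:
        return len(self.sequence)


class Assembly:
    """Ordered mapping of sequence name -> :class:`SequenceRecord`."""

    def __init__(self, records: Iterable[SequenceRecord]):
        self._records: dict[str, SequenceRecord] = {}
        for rec in records:
            if rec.name in self._records:
                raise ValueError(f"duplicate sequence name {rec.name!r}")
            self._records[rec.name] = rec

    @classmethod
    def from_sequences(
        cls,
        sequences: Mapping[str, str],
        unplaced_pattern: str = DEFAULT_UNPLACED_PATTERN,
    ) -> "Assembly":
        pat = re.compile(unplaced_pattern)
        recs = []
        for name, seq in sequences.items():
            cat = "unplaced" if pat.search(name) else "chromosome"
            recs.append(SequenceRecord(name, clean_sequence(seq, name), cat))
        return cls(recs)

    @classmethod
    def from_fasta(
        cls,
        path: Union[str, Path],
        unplaced_pattern: str = DEFAULT_UNPLACED_PATTERN,
    ) -> "Assembly":
        from Bio import SeqIO

        seqs = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            seqs[rec.id] = str(rec.seq)
        return cls.from_sequences(seqs, unplaced_pattern)

    def write_fasta(self, path: Union[str, Path], width: int = 60) -> None:
        with open(path, "w") as fh:
            for rec in self:
                fh.write(f">{rec.name}\n")
                seq = rec.sequence
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, name: str) -> bool:
        return name in self._records

    def __getitem__(self, name: str) -> SequenceRecord:
        return self._records[name]

    def names(self) -> list[str]:
        return list(self._records)

    def chromosomes(self) -> list[SequenceRecord]:
        return [r for r in self if r.category == "chromosome"]

    def unplaced(self) -> list[SequenceRecord]:
        return [r for r in self if r.category == "unplaced"]

    def total_length(self, include_unplaced: bool = True) -> int:
        return sum(
            len(r) for r in self if include_unplaced or r.category == "chromosome"
        )

    def non_n_size(self, include_unplaced: bool = True) -> int:
        return sum(
            len(r) - r.sequence.count("N")
            for r in self
            if include_unplaced or r.category == "chromosome"
        )


@dataclass
class GapRecord:
    """A maximal N-run within a chromosome scaffold."""

    chrom: str
    start: int
    end: int
    status: str = "open"  # open | closed | partial
    fill_source: Optional[str] = None
    added_bases: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("gap end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def gap_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def find_gaps(assembly: Assembly, min_run: int = 1) -> list[GapRecord]:
    """Every maximal run of >= ``min_run`` consecutive N in chromosome scaffolds.

    Unplaced sequences are excluded.  Leading/trailing N-runs count as gaps.
    Result sorted by (chrom, start).
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    pat = re.compile("N{%d,}" % min_run)
    gaps = []
    for rec in assembly.chromosomes():
        for m in pat.finditer(rec.sequence):
            gaps.append(GapRecord(rec.name, m.start(), m.end()))
    gaps.sort(key=lambda g: (g.chrom, g.start))
    return gaps


@dataclass
class Edit:
    """One ledger edit: replace ``[start, end)`` of ``chrom`` by ``replacement``.

    End extensions are zero-length old intervals at a sequence terminus.
    """

    chrom: str
    start: int
    end: int
    replacement: str
    fill_source: Optional[str] = None
    kind: str = _GAP_FILL

    def __post_init__(self) -> None:
        if self.kind not in _VALID_KINDS:
            raise ValueError(f"bad edit kind {self.kind!r}")
        if self.end < self.start:
            raise ValueError("edit end before start")
        if self.kind == _GAP_FILL and self.end == self.start:
            raise ValueError("gap_fill edit needs a non-empty old interval")

    @property
    def net(self) -> int:
        return len(self.replacement) - (self.end - self.start)


@dataclass
class LiftedPosition:
    """Result of lifting one position across a ledger."""

    pos: Optional[int]
    inside_edit: bool = False
    new_interval: Optional[tuple[int, int]] = None


class PatchLedger:
    """Ordered, non-overlapping edits mapping an old assembly to a new one."""

    def __init__(self, edits: Iterable[Edit] = ()):
        self._edits: dict[str, list[Edit]] = {}
        for e in edits:
            self.add(e)

    def add(self, edit: Edit) -> None:
        chrom_edits = self._edits.setdefault(edit.chrom, [])
        for other in chrom_edits:
            if edit.start < other.end and other.start < edit.end:
                raise CoordinateConflictError(
                    f"{edit.chrom}: edit [{edit.start},{edit.end}) overlaps "
                    f"[{other.start},{other.end})"
                )
            # two zero-length insertions at the same point are also a conflict
            if (edit.start, edit.end) == (other.start, other.end):
                raise CoordinateConflictError(
                    f"{edit.chrom}: duplicate insertion point {edit.start}"
                )
        chrom_edits.append(edit)
        chrom_edits.sort(key=lambda e: (e.start, e.end))

    @property
    def edits(self) -> list[Edit]:
        return [e for chrom in sorted(self._edits) for e in self._edits[chrom]]

    def __len__(self) -> int:
        return sum(len(v) for v in self._edits.values())

    def chrom_edits(self, chrom: str) -> list[Edit]:
        return list(self._edits.get(chrom, []))

    def net_change(self, chrom: str) -> int:
        return sum(e.net for e in self._edits.get(chrom, []))

    def apply(self, assembly: Assembly) -> Assembly:
        new_records = []
        for rec in assembly:
            edits = self._edits.get(rec.name, [])
            if not edits:
                new_records.append(rec)
                continue
            pieces = []
            cursor = 0
            for e in edits:
                if e.end > len(rec):
                    raise ValueError(
                        f"{rec.name}: edit [{e.start},{e.end}) beyond length {len(rec)}"
                    )
                pieces.append(rec.sequence[cursor : e.start])
                pieces.append(e.replacement)
                cursor = e.end
            pieces.append(rec.sequence[cursor:])
            new_records.append(
                SequenceRecord(rec.name, "".join(pieces), rec.category)
            )
        return Assembly(new_records)

    def lift(self, chrom: str, pos: int) -> LiftedPosition:
        """Lift an old-assembly position to new-assembly coordinates.

        Positions inside a replaced interval return ``inside_edit`` with the
        enclosing new interval instead of a point.
        """
        if chrom not in self._edits and pos < 0:
            raise ValueError("negative position")
        edits = self._edits.get(chrom)
        if edits is None:
            raise KeyError(f"chromosome {chrom!r} not in ledger")
        shift = 0
        for e in edits:
            if pos >= e.end and not (e.start == e.end == pos):
                shift += e.net
                continue
            if e.start <= pos < e.end:
                new_start = e.start + shift
                return LiftedPosition(
                    None, True, (new_start, new_start + len(e.replacement))
                )
            break
        return LiftedPosition(pos + shift)

    def lift_back(self, chrom: str, new_pos: int) -> LiftedPosition:
        """Inverse liftover (new -> old) for positions outside edits."""
        edits = self._edits.get(chrom)
        if edits is None:
            raise KeyError(f"chromosome {chrom!r} not in ledger")
        shift = 0
        for e in edits:
            new_start = e.start + shift
            new_end = new_start + len(e.replacement)
            if new_pos >= new_end and not (new_start == new_end == new_pos):
                shift += e.net
                continue
            if new_start <= new_pos < new_end:
                return LiftedPosition(None, True, (e.start, e.end))
            break
        return LiftedPosition(new_pos - shift)

    def new_intervals(self, kind: Optional[str] = None) -> list[tuple[str, int, int, Edit]]:
        """New-assembly interval occupied by each edit's replacement."""
        out = []
        for chrom in sorted(self._edits):
            shift = 0
            for e in self._edits[chrom]:
                new_start = e.start + shift
                if kind is None or e.kind == kind:
                    out.append((chrom, new_start, new_start + len(e.replacement), e))
                shift += e.net
        return out

    # --- serialization: AGP-like TSV -------------------------------------
    _HEADER = (
        "chrom\told_start\told_end\tnew_start\tnew_end\tfill_source\tkind\treplacement\n"
    )

    def to_tsv(self, path: Union[str, Path], with_sequence: bool = True) -> None:
        """AGP-like TSV; the trailing ``replacement`` column makes the ledger
        self-contained so that ``apply`` works after a round-trip."""
        with open(path, "w") as fh:
            fh.write(self._HEADER)
            for chrom, ns, ne, e in self.new_intervals():
                seq = e.replacement if with_sequence else "*"
                fh.write(
                    f"{e.chrom}\t{e.start}\t{e.end}\t{ns}\t{ne}\t"
                    f"{e.fill_source or '.'}\t{e.kind}\t{seq}\n"
                )

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "PatchLedger":
        ledger = cls()
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("chrom\t"):
                raise ValueError("missing ledger header")
            for line in fh:
                f = line.rstrip("\n").split("\t")
                chrom, old_start, old_end = f[0], int(f[1]), int(f[2])
                new_start, new_end = int(f[3]), int(f[4])
                source = None if f[5] == "." else f[5]
                kind = f[6]
                seq = f[7] if len(f) > 7 and f[7] != "*" else "N" * (new_end - new_start)
                ledger.add(Edit(chrom, old_start, old_end, seq, source, kind))
        return ledger

    def closed_gaps_bed(self, path: Union[str, Path]) -> None:
        """BED of replacement intervals (new coordinates) for gap fills."""
        with open(path, "w") as fh:
            for chrom, ns, ne, e in self.new_intervals(kind=_GAP_FILL):
                fh.write(f"{chrom}\t{ns}\t{ne}\t{e.fill_source or '.'}\n")


def apply_patches(assembly: Assembly, ledger: PatchLedger) -> Assembly:
    """Apply all ledger edits, yielding the next assembly version."""
    return ledger.apply(assembly)


def lift_coordinates(ledger: PatchLedger, chrom: str, pos: int) -> LiftedPosition:
    return ledger.lift(chrom, pos)


@dataclass
class ContiguityMetrics:
    n_gaps: int
    contig_n50: int
    contig_n90: int
    l50: int
    l90: int
    assembly_size_no_n: int
    assembly_size_no_n_no_unplaced: int


def contig_lengths(assembly: Assembly, gaps: Iterable[GapRecord]) -> list[int]:
    """Lengths of gap-free segments of chromosome scaffolds."""
    by_chrom: dict[str, list[GapRecord]] = {}
    for g in gaps:
        by_chrom.setdefault(g.chrom, []).append(g)
    lengths = []
    for rec in assembly.chromosomes():
        cursor = 0
        for g in sorted(by_chrom.get(rec.name, []), key=lambda g: g.start):
            if g.start > cursor:
                lengths.append(g.start - cursor)
            cursor = g.end
        if len(rec) > cursor:
            lengths.append(len(rec) - cursor)
    return lengths


def _nx_lx(lengths: list[int], frac: float) -> tuple[int, int]:
    if not lengths:
        return 0, 0
    lengths = sorted(lengths, reverse=True)
    total = sum(lengths)
    cum = 0
    for i, L in enumerate(lengths, start=1):
        cum += L
        if cum >= frac * total:
            return L, i
    return lengths[-1], len(lengths)


def contiguity_metrics(assembly: Assembly, gaps: Iterable[GapRecord]) -> ContiguityMetrics:
    gaps = list(gaps)
    lengths = contig_lengths(assembly, gaps)
    n50, l50 = _nx_lx(lengths, 0.5)
    n90, l90 = _nx_lx(lengths, 0.9)
    return ContiguityMetrics(
        n_gaps=len(gaps),
        contig_n50=n50,
        contig_n90=n90,
        l50=l50,
        l90=l90,
        assembly_size_no_n=assembly.non_n_size(include_unplaced=True),
        assembly_size_no_n_no_unplaced=assembly.non_n_size(include_unplaced=False),
    )


def fold_change(metric_new: float, metric_old: float) -> float:
    """Ratio new/old reported to 2 decimals."""
    if metric_old <= 0:
        raise ValueError("fold_change denominator must be positive")
    return round(metric_new / metric_old, 2)


def percentage(part: float, whole: float, ndigits: int = 1) -> float:
    """part/whole as a percentage rounded to ``ndigits``."""
    if whole <= 0:
        raise ValueError("percentage denominator must be positive")
    return round(100.0 * part / whole, ndigits)


def to_mb(bp: float, ndigits: int = 2) -> float:
    """Base pairs -> megabases, rounded."""
    return round(bp / 1e6, ndigits)
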