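"""Genomic intervals, BED/bedGraph I/O, interval algebra, and peak-set comparison.

Coordinates are BED-style throughout: 0-based, half-open ``[start, end)``.
Histone-mark and TF peaks are unstranded, so no operation here consults strand.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .errors import InvalidParameterError, ParseError

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "PeakComparison",
    "SignalTrack",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "intersect",
    "compare_peak_sets",
    "merge_within",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional name and signal."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    signal: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise InvalidParameterError(f"negative start: {self}")
        if self.end <= self.start:
            raise InvalidParameterError(f"empty or inverted interval: {self}")
        if self.signal is not None and self.signal < 0:
            raise InvalidParameterError(f"negative signal: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class PeakSet:
    """An immutable, sorted collection of intervals (one peak call set)."""

    intervals: tuple
    label: str = ""

    def __post_init__(self) -> None:
        ivs = tuple(sorted(self.intervals, key=GenomicInterval.sort_key))
        object.__setattr__(self, "intervals", ivs)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def by_chrom(self) -> dict:
        out: dict = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval], label: str = "") -> "PeakSet":
        return cls(intervals=tuple(intervals), label=label)


@dataclass(frozen=True)
class PeakComparison:
    """Shared/specific decomposition of two peak sets (counts and percentages)."""

    shared: PeakSet
    a_specific: PeakSet
    b_specific: PeakSet
    counts: tuple  # (n_shared, n_a_specific, n_b_specific)
    percentages: tuple  # same order, % of the three-way total


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_bed(path, label: str = "") -> PeakSet:
    """Read a BED3+ file into a sorted :class:`PeakSet`.

    Column 5 (the BED score) is mapped to ``signal`` when it parses as a
    number; column 4 to ``name``. Malformed records raise :class:`ParseError`
    naming the offending line.
    """
    intervals = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns, got {len(fields)}")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            signal = None
            if len(fields) > 4:
                try:
                    signal = float(fields[4])
                except ValueError:
                    signal = None
            try:
                intervals.append(GenomicInterval(chrom, start, end, name, signal))
            except InvalidParameterError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet.from_intervals(intervals, label=label or str(path))


def write_bed(peaks: PeakSet, path) -> None:
    """Write a PeakSet as BED (BED6 when name/signal present, BED3 otherwise)."""
    with _open_text(path, "wt") as fh:
        for iv in peaks:
            if iv.name is None and iv.signal is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = iv.name if iv.name is not None else "."
                score = repr(iv.signal) if iv.signal is not None else "0"
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t.\n")


class SignalTrack:
    """Piecewise-constant per-base coverage, as read from a bedGraph.

    Stored per chromosome as parallel arrays (starts, ends, values); bases not
    covered by any record have value 0.
    """

    def __init__(self, records: dict):
        # records: chrom -> (starts, ends, values) numpy arrays sorted by start
        self._records = records

    @property
    def chroms(self):
        return set(self._records)

    def chrom_arrays(self, chrom: str):
        return self._records.get(chrom)

    @classmethod
    def from_intervals(cls, ivs: Sequence[tuple]) -> "SignalTrack":
        """Build from (chrom, start, end, value) tuples; overlapping records sum."""
        by_chrom: dict = {}
        for chrom, start, end, value in ivs:
            by_chrom.setdefault(chrom, []).append((start, end, value))
        records = {}
        for chrom, recs in by_chrom.items():
            recs.sort()
            starts = np.array([r[0] for r in recs], dtype=np.int64)
            ends = np.array([r[1] for r in recs], dtype=np.int64)
            values = np.array([r[2] for r in recs], dtype=float)
            records[chrom] = (starts, ends, values)
        return cls(records)

    def sum_over(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base values over ``[start, end)`` (uncovered bases are 0)."""
        arrs = self._records.get(chrom)
        if arrs is None:
            return 0.0
        starts, ends, values = arrs
        lo = np.maximum(starts, start)
        hi = np.minimum(ends, end)
        widths = np.clip(hi - lo, 0, None)
        return float(np.dot(widths, values))


def read_bedgraph(path) -> SignalTrack:
    """Read a 4-column bedGraph (chrom, start, end, value) into a SignalTrack."""
    recs = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed record") from exc
            if end <= start or start < 0:
                raise ParseError(f"{path}:{lineno}: invalid interval [{start},{end})")
            recs.append((chrom, start, end, value))
    return SignalTrack.from_intervals(recs)


def write_bedgraph(records: Iterable[tuple], path) -> None:
    """Write (chrom, start, end, value) records as bedGraph, sorted."""
    recs = sorted(records)
    with _open_text(path, "wt") as fh:
        for chrom, start, end, value in recs:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


def _overlap_any(iv: GenomicInterval, others: Sequence[GenomicInterval],
                 starts: np.ndarray, min_overlap_bp: int) -> bool:
    # others sorted by start on iv's chromosome
    hi = int(np.searchsorted(starts, iv.end - min_overlap_bp, side="right"))
    for other in others[:hi]:
        if min(iv.end, other.end) - max(iv.start, other.start) >= min_overlap_bp:
            return True
    return False


def _overlap_flags(a: PeakSet, b: PeakSet, min_overlap_bp: int) -> list:
    """For each member of a (in sorted order), whether it overlaps b by >= k bp."""
    b_by_chrom = b.by_chrom()
    b_starts = {c: np.array([iv.start for iv in ivs]) for c, ivs in b_by_chrom.items()}
    flags = []
    for iv in a:
        others = b_by_chrom.get(iv.chrom)
        if not others:
            flags.append(False)
            continue
        flags.append(_overlap_any(iv, others, b_starts[iv.chrom], min_overlap_bp))
    return flags


def intersect(a: PeakSet, b: PeakSet, min_overlap_bp: int = 1) -> PeakSet:
    """Members of ``a`` overlapping some member of ``b`` by >= ``min_overlap_bp``.

    Each member of ``a`` is reported at most once, in ``a``'s own coordinates.
    """
    if min_overlap_bp < 1:
        raise InvalidParameterError("min_overlap_bp must be >= 1")
    flags = _overlap_flags(a, b, min_overlap_bp)
    return PeakSet.from_intervals(
        (iv for iv, f in zip(a, flags) if f), label=a.label)


def compare_peak_sets(a: PeakSet, b: PeakSet) -> PeakComparison:
    """Shared/specific peak decomposition between two conditions.

    ``shared`` are members of ``a`` with >=1 bp overlap in ``b`` (reported in
    ``a``'s coordinates); ``a_specific``/``b_specific`` are the non-overlapping
    remainders. Percentages are over the three-way total count.
    """
    a_flags = _overlap_flags(a, b, 1)
    b_flags = _overlap_flags(b, a, 1)
    shared = PeakSet.from_intervals((iv for iv, f in zip(a, a_flags) if f), label="shared")
    a_spec = PeakSet.from_intervals((iv for iv, f in zip(a, a_flags) if not f),
                                    label=f"{a.label}_specific")
    b_spec = PeakSet.from_intervals((iv for iv, f in zip(b, b_flags) if not f),
                                    label=f"{b.label}_specific")
    counts = (len(shared), len(a_spec), len(b_spec))
    total = sum(counts)
    if total == 0:
        percentages = (0.0, 0.0, 0.0)
    else:
        percentages = tuple(100.0 * c / total for c in counts)
    return PeakComparison(shared, a_spec, b_spec, counts, percentages)


def merge_within(s: PeakSet, gap: int) -> PeakSet:
    """Transitively merge intervals whose inter-interval gap is <= ``gap`` bp.

    The gap between consecutive intervals is ``next.start - prev.end``; equal
    to ``gap`` still merges. Constituent names are concatenated with commas and
    signals summed.
    """
    if gap < 0:
        raise InvalidParameterError("gap must be >= 0")
    merged = []
    cur = None
    for iv in s:
        if cur is None:
            cur = iv
            continue
        if iv.chrom == cur.chrom and iv.start - cur.end <= gap:
            names = [n for n in (cur.name, iv.name) if n]
            sig = None
            if cur.signal is not None or iv.signal is not None:
                sig = (cur.signal or 0.0) + (iv.signal or 0.0)
            cur = GenomicInterval(cur.chrom, cur.start, max(cur.end, iv.end),
                                  ",".join(names) or None, sig)
        else:
            merged.append(cur)
            cur = iv
    if cur is not None:
        merged.append(cur)
    return PeakSet.from_intervals(merged, label=s.label)
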