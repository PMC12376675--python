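"""ROSE-style super-enhancer identification.

Enhancer peaks are stitched within a genomic gap (default 12 kb), quantified
against treatment (minus optional input control) coverage, rank-ordered by
ascending total signal, and split at the point where the rank/signal curve —
rescaled to the unit square — first reaches tangent slope 1 and stays at or
above it through the top rank. Elements with signal strictly above the signal
at that rank are super-enhancers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple
import warnings

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidParameterError
from .intervals import GenomicInterval, PeakSet, SignalTrack, merge_within

__all__ = [
    "StitchedEnhancer",
    "SECallResult",
    "quantify_signal",
    "stitch_and_rank",
    "inflection_cutoff",
    "call_superenhancers",
]


@dataclass
class StitchedEnhancer:
    """A merged cluster of enhancer peaks with its aggregate signal and rank."""

    span: GenomicInterval
    constituents: List[GenomicInterval]
    total_signal: float
    rank: int = 0  # 1-based, ascending signal
    is_super: bool = False


@dataclass
class SECallResult:
    enhancers: List[StitchedEnhancer]
    cutoff_signal: float
    cutoff_rank: int
    n_super: int
    scaling: Tuple[float, float]  # (x, y) scale factors applied to rank/signal

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.enhancers:
            rows.append({
                "chrom": e.span.chrom, "start": e.span.start, "end": e.span.end,
                "name": e.span.name or "", "n_constituents": len(e.constituents),
                "total_signal": e.total_signal, "rank": e.rank,
                "is_super": e.is_super,
            })
        return pd.DataFrame(rows)

    def super_peakset(self, label: str = "SE") -> PeakSet:
        return PeakSet.from_intervals(
            (e.span for e in self.enhancers if e.is_super), label=label)


def quantify_signal(span: GenomicInterval, treatment: SignalTrack,
                    control: Optional[SignalTrack] = None, *,
                    strict: bool = False) -> float:
    """Sum of per-base (treatment - control) over the span, floored at 0.

    Bases not covered by a track count as 0. With ``strict`` on, a span on a
    chromosome absent from the treatment track raises a lookup error.
    """
    if strict and span.chrom not in treatment.chroms:
        raise KeyError(f"chromosome {span.chrom!r} not in treatment track")
    total = treatment.sum_over(span.chrom, span.start, span.end)
    if control is not None:
        total -= control.sum_over(span.chrom, span.start, span.end)
    return max(0.0, total)


def _tss_windows(annotation: pd.DataFrame, window: int) -> PeakSet:
    ivs = []
    for row in annotation.itertuples():
        start = max(0, int(row.tss) - window)
        ivs.append(GenomicInterval(row.chrom, start, int(row.tss) + window, row.gene))
    return PeakSet.from_intervals(ivs)


def stitch_and_rank(peaks: PeakSet, treatment: SignalTrack,
                    control: Optional[SignalTrack] = None, gap: int = 12_000,
                    tss_exclusion: Optional[Tuple[pd.DataFrame, int]] = None,
                    ) -> List[StitchedEnhancer]:
    """Stitch peaks within ``gap`` bp and rank stitched elements by signal.

    With ``tss_exclusion = (annotation, window)``, peaks falling entirely
    inside some TSS +/- window are removed before stitching. Each stitched
    element's ``total_signal`` is the sum of its constituents' quantified
    signals; ranks are 1-based ascending by (signal, then genomic position).
    """
    if gap < 0:
        raise InvalidParameterError("gap must be >= 0")
    constituents = list(peaks)
    if tss_exclusion is not None:
        annotation, window = tss_exclusion
        windows = _tss_windows(annotation, window)
        by_chrom = windows.by_chrom()
        kept = []
        for iv in constituents:
            inside = any(w.start <= iv.start and iv.end <= w.end
                         for w in by_chrom.get(iv.chrom, ()))
            if not inside:
                kept.append(iv)
        constituents = kept
    if not constituents:
        warnings.warn("all peaks removed before stitching; empty result")
        return []

    merged = merge_within(PeakSet.from_intervals(constituents), gap)
    cons_by_chrom = PeakSet.from_intervals(constituents).by_chrom()
    enhancers = []
    for span in merged:
        members = [c for c in cons_by_chrom.get(span.chrom, ())
                   if span.start <= c.start and c.end <= span.end]
        total = sum(quantify_signal(c, treatment, control) for c in members)
        enhancers.append(StitchedEnhancer(span=span, constituents=members,
                                          total_signal=total))
    order = sorted(range(len(enhancers)),
                   key=lambda i: (enhancers[i].total_signal,
                                  enhancers[i].span.sort_key()))
    for rank, i in enumerate(order, start=1):
        enhancers[i].rank = rank
    enhancers.sort(key=lambda e: e.rank)
    return enhancers


def inflection_cutoff(signals: Sequence[float]) -> Tuple[float, int]:
    """Locate the slope-1 inflection on the ascending rank/signal curve.

    ``signals`` must be sorted ascending. Ranks and signals are rescaled to
    the unit square (x = rank/n, y = signal/max). The discrete tangent slope
    at each rank uses a symmetric difference over a 3-point window (one-sided
    at the ends). Returns ``(cutoff_signal, cutoff_rank)`` where
    ``cutoff_rank`` is the smallest 1-based rank at which the slope reaches
    >= 1 and stays >= 1 through the top rank. Elements with signal strictly
    above ``cutoff_signal`` are super-enhancers.
    """
    y = np.asarray(signals, dtype=float)
    n = y.size
    if n < 3:
        raise InvalidParameterError("need at least 3 signals")
    if np.any(np.diff(y) < 0):
        raise InvalidParameterError("signals must be sorted ascending")
    ymax = y[-1]
    if ymax <= 0:
        raise DegenerateInputError("all signals are zero")
    ys = y / ymax
    xs = np.arange(1, n + 1, dtype=float) / n
    slopes = np.empty(n)
    slopes[1:-1] = (ys[2:] - ys[:-2]) / (xs[2:] - xs[:-2])
    slopes[0] = (ys[1] - ys[0]) / (xs[1] - xs[0])
    slopes[-1] = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
    ok = slopes >= 1.0
    # smallest rank from which the slope condition holds through the top
    suffix_ok = np.logical_and.accumulate(ok[::-1])[::-1]
    idx = np.flatnonzero(suffix_ok)
    cut = int(idx[0]) if idx.size else n - 1
    return float(y[cut]), cut + 1


def call_superenhancers(peaks: PeakSet, treatment: SignalTrack,
                        control: Optional[SignalTrack] = None,
                        gap: int = 12_000,
                        tss_exclusion: Optional[Tuple[pd.DataFrame, int]] = None,
                        ) -> SECallResult:
    """Full SE call: stitch, quantify, rank, and apply the inflection cutoff."""
    enhancers = stitch_and_rank(peaks, treatment, control, gap, tss_exclusion)
    if len(enhancers) < 3:
        raise InvalidParameterError("need at least 3 stitched elements to call SEs")
    signals = [e.total_signal for e in enhancers]
    cutoff_signal, cutoff_rank = inflection_cutoff(signals)
    n_super = 0
    for e in enhancers:
        e.is_super = e.total_signal > cutoff_signal
        n_super += e.is_super
    ymax = max(signals)
    return SECallResult(enhancers=enhancers, cutoff_signal=cutoff_signal,
                        cutoff_rank=cutoff_rank, n_super=n_super,
                        scaling=(1.0 / len(enhancers), 1.0 / ymax))
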