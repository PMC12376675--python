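"""Regulatory-element classification, TF co-binding stratification, and motifs.

H3K27ac regions are classified as promoters (H3K4me3 co-occupancy AND a
strand-aware TSS window hit) or enhancers (H3K4me1 co-occupancy); regions
carrying neither mark are dropped. Elements are then stratified by how many
of the three circuit TFs bind them (trio / dual / solo / none), linked to
gene expression, and scored for super-enhancer overlap. A small PWM scanner
supports the motif-span statistic: the tightest window in a co-bound region
containing one motif hit of each TF.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError
from .intervals import GenomicInterval, PeakSet, intersect

__all__ = [
    "RegulatoryElement",
    "GroupSummary",
    "classify_elements",
    "stratify_cobinding",
    "group_expression_summary",
    "motif_scan",
    "motif_span",
    "read_pwm",
]

GROUP_ORDER = ("trio", "dual", "solo", "none")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class RegulatoryElement:
    """An H3K27ac region with its kind, assigned gene, and binding pattern."""

    span: GenomicInterval
    kind: str  # "promoter" | "enhancer"
    gene: str
    tss_distance: int  # signed bp, negative = upstream of the TSS
    bound_by: Tuple[str, ...] = ()
    group: str = "none"
    se_overlap: bool = False


@dataclass
class GroupSummary:
    """Per-(kind, group) expression and SE-overlap summary."""

    kind: str
    group: str
    n_elements: int
    genes: List[str]
    expr_values: np.ndarray  # per-gene mean expression over the stated samples
    se_overlap_fraction: float
    test_skipped: bool = False


def _group_of(bound_by: Sequence[str]) -> str:
    return {3: "trio", 2: "dual", 1: "solo"}.get(len(bound_by), "none")


def classify_elements(h3k27ac: PeakSet, h3k4me3: PeakSet, h3k4me1: PeakSet,
                      annotation: pd.DataFrame,
                      promoter_window: Tuple[int, int] = (1000, 100),
                      ) -> List[RegulatoryElement]:
    """Classify H3K27ac regions into promoters/enhancers and assign genes.

    A region is a promoter when it overlaps H3K4me3 and some strand-aware TSS
    window [TSS - upstream, TSS + downstream]; otherwise an enhancer when it
    overlaps H3K4me1; regions overlapping neither mark are dropped. Promoter
    takes precedence over enhancer. Each kept region is assigned the gene of
    the nearest TSS by region midpoint, with a signed distance (negative =
    upstream of the TSS in the gene's orientation); distance ties break by
    gene name.
    """
    if annotation.empty:
        raise InvalidParameterError("annotation table is empty")
    upstream, downstream = promoter_window
    tss_ivs = []
    for row in annotation.itertuples():
        tss = int(row.tss)
        if row.strand == "+":
            lo, hi = tss - upstream, tss + downstream
        else:
            lo, hi = tss - downstream, tss + upstream
        tss_ivs.append(GenomicInterval(str(row.chrom), max(0, lo), max(1, hi),
                                       str(row.gene)))
    tss_windows = PeakSet.from_intervals(tss_ivs)

    me3_hits = {iv.sort_key() for iv in intersect(h3k27ac, h3k4me3)}
    me1_hits = {iv.sort_key() for iv in intersect(h3k27ac, h3k4me1)}
    win_hits = {iv.sort_key() for iv in intersect(h3k27ac, tss_windows)}

    # nearest-TSS lookup per chromosome
    ann_sorted = annotation.sort_values(["chrom", "tss", "gene"])
    by_chrom: Dict[str, Tuple[np.ndarray, list, list]] = {}
    for chrom, sub in ann_sorted.groupby("chrom", sort=False):
        by_chrom[str(chrom)] = (sub["tss"].to_numpy(dtype=float),
                                sub["gene"].tolist(), sub["strand"].tolist())

    elements: List[RegulatoryElement] = []
    for iv in h3k27ac:
        key = iv.sort_key()
        if key in me3_hits and key in win_hits:
            kind = "promoter"
        elif key in me1_hits:
            kind = "enhancer"
        else:
            continue
        chrom_ann = by_chrom.get(iv.chrom)
        if chrom_ann is None:
            continue
        tss_arr, gene_list, strand_list = chrom_ann
        mid = iv.midpoint
        dists = np.abs(tss_arr - mid)
        best = np.flatnonzero(dists == dists.min())
        # distance ties break by gene name
        j = min(best, key=lambda k: gene_list[k])
        signed = mid - tss_arr[j]
        if strand_list[j] == "-":
            signed = -signed
        elements.append(RegulatoryElement(span=iv, kind=kind,
                                          gene=gene_list[j],
                                          tss_distance=int(round(signed))))
    return elements


def stratify_cobinding(elements: List[RegulatoryElement],
                       tf_peaks: Dict[str, PeakSet],
                       ) -> List[RegulatoryElement]:
    """Fill ``bound_by``/``group`` from >= 1 bp overlap with each TF peak set."""
    if len(tf_peaks) != 3:
        raise InvalidParameterError("exactly three TF peak sets are required")
    spans = PeakSet.from_intervals([el.span for el in elements])
    hit_keys = {tf: {iv.sort_key() for iv in intersect(spans, peaks)}
                for tf, peaks in tf_peaks.items()}
    for el in elements:
        key = el.span.sort_key()
        el.bound_by = tuple(tf for tf in tf_peaks if key in hit_keys[tf])
        el.group = _group_of(el.bound_by)
    return elements


def group_expression_summary(elements: List[RegulatoryElement],
                             expr: pd.DataFrame, samples: Sequence[str],
                             se_peaks: Optional[PeakSet] = None,
                             ) -> Tuple[List[GroupSummary], pd.DataFrame]:
    """Per-(kind, group) expression summary with pairwise Welch tests.

    ``expr`` is a gene x sample expression matrix (FPKM); each group's value
    set is the per-gene mean over ``samples`` of log2(expr + 1) for the genes
    its elements target (deduplicated). Pairwise groups are compared with
    Welch's t (one row per ordered pair, statistic for first > second);
    groups with fewer than 2 genes are flagged skipped. When ``se_peaks`` is
    given, each summary carries the fraction of the group's elements
    overlapping a super-enhancer.

    Returns ``(summaries, pairwise_tests)``.
    """
    missing = sorted({el.gene for el in elements} - set(expr.index))
    if missing:
        import warnings
        warnings.warn(f"{len(missing)} element gene(s) absent from expression "
                      f"matrix, e.g. {missing[:3]}; dropped")
    mean_log = np.log2(expr.loc[:, list(samples)] + 1.0).mean(axis=1)

    if se_peaks is not None and len(elements):
        spans = PeakSet.from_intervals([el.span for el in elements])
        se_keys = {iv.sort_key() for iv in intersect(spans, se_peaks)}
        for el in elements:
            el.se_overlap = el.span.sort_key() in se_keys

    summaries: List[GroupSummary] = []
    for kind in ("promoter", "enhancer"):
        for group in GROUP_ORDER:
            members = [el for el in elements
                       if el.kind == kind and el.group == group]
            genes = sorted({el.gene for el in members} & set(expr.index))
            values = mean_log.loc[genes].to_numpy() if genes else np.array([])
            frac = (float(np.mean([el.se_overlap for el in members]))
                    if members else 0.0)
            summaries.append(GroupSummary(
                kind=kind, group=group, n_elements=len(members), genes=genes,
                expr_values=values, se_overlap_fraction=frac,
                test_skipped=len(genes) < 2))

    rows = []
    for kind in ("promoter", "enhancer"):
        per_kind = {s.group: s for s in summaries if s.kind == kind}
        for g1, g2 in itertools.combinations(GROUP_ORDER, 2):
            s1, s2 = per_kind[g1], per_kind[g2]
            if s1.test_skipped or s2.test_skipped:
                rows.append({"kind": kind, "group1": g1, "group2": g2,
                             "t": np.nan, "p": np.nan, "skipped": True})
                continue
            t, p = stats.ttest_ind(s1.expr_values, s2.expr_values,
                                   equal_var=False)
            rows.append({"kind": kind, "group1": g1, "group2": g2,
                         "t": float(t), "p": float(p), "skipped": False})
    return summaries, pd.DataFrame(rows)


def read_pwm(path) -> np.ndarray:
    """Read a 4 x L count/probability matrix (rows A, C, G, T) from TSV."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    mat = df.to_numpy(dtype=float)
    if mat.shape[0] != 4:
        if mat.shape[1] == 4:
            mat = mat.T
        else:
            raise InvalidParameterError("PWM must be 4 x L (rows A, C, G, T)")
    return mat / mat.sum(axis=0, keepdims=True)


def motif_scan(sequence: str, pwm: np.ndarray,
               background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
               score_threshold: float = 6.0,
               pseudocount: float = 1e-3,
               ) -> List[Tuple[int, str, float]]:
    """Log2-odds PWM scan of both strands; hits are (offset, strand, score).

    The PWM is a 4 x L probability matrix (rows A, C, G, T; columns sum to
    1). A pseudocount is mixed in before taking log-odds against the
    background. Non-ACGT characters score as background (zero log-odds
    contribution) rather than erroring. Offsets are 0-based positions of the
    motif's leftmost base on the forward strand, for both strand hits.
    """
    pwm = np.asarray(pwm, dtype=float)
    if pwm.shape[0] != 4:
        raise InvalidParameterError("PWM must be 4 x L")
    if not np.allclose(pwm.sum(axis=0), 1.0, atol=1e-6):
        raise InvalidParameterError("PWM columns must sum to 1")
    bg = np.asarray(background, dtype=float)
    bg = bg / bg.sum()
    L = pwm.shape[1]
    seq = sequence.upper()
    if len(seq) < L:
        raise InvalidParameterError("sequence shorter than motif")
    p = (pwm + pseudocount) / (1.0 + 4.0 * pseudocount)
    logodds = np.log2(p / bg[:, None])  # 4 x L

    idx = np.array([_BASE_INDEX.get(c, -1) for c in seq])
    n_off = len(seq) - L + 1
    # window matrix of base indices; -1 (N policy) contributes 0
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    valid = windows >= 0
    safe = np.where(valid, windows, 0)
    fwd = np.where(valid, logodds[safe, np.arange(L)], 0.0).sum(axis=1)

    rc = seq.translate(_COMPLEMENT)[::-1]
    idx_rc = np.array([_BASE_INDEX.get(c, -1) for c in rc])
    windows_rc = np.lib.stride_tricks.sliding_window_view(idx_rc, L)
    valid_rc = windows_rc >= 0
    safe_rc = np.where(valid_rc, windows_rc, 0)
    rev = np.where(valid_rc, logodds[safe_rc, np.arange(L)], 0.0).sum(axis=1)

    hits: List[Tuple[int, str, float]] = []
    for off in range(n_off):
        if fwd[off] >= score_threshold:
            hits.append((off, "+", float(fwd[off])))
        # offset on the reverse-complement maps to forward-strand position
        rc_off = len(seq) - L - off
        if rev[rc_off] >= score_threshold:
            hits.append((off, "-", float(rev[rc_off])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def motif_span(hits_per_tf: Dict[str, List[Tuple[int, str, float]]],
               motif_lengths: Dict[str, int]) -> Optional[int]:
    """Minimal bp span containing >= 1 motif hit of each TF, or None.

    Each hit is (offset, strand, score); a hit occupies
    [offset, offset + motif_length). The span of a triple is max end - min
    start; the minimum over all one-hit-per-TF combinations is returned,
    None when any TF has no hit.
    """
    tfs = list(hits_per_tf)
    if any(not hits_per_tf[tf] for tf in tfs):
        return None
    best = None
    ranges = [[(off, off + motif_lengths[tf]) for off, _, _ in hits_per_tf[tf]]
              for tf in tfs]
    for combo in itertools.product(*ranges):
        span = max(e for _, e in combo) - min(s for s, _ in combo)
        if best is None or span < best:
            best = span
    return best
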