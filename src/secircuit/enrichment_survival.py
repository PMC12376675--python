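"""Preranked GSEA, single-sample GSEA scoring, and survival cutpoint analysis.

The enrichment side implements the classic weighted Kolmogorov-Smirnov
running sum for a preranked gene list (with a gene-label permutation null)
and a per-sample rank-weighted ECDF-difference signature score (ssGSEA). The
survival side finds the score cutpoint maximizing the standardized two-group
log-rank statistic over all admissible splits (maximally selected rank
statistic) with a selection-adjusted permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InvalidParameterError

__all__ = [
    "ESResult",
    "CutpointResult",
    "preranked_es",
    "preranked_gsea",
    "ssgsea_score",
    "maxstat_cutpoint",
    "logrank",
    "read_gmt",
]


@dataclass
class ESResult:
    es: float
    nes: float  # NaN when the same-sign permutation null is empty
    p: float
    n_perm: int
    weight_p: float


@dataclass
class CutpointResult:
    cutpoint: float
    max_stat: float  # standardized log-rank statistic at the cutpoint
    p: float  # selection-adjusted (permutation); NaN if not requested
    groups: pd.Series  # sample -> "high" | "low"


def read_gmt(path) -> Dict[str, List[str]]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def _validate_ranked(genes: Sequence[str], scores: np.ndarray,
                     gene_set: Set[str]) -> np.ndarray:
    if len(set(genes)) != len(genes):
        raise InvalidParameterError("ranked list contains duplicate genes")
    if not np.all(np.isfinite(scores)):
        raise InvalidParameterError("scores must be finite")
    in_set = np.array([g in gene_set for g in genes])
    k = int(in_set.sum())
    if k == 0 or k == len(genes):
        raise InvalidParameterError(
            "gene set must be a non-empty strict subset of the ranked genes")
    return in_set


def _es_from_order(scores_desc: np.ndarray, in_set: np.ndarray,
                   weight_p: float) -> float:
    """Signed maximum deviation of the weighted KS running sum."""
    w = np.abs(scores_desc) ** weight_p
    hit_w = np.where(in_set, w, 0.0)
    total_hit = hit_w.sum()
    n_miss = in_set.size - int(in_set.sum())
    if total_hit == 0:
        # all hit scores are zero at this weighting: fall back to unweighted
        hit_w = in_set.astype(float)
        total_hit = hit_w.sum()
    running = np.cumsum(hit_w / total_hit - np.where(in_set, 0.0, 1.0 / n_miss))
    return float(running[np.argmax(np.abs(running))])


def preranked_es(genes: Sequence[str], scores: Sequence[float],
                 gene_set: Sequence[str], weight_p: float = 1.0) -> float:
    """Enrichment score of ``gene_set`` in a score-ranked gene list.

    ``genes``/``scores`` need not be pre-sorted; genes are ordered by score
    descending (ties broken by input order). At each hit the running sum
    gains |score|^weight_p normalized by the in-set total; at each miss it
    loses 1/(N - k). The ES is the running sum's signed maximum deviation.
    """
    scores = np.asarray(scores, dtype=float)
    gene_set = set(gene_set)
    in_set = _validate_ranked(genes, scores, gene_set)
    order = np.argsort(-scores, kind="stable")
    return _es_from_order(scores[order], in_set[order], weight_p)


def preranked_gsea(genes: Sequence[str], scores: Sequence[float],
                   gene_set: Sequence[str], n_perm: int = 999,
                   seed: int = 0, weight_p: float = 1.0) -> ESResult:
    """Preranked GSEA with a gene-label permutation null.

    p = (1 + #{|ES_perm| >= |ES|}) / (n_perm + 1); NES divides the observed
    ES by the mean |ES_perm| of permutations sharing its sign (NaN when that
    null side is empty).
    """
    if n_perm < 100:
        raise InvalidParameterError("n_perm must be >= 100")
    scores = np.asarray(scores, dtype=float)
    gene_set = set(gene_set)
    in_set = _validate_ranked(genes, scores, gene_set)
    order = np.argsort(-scores, kind="stable")
    scores_desc, in_set_desc = scores[order], in_set[order]
    es = _es_from_order(scores_desc, in_set_desc, weight_p)

    rng = np.random.default_rng(seed)
    perm_es = np.empty(n_perm)
    membership = in_set_desc.copy()
    for i in range(n_perm):
        rng.shuffle(membership)  # permute gene labels = random set of size k
        perm_es[i] = _es_from_order(scores_desc, membership, weight_p)
    p = (1.0 + np.sum(np.abs(perm_es) >= abs(es))) / (n_perm + 1.0)
    same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
    nes = es / np.mean(np.abs(same_sign)) if same_sign.size else float("nan")
    return ESResult(es=es, nes=float(nes), p=float(p), n_perm=n_perm,
                    weight_p=weight_p)


def ssgsea_score(expr_sample: pd.Series, gene_set: Sequence[str],
                 alpha: float = 0.25) -> float:
    """Single-sample signature score from rank-weighted ECDF differences.

    Genes are ordered by expression descending; ties receive average ranks.
    Walking down the list, the in-set ECDF steps by rank^alpha (normalized)
    at hits and the out-of-set ECDF by 1/(N - k) at misses; the raw score is
    the sum of their differences over all positions, normalized by the
    magnitude attained if the set occupied the top |set| positions — so the
    score lies in [-1, 1] and is comparable across samples.
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise InvalidParameterError("gene set is empty")
    values = expr_sample.to_numpy(dtype=float)
    genes = list(expr_sample.index)
    in_set = _validate_ranked(genes, values, gene_set)
    n = values.size
    k = int(in_set.sum())
    ranks = stats.rankdata(values)  # 1 = lowest expression, average ties
    order = np.argsort(-values, kind="stable")
    in_set_desc = in_set[order]
    w = ranks[order] ** alpha
    hit_w = np.where(in_set_desc, w, 0.0)
    ecdf_hit = np.cumsum(hit_w) / hit_w.sum()
    ecdf_miss = np.cumsum(~in_set_desc) / (n - k)
    raw = float(np.sum(ecdf_hit - ecdf_miss))

    # best case: the set occupies the top k positions with ranks n..n-k+1
    best_w = np.zeros(n)
    best_w[:k] = np.arange(n, n - k, -1) ** alpha
    best_hit = np.cumsum(best_w) / best_w.sum()
    best_miss = np.cumsum(np.arange(n) >= k) / (n - k)
    norm = float(np.sum(best_hit - best_miss))
    return raw / norm


def _logrank_scan(times: np.ndarray, events: np.ndarray,
                  groups: np.ndarray) -> np.ndarray:
    """Standardized log-rank statistics for K group assignments at once.

    ``groups`` is a K x n boolean matrix (True = in group 1). Returns the K
    statistics (O - E)/sqrt(V) with hypergeometric variance; 0 where V = 0.
    """
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order].astype(float)
    g = groups[:, order].astype(float)
    n = t.size
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    n_at_risk = (n - starts).astype(float)
    d = np.add.reduceat(e, starts)
    d1 = np.add.reduceat(g * e, starts, axis=1)
    suffix = np.cumsum(g[:, ::-1], axis=1)[:, ::-1]
    n1 = suffix[:, starts]
    has_event = d > 0
    nb, db = n_at_risk[has_event], d[has_event]
    frac = n1[:, has_event] / nb
    oe = (d1[:, has_event] - db * frac).sum(axis=1)
    denom = np.maximum(nb - 1.0, 1.0)
    var = (db * frac * (1.0 - frac) * (nb - db) / denom).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(var > 0, oe / np.sqrt(var), 0.0)
    return stat


def logrank(times: Sequence[float], events: Sequence[int],
            group_labels: Sequence) -> Tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, p from chi2, 1 df)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.asarray(group_labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise InvalidParameterError(f"need exactly 2 groups, got {uniq.size}")
    if events.sum() < 1:
        raise InvalidParameterError("need at least one event")
    g = (labels == uniq[0])[None, :]
    stat = _logrank_scan(times, events, g)[0]
    chi2 = float(stat ** 2)
    return chi2, float(stats.chi2.sf(chi2, df=1))


def maxstat_cutpoint(scores: Sequence[float], times: Sequence[float],
                     events: Sequence[int],
                     band: Tuple[float, float] = (0.10, 0.90),
                     p_method: str = "permutation", n_perm: int = 999,
                     seed: int = 0) -> CutpointResult:
    """Maximally selected log-rank statistic over candidate score cutpoints.

    Candidates are observed score values within the [q_lo, q_hi] quantile
    band that leave both groups (score > c vs score <= c) non-empty. The
    cutpoint maximizes |standardized log-rank statistic|; its p-value is the
    permutation tail probability of that maximum under random score-to-
    outcome assignment (the selection-adjusted p, not the naive log-rank p).
    """
    scores_s = pd.Series(scores)
    scores = scores_s.to_numpy(dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if scores.size < 10:
        raise InvalidParameterError("need n >= 10")
    if events.sum() < 1:
        raise InvalidParameterError("need at least one event")
    if np.ptp(scores) == 0:
        raise DegenerateInputError("all scores equal")
    q_lo, q_hi = np.quantile(scores, band)
    uniq = np.unique(scores)
    candidates = np.array([c for c in uniq[:-1] if q_lo <= c <= q_hi])
    if candidates.size == 0:
        raise InvalidParameterError("no admissible cutpoint inside the band")

    def max_scan(s: np.ndarray) -> Tuple[float, float]:
        groups = s[None, :] > candidates[:, None]
        stat = _logrank_scan(times, events, groups)
        i = int(np.argmax(np.abs(stat)))
        return float(candidates[i]), float(stat[i])

    cutpoint, stat = max_scan(scores)
    p = float("nan")
    if p_method == "permutation":
        rng = np.random.default_rng(seed)
        obs = abs(stat)
        exceed = 0
        s_perm = scores.copy()
        for _ in range(n_perm):
            rng.shuffle(s_perm)
            _, st = max_scan(s_perm)
            exceed += abs(st) >= obs
        p = (1.0 + exceed) / (n_perm + 1.0)
    elif p_method != "none":
        raise InvalidParameterError(f"unknown p_method {p_method!r}")
    groups = pd.Series(np.where(scores > cutpoint, "high", "low"),
                       index=scores_s.index)
    return CutpointResult(cutpoint=cutpoint, max_stat=stat, p=p, groups=groups)
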