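"""Expression normalization and a simplified differential-expression test.

FPKM is the normalization the rest of the pipeline consumes. The built-in DE
engine is a deliberately simple stand-in — Welch's t on log2(FPKM + c) with
Benjamini-Hochberg adjustment — honoring the |log2FC| > 0.584 and p < 0.05
call thresholds; externally produced DE tables with the same columns can be
imported instead via :func:`read_de_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidParameterError, ParseError

__all__ = [
    "ExpressionMatrix",
    "fpkm",
    "differential_expression",
    "bh_adjust",
    "read_counts",
    "read_de_table",
]

LFC_THRESHOLD = 0.584  # |log2 FC| call threshold (~1.5-fold)
P_THRESHOLD = 0.05


@dataclass
class ExpressionMatrix:
    """Gene x sample counts with gene lengths and derived FPKM."""

    counts: pd.DataFrame  # genes x samples, non-negative
    lengths: pd.Series  # bp, aligned to counts index

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.lengths.index):
            self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()][:5].tolist()
            raise InvalidParameterError(f"genes missing lengths, e.g. {missing}")
        if (self.lengths <= 0).any():
            raise InvalidParameterError("gene lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise InvalidParameterError("counts must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def fpkm(self) -> pd.DataFrame:
        return fpkm(self.counts, self.lengths)


def fpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """FPKM: counts * 1e9 / (library size * gene length in bp)."""
    lengths = lengths.reindex(counts.index)
    libsize = counts.sum(axis=0)
    zero = libsize[libsize <= 0]
    if len(zero):
        raise InvalidParameterError(f"zero library size in sample(s) {list(zero.index)}")
    return counts * 1e9 / libsize / lengths.to_numpy()[:, None]


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped to <= 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(expr: ExpressionMatrix, group_a: Sequence[str],
                            group_b: Sequence[str],
                            lfc_threshold: float = LFC_THRESHOLD,
                            p_threshold: float = P_THRESHOLD,
                            pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene B-vs-A differential expression on log2(FPKM + pseudocount).

    log2fc is the difference of group means of log2(FPKM + c); p comes from
    Welch's unequal-variance t-test on the same values, q from BH. ``call``
    is ``up`` when log2fc > lfc_threshold and p < p_threshold, ``down`` for
    the mirrored condition, else ``ns``. Genes constant across both groups
    get p = 1.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise InvalidParameterError("need >= 2 samples per group")
    missing = [s for s in group_a + group_b if s not in expr.samples]
    if missing:
        raise InvalidParameterError(f"unknown sample(s) {missing}")
    f = expr.fpkm
    la = np.log2(f[group_a].to_numpy() + pseudocount)
    lb = np.log2(f[group_b].to_numpy() + pseudocount)
    log2fc = lb.mean(axis=1) - la.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    q = bh_adjust(p)
    call = np.where((log2fc > lfc_threshold) & (p < p_threshold), "up",
                    np.where((log2fc < -lfc_threshold) & (p < p_threshold),
                             "down", "ns"))
    return pd.DataFrame({"gene": expr.genes, "log2fc": log2fc, "p": p,
                         "q": q, "call": call}).set_index("gene")


def read_counts(counts_path, lengths_path) -> ExpressionMatrix:
    """Read TSV counts (gene x sample, first column gene) and gene lengths."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    return ExpressionMatrix(counts=counts, lengths=lengths)


def read_de_table(path, lfc_threshold: float = LFC_THRESHOLD,
                  p_threshold: float = P_THRESHOLD) -> pd.DataFrame:
    """Import an externally produced DE table (gene, log2fc, p [, q, call]).

    Missing q/call columns are derived with the same rules as the built-in
    engine, so downstream stages see one schema regardless of the DE source.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "log2fc", "p"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: DE table needs columns {sorted(required)}")
    df = df.set_index("gene")
    if "q" not in df.columns:
        df["q"] = bh_adjust(df["p"].to_numpy())
    if "call" not in df.columns:
        df["call"] = np.where(
            (df["log2fc"] > lfc_threshold) & (df["p"] < p_threshold), "up",
            np.where((df["log2fc"] < -lfc_threshold) & (df["p"] < p_threshold),
                     "down", "ns"))
    return df
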