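"""Nomination of SE-driven transcription-factor circuits.

Candidate TFs are genes that are (i) driven by a called super-enhancer,
(ii) upregulated in the resistant condition, and (iii) members of a TF
catalog. Their pairwise Pearson correlations across patient-like samples
form a network; candidate circuits are maximal cliques whose every edge has
r >= r_min and p <= p_max — an explicit, reproducible formalization of
reading a mutually correlated TF block off a correlation heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InvalidParameterError

__all__ = [
    "CandidateTF",
    "CorrelationNetwork",
    "CandidateCircuit",
    "select_candidates",
    "pearson",
    "build_network",
    "nominate_circuits",
]


@dataclass(frozen=True)
class CandidateTF:
    gene: str
    is_se_associated: bool
    de_call: str  # "up" | "down" | "ns"
    in_tf_catalog: bool

    @property
    def is_candidate(self) -> bool:
        return self.is_se_associated and self.de_call == "up" and self.in_tf_catalog


@dataclass
class CorrelationNetwork:
    """Symmetric pairwise Pearson network over candidate genes."""

    nodes: List[str]
    edges: Dict[Tuple[str, str], Tuple[float, float, int]]  # (r, p, n)

    def edge(self, a: str, b: str) -> Tuple[float, float, int]:
        return self.edges[(a, b) if a < b else (b, a)]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"gene1": a, "gene2": b, "r": r, "p": p, "n": n}
                for (a, b), (r, p, n) in sorted(self.edges.items())]
        return pd.DataFrame(rows, columns=["gene1", "gene2", "r", "p", "n"])


@dataclass
class CandidateCircuit:
    members: Tuple[str, ...]
    min_edge_r: float
    max_edge_p: float

    @property
    def size(self) -> int:
        return len(self.members)


def select_candidates(se_genes: Sequence[str], de_table: pd.DataFrame,
                      tf_catalog: Sequence[str]) -> List[CandidateTF]:
    """Flag each SE-driven gene as candidate or not; sorted by gene name.

    ``de_table`` is indexed by gene with a ``call`` column; SE genes absent
    from it count as ``ns``.
    """
    catalog = set(tf_catalog)
    if not catalog:
        raise InvalidParameterError("TF catalog is empty")
    out = []
    for gene in sorted(set(se_genes)):
        call = str(de_table.loc[gene, "call"]) if gene in de_table.index else "ns"
        out.append(CandidateTF(gene=gene, is_se_associated=True, de_call=call,
                               in_tf_catalog=gene in catalog))
    return out


def pearson(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Sample Pearson r with the two-sided t-test p-value (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InvalidParameterError("vectors must have equal length")
    n = x.size
    if n < 3:
        raise InvalidParameterError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0  # distribution's limit; perfectly collinear
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def build_network(expr: pd.DataFrame) -> CorrelationNetwork:
    """All pairwise Pearson edges over the rows (genes) of ``expr``.

    ``expr`` is gene x sample, restricted to candidate genes; genes constant
    across samples are excluded with a warning.
    """
    if expr.shape[1] < 3:
        raise InvalidParameterError("need >= 3 samples")
    values = expr.to_numpy(dtype=float)
    keep = np.ptp(values, axis=1) > 0
    dropped = list(expr.index[~keep])
    if dropped:
        warnings.warn(f"excluding constant gene(s): {dropped}")
    genes = list(expr.index[keep])
    values = values[keep]
    n = expr.shape[1]
    edges: Dict[Tuple[str, str], Tuple[float, float, int]] = {}
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            r, p = pearson(values[i], values[j])
            a, b = sorted((genes[i], genes[j]))
            edges[(a, b)] = (r, p, n)
    return CorrelationNetwork(nodes=genes, edges=edges)


def nominate_circuits(net: CorrelationNetwork, r_min: float = 0.5,
                      p_max: float = 0.05, min_size: int = 3,
                      ) -> List[CandidateCircuit]:
    """Maximal cliques of the thresholded positive-correlation graph.

    An edge qualifies when r >= r_min and p <= p_max. Cliques below
    ``min_size`` are discarded; the rest are sorted by (size descending,
    minimum edge r descending, members).
    """
    if not (-1.0 <= r_min <= 1.0) or not (0.0 <= p_max <= 1.0) or min_size < 2:
        raise InvalidParameterError("invalid thresholds")
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    for (a, b), (r, p, _n) in net.edges.items():
        if r >= r_min and p <= p_max:
            g.add_edge(a, b)
    circuits = []
    for clique in nx.find_cliques(g):
        if len(clique) < min_size:
            continue
        members = tuple(sorted(clique))
        rs, ps = [], []
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                r, p, _n = net.edge(members[i], members[j])
                rs.append(r)
                ps.append(p)
        circuits.append(CandidateCircuit(members=members, min_edge_r=min(rs),
                                         max_edge_p=max(ps)))
    circuits.sort(key=lambda c: (-c.size, -c.min_edge_r, c.members))
    return circuits
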