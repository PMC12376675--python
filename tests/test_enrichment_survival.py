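"""Preranked GSEA, ssGSEA scoring, log-rank test, and maxstat cutpoint."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from secircuit.enrichment_survival import (logrank, maxstat_cutpoint,
                                           preranked_es, preranked_gsea,
                                           ssgsea_score)
from secircuit.errors import (DegenerateInputError, InvalidParameterError)


class TestPrerankedEs:
    def _ranked(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n)]
        scores = np.sort(rng.standard_normal(n))[::-1]
        return genes, scores

    def test_extreme_sets_reach_plus_minus_one_unweighted(self):
        genes, scores = self._ranked()
        assert preranked_es(genes, scores, genes[:5], weight_p=0) == \
            pytest.approx(1.0)
        assert preranked_es(genes, scores, genes[-5:], weight_p=0) == \
            pytest.approx(-1.0)

    def test_matches_step_by_step_running_sum(self):
        genes, scores = self._ranked(20, seed=3)
        gene_set = {genes[i] for i in (0, 4, 7, 11, 16)}
        # independent walk down the ranked list
        w = {g: abs(s) for g, s in zip(genes, scores)}
        total = sum(w[g] for g in gene_set)
        running, best = 0.0, 0.0
        for g in genes:
            if g in gene_set:
                running += w[g] / total
            else:
                running -= 1 / (20 - 5)
            if abs(running) > abs(best):
                best = running
        assert preranked_es(genes, scores, gene_set, weight_p=1) == \
            pytest.approx(best)

    def test_degenerate_sets_rejected(self):
        genes, scores = self._ranked()
        with pytest.raises(InvalidParameterError):
            preranked_es(genes, scores, genes)
        with pytest.raises(InvalidParameterError):
            preranked_es(genes, scores, ["absent"])

    def test_invariant_to_monotone_rescale_at_weight_zero(self):
        genes, scores = self._ranked(30, seed=4)
        gene_set = genes[3:9]
        a = preranked_es(genes, scores, gene_set, weight_p=0)
        b = preranked_es(genes, 10 + 3 * scores, gene_set, weight_p=0)
        assert a == pytest.approx(b)


class TestPrerankedGsea:
    def test_planted_concordance_hits_minimum_p(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(100)]
        scores = np.sort(rng.standard_normal(100))[::-1]
        res = preranked_gsea(genes, scores, genes[:10], n_perm=999, seed=1)
        assert res.p == pytest.approx(1 / 1000)
        assert res.es > 0.9

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(50)]
        scores = rng.standard_normal(50)
        a = preranked_gsea(genes, scores, genes[5:12], n_perm=199, seed=9)
        b = preranked_gsea(genes, scores, genes[5:12], n_perm=199, seed=9)
        assert (a.es, a.nes, a.p) == (b.es, b.nes, b.p)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(2)
        pvals = []
        genes = [f"g{i}" for i in range(60)]
        for rep in range(200):
            scores = rng.standard_normal(60)
            gene_set = list(rng.choice(genes, size=8, replace=False))
            res = preranked_gsea(genes, scores, gene_set, n_perm=199,
                                 seed=rep)
            pvals.append(res.p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestSsgseaScore:
    def _sample(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        return pd.Series(rng.standard_normal(n),
                         index=[f"g{i}" for i in range(n)])

    def test_top_set_positive_bottom_set_negative(self):
        s = self._sample(50, seed=1)
        top = list(s.nlargest(5).index)
        bottom = list(s.nsmallest(5).index)
        assert ssgsea_score(s, top) > 0
        assert ssgsea_score(s, bottom) < 0
        assert ssgsea_score(s, top) == pytest.approx(1.0)

    def test_alpha_zero_matches_hand_ecdf_difference(self):
        s = self._sample(10, seed=2)
        gene_set = list(s.index[:3])
        order = s.sort_values(ascending=False).index
        hit, miss, raw = 0.0, 0.0, 0.0
        for g in order:
            if g in gene_set:
                hit += 1 / 3
            else:
                miss += 1 / 7
            raw += hit - miss
        # best case: 3 hits first, then 7 misses
        best = sum(min((i + 1) / 3, 1.0) for i in range(10)) \
            - sum(max(0, i + 1 - 3) / 7 for i in range(10))
        assert ssgsea_score(s, gene_set, alpha=0.0) == \
            pytest.approx(raw / best)

    def test_invariant_to_additive_shift(self):
        s = self._sample(30, seed=3)
        gene_set = list(s.index[5:9])
        assert ssgsea_score(s, gene_set) == \
            pytest.approx(ssgsea_score(s + 100.0, gene_set))

    def test_empty_set_rejected(self):
        with pytest.raises(InvalidParameterError):
            ssgsea_score(self._sample(), [])


def _risk_table_logrank(times, events, groups):
    """Independent O-E/V accumulation over explicit risk tables."""
    df = pd.DataFrame({"t": times, "e": events, "g": groups})
    uniq = sorted(df[df.e == 1]["t"].unique())
    o_minus_e, var = 0.0, 0.0
    g1 = df["g"].unique()[0]
    for t in uniq:
        at_risk = df[df.t >= t]
        d = int(((at_risk.t == t) & (at_risk.e == 1)).sum())
        n = len(at_risk)
        n1 = int((at_risk.g == g1).sum())
        d1 = int(((at_risk.t == t) & (at_risk.e == 1)
                  & (at_risk.g == g1)).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


class TestLogrank:
    def test_duplicated_groups_give_zero_statistic(self):
        times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        events = [1, 1, 0, 1, 1, 0]
        chi2, p = logrank(times, events, list("AAABBB"))
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_risk_tables(self):
        times, events, groups = [1, 2, 3, 4.0], [1, 1, 1, 1], list("AABB")
        chi2, _ = logrank(times, events, groups)
        assert chi2 == pytest.approx(_risk_table_logrank(times, events,
                                                         groups))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracle_and_lifelines_on_random_data(self, seed):
        from lifelines.statistics import logrank_test
        rng = np.random.default_rng(seed)
        n = 40
        times = rng.exponential(10, n).round(1) + 0.1
        events = rng.integers(0, 2, n)
        if events.sum() == 0:
            events[0] = 1
        groups = np.where(rng.random(n) < 0.5, "A", "B")
        if len(np.unique(groups)) < 2:
            groups[0] = "A" if groups[1] == "B" else "B"
        chi2, p = logrank(times, events, groups)
        assert chi2 == pytest.approx(_risk_table_logrank(times, events,
                                                         groups))
        ref = logrank_test(times[groups == "A"], times[groups == "B"],
                           events[groups == "A"], events[groups == "B"])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(11)
        times = rng.exponential(5, 30)
        events = rng.integers(0, 2, 30)
        events[0] = 1
        groups = np.array(["A"] * 15 + ["B"] * 15)
        swapped = np.where(groups == "A", "B", "A")
        assert logrank(times, events, groups)[0] == \
            pytest.approx(logrank(times, events, swapped)[0])


class TestMaxstatCutpoint:
    def _planted(self, seed, n=200, hr=4.0, cut=0.0):
        rng = np.random.default_rng(seed)
        scores = rng.standard_normal(n)
        hazard = 0.1 * np.where(scores > cut, hr, 1.0)
        times = rng.exponential(1 / hazard)
        cens = rng.exponential(1 / (0.1 / 9), n)
        return scores, np.minimum(times, cens), (times <= cens).astype(int)

    def test_recovered_groups_agree_with_planted_split(self):
        # the argmax itself jitters by a few order statistics, but the
        # induced high/low partition tracks the planted one closely
        agreements = []
        for seed in range(50):
            scores, times, events = self._planted(seed)
            res = maxstat_cutpoint(scores, times, events, p_method="none")
            got = scores > res.cutpoint
            want = scores > 0.0
            agreements.append((got == want).mean())
        assert np.mean(agreements) >= 0.95

    def test_matches_exhaustive_scan(self):
        for seed in range(20):
            scores, times, events = self._planted(seed, n=50)
            res = maxstat_cutpoint(scores, times, events, p_method="none")
            q_lo, q_hi = np.quantile(scores, (0.1, 0.9))
            best = None
            for c in np.unique(scores)[:-1]:
                if not (q_lo <= c <= q_hi):
                    continue
                groups = np.where(scores > c, "high", "low")
                chi2, _ = logrank(times, events, groups)
                if best is None or chi2 > best[1]:
                    best = (c, chi2)
            assert res.cutpoint == pytest.approx(best[0])
            assert res.max_stat ** 2 == pytest.approx(best[1])

    def test_null_permutation_p_uniform(self):
        pvals = []
        for seed in range(200):
            scores, times, events = self._planted(seed, n=40, hr=1.0)
            res = maxstat_cutpoint(scores, times, events, n_perm=99,
                                   seed=seed)
            pvals.append(res.p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_degenerate_inputs(self):
        with pytest.raises(InvalidParameterError):
            maxstat_cutpoint([1.0, 2.0], [1, 2], [1, 1])
        with pytest.raises(DegenerateInputError):
            maxstat_cutpoint([1.0] * 12, np.arange(12) + 1.0,
                             np.ones(12, dtype=int))

    def test_groups_partition_samples(self):
        scores, times, events = self._planted(5, n=60)
        res = maxstat_cutpoint(scores, times, events, p_method="none")
        assert set(res.groups) == {"high", "low"}
        assert (res.groups == "high").sum() + (res.groups == "low").sum() == 60
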