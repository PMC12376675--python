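"""Promoter/enhancer classification, co-binding groups, motif scanning/span."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from secircuit.element_annotation import (GROUP_ORDER, classify_elements,
                                          group_expression_summary,
                                          motif_scan, motif_span,
                                          stratify_cobinding)
from secircuit.errors import InvalidParameterError
from secircuit.intervals import GenomicInterval, PeakSet


def _ps(*triples):
    return PeakSet.from_intervals(
        [GenomicInterval(c, s, e) for c, s, e in triples])


ANN = pd.DataFrame({
    "gene": ["gA", "gB"],
    "chrom": ["chr1", "chr1"],
    "strand": ["+", "-"],
    "tss": [10_000, 80_000],
})


class TestClassifyElements:
    def test_promoter_requires_mark_and_tss_window(self):
        h3k27ac = _ps(("chr1", 9_500, 10_200))
        me3 = _ps(("chr1", 9_400, 10_400))
        me1 = _ps(("chr1", 1, 2))
        els = classify_elements(h3k27ac, me3, me1, ANN)
        assert len(els) == 1 and els[0].kind == "promoter"
        assert els[0].gene == "gA"

    def test_distal_h3k4me1_region_is_enhancer(self):
        h3k27ac = _ps(("chr1", 40_000, 41_000))
        me1 = _ps(("chr1", 39_900, 41_100))
        els = classify_elements(h3k27ac, _ps(("chr1", 1, 2)), me1, ANN)
        assert len(els) == 1 and els[0].kind == "enhancer"
        assert els[0].gene == "gA"  # midpoint 40500 nearer to 10000 than 80000
        assert els[0].tss_distance == 40_500 - 10_000

    def test_promoter_precedence_over_enhancer(self):
        h3k27ac = _ps(("chr1", 9_500, 10_200))
        both = _ps(("chr1", 9_000, 11_000))
        els = classify_elements(h3k27ac, both, both, ANN)
        assert els[0].kind == "promoter"

    def test_region_with_neither_mark_is_dropped(self):
        h3k27ac = _ps(("chr1", 40_000, 41_000))
        empty = _ps(("chr2", 1, 2))
        assert classify_elements(h3k27ac, empty, empty, ANN) == []

    def test_minus_strand_window_and_signed_distance(self):
        # gB is on -, so its promoter window extends to higher coordinates
        h3k27ac = _ps(("chr1", 80_300, 80_900))
        me3 = _ps(("chr1", 80_200, 81_000))
        els = classify_elements(h3k27ac, me3, _ps(("chr1", 1, 2)), ANN)
        assert els[0].kind == "promoter" and els[0].gene == "gB"
        assert els[0].tss_distance == -(80_600 - 80_000)  # downstream = upstream of -

    def test_empty_annotation_rejected(self):
        with pytest.raises(InvalidParameterError):
            classify_elements(_ps(("chr1", 0, 10)), _ps(("chr1", 0, 10)),
                              _ps(("chr1", 0, 10)), ANN.iloc[:0])


class TestStratifyCobinding:
    def _elements(self, spans):
        h3k27ac = _ps(*spans)
        me1 = _ps(*((c, s - 1, e + 1) for c, s, e in spans))
        return classify_elements(h3k27ac, _ps(("chr2", 1, 2)), me1, ANN)

    def test_group_from_cardinality(self):
        els = self._elements([("chr1", 20_000, 21_000),
                              ("chr1", 40_000, 41_000)])
        tf_peaks = {
            "TF1": _ps(("chr1", 20_100, 20_200)),
            "TF2": _ps(("chr1", 20_300, 20_400)),
            "TF3": _ps(("chr1", 20_500, 20_600)),
        }
        stratify_cobinding(els, tf_peaks)
        assert els[0].group == "trio" and set(els[0].bound_by) == \
            {"TF1", "TF2", "TF3"}
        assert els[1].group == "none" and els[1].bound_by == ()

    def test_requires_exactly_three_tf_sets(self):
        els = self._elements([("chr1", 20_000, 21_000)])
        with pytest.raises(InvalidParameterError):
            stratify_cobinding(els, {"TF1": _ps(("chr1", 1, 2))})

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pairwise_overlap_oracle(self, seed):
        rng = np.random.default_rng(seed)
        spans = []
        pos = 0
        for _ in range(30):
            pos += int(rng.integers(13_000, 20_000))
            spans.append(("chr1", pos, pos + int(rng.integers(200, 900))))
        ann = pd.DataFrame({"gene": ["g"], "chrom": ["chr1"], "strand": ["+"],
                            "tss": [1]})
        h3k27ac = _ps(*spans)
        me1 = _ps(*spans)
        els = classify_elements(h3k27ac, _ps(("chr2", 1, 2)), me1, ann)
        tf_peaks = {}
        for tf in ("TF1", "TF2", "TF3"):
            ivs = []
            for c, s, e in spans:
                if rng.random() < 0.4:
                    ivs.append(GenomicInterval(c, s + 10, s + 50))
            ivs.append(GenomicInterval("chr1", 1, 2))  # decoy far away
            tf_peaks[tf] = PeakSet.from_intervals(ivs)
        stratify_cobinding(els, tf_peaks)
        for el in els:
            want = tuple(tf for tf in ("TF1", "TF2", "TF3")
                         if any(el.span.overlap_bp(iv) >= 1
                                for iv in tf_peaks[tf]))
            assert el.bound_by == want


class TestGroupExpressionSummary:
    def _planted(self, seed, boost=1.0, n_per_group=25):
        """Elements in 4 groups whose genes get expression ~ boost per TF."""
        rng = np.random.default_rng(seed)
        els, rows = [], {}
        tf_sets = {"trio": ("TF1", "TF2", "TF3"), "dual": ("TF1", "TF2"),
                   "solo": ("TF1",), "none": ()}
        ann = pd.DataFrame({"gene": ["g"], "chrom": ["chr1"], "strand": ["+"],
                            "tss": [1]})
        pos = 0
        spans, genes, bounds = [], [], []
        for group, tfs in tf_sets.items():
            for i in range(n_per_group):
                pos += 20_000
                spans.append(("chr1", pos, pos + 500))
                genes.append(f"{group}_{i}")
                bounds.append(tfs)
        els = classify_elements(_ps(*spans), _ps(("chr2", 1, 2)), _ps(*spans),
                                ann)
        # overwrite nearest-gene assignment with the planted genes
        for el, g in zip(els, genes):
            el.gene = g
        tf_peaks = {tf: PeakSet.from_intervals(
            [GenomicInterval(c, s + 1, s + 60)
             for (c, s, e), tfs in zip(spans, bounds) if tf in tfs]
            + [GenomicInterval("chr1", 1, 2)])
            for tf in ("TF1", "TF2", "TF3")}
        stratify_cobinding(els, tf_peaks)
        expr = pd.DataFrame(
            {"s1": [2 ** (6 + boost * len(b) + rng.normal(0, 1))
                    for b in bounds]},
            index=genes)
        return els, expr

    def test_planted_boost_orders_groups(self):
        for seed in range(20):
            els, expr = self._planted(seed)
            summaries, tests = group_expression_summary(els, expr, ["s1"])
            enh = {s.group: s for s in summaries if s.kind == "enhancer"}
            means = [enh[g].expr_values.mean() for g in GROUP_ORDER]
            assert means == sorted(means, reverse=True)
            row = tests[(tests.kind == "enhancer") & (tests.group1 == "trio")
                        & (tests.group2 == "none")].iloc[0]
            assert row.t > 0 and row.p / 2 < 0.01  # one-sided Welch

    def test_null_pairwise_p_uniform(self):
        pvals = []
        for seed in range(200):
            els, expr = self._planted(seed + 1000, boost=0.0, n_per_group=12)
            _, tests = group_expression_summary(els, expr, ["s1"])
            sub = tests[(tests.kind == "enhancer") & ~tests.skipped]
            pvals.append(float(sub.iloc[seed % len(sub)]["p"]))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_single_gene_group_is_skipped(self):
        els, expr = self._planted(0, n_per_group=1)
        summaries, tests = group_expression_summary(els, expr, ["s1"])
        assert all(s.test_skipped for s in summaries if s.n_elements)
        assert tests["skipped"].all()

    def test_se_overlap_fraction_monotone_in_se_set(self):
        els, expr = self._planted(3)
        spans = [el.span for el in els]
        se_small = PeakSet.from_intervals(spans[:10])
        se_big = PeakSet.from_intervals(spans[:30])
        s_small, _ = group_expression_summary(els, expr, ["s1"],
                                              se_peaks=se_small)
        f_small = {(s.kind, s.group): s.se_overlap_fraction for s in s_small}
        s_big, _ = group_expression_summary(els, expr, ["s1"],
                                            se_peaks=se_big)
        for s in s_big:
            assert s.se_overlap_fraction >= f_small[(s.kind, s.group)]


CONSENSUS = "TGACTCA"  # 7-mer used as a degenerate PWM


def _consensus_pwm(seq):
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    pwm = np.zeros((4, len(seq)))
    for j, c in enumerate(seq):
        pwm[idx[c], j] = 1.0
    return pwm


def _revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestMotifScan:
    def test_consensus_found_once_forward(self):
        seq = "A" * 20 + CONSENSUS + "A" * 20
        hits = motif_scan(seq, _consensus_pwm(CONSENSUS), score_threshold=10)
        fwd = [h for h in hits if h[1] == "+"]
        assert len(fwd) == 1 and fwd[0][0] == 20

    def test_strand_symmetry_under_reverse_complement(self):
        seq = "C" * 11 + CONSENSUS + "G" * 5
        pwm = _consensus_pwm(CONSENSUS)
        fwd_hits = motif_scan(seq, pwm, score_threshold=10)
        rc_hits = motif_scan(_revcomp(seq), pwm, score_threshold=10)
        assert len(fwd_hits) == len(rc_hits) == 1
        off, strand, score = fwd_hits[0]
        off2, strand2, score2 = rc_hits[0]
        assert strand == "+" and strand2 == "-"
        assert off2 == len(seq) - len(CONSENSUS) - off
        assert score == pytest.approx(score2)

    def test_n_bases_score_as_background(self):
        seq = "A" * 10 + "NNNNNNN" + "A" * 10
        hits = motif_scan(seq, _consensus_pwm(CONSENSUS), score_threshold=-100)
        n_window = [h for h in hits if h[0] == 10 and h[1] == "+"]
        assert n_window[0][2] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_per_offset_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=60))
        pwm = rng.dirichlet(np.ones(4), size=5).T  # random 4x5 PWM
        thr = -2.0
        hits = motif_scan(seq, pwm, score_threshold=thr)
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        p = (pwm + 1e-3) / (1 + 4e-3)
        lo = np.log2(p / 0.25)

        def score(s):
            return sum(lo[idx[c], j] for j, c in enumerate(s))

        want = []
        for off in range(len(seq) - 5 + 1):
            w = seq[off:off + 5]
            if score(w) >= thr:
                want.append((off, "+", pytest.approx(score(w))))
            if score(_revcomp(w)) >= thr:
                want.append((off, "-", pytest.approx(score(_revcomp(w)))))
        want.sort(key=lambda h: (h[0], h[1]))
        assert hits == want


class TestMotifSpan:
    def test_three_singleton_hits(self):
        hits = {"TF1": [(0, "+", 1.0)], "TF2": [(10, "+", 1.0)],
                "TF3": [(15, "+", 1.0)]}
        lengths = {"TF1": 8, "TF2": 8, "TF3": 8}
        assert motif_span(hits, lengths) == 23

    def test_absent_when_a_tf_has_no_hit(self):
        hits = {"TF1": [(0, "+", 1.0)], "TF2": [], "TF3": [(5, "+", 1.0)]}
        assert motif_span(hits, {"TF1": 8, "TF2": 8, "TF3": 8}) is None

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_triple_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        lengths = {f"TF{i}": int(rng.integers(5, 15)) for i in (1, 2, 3)}
        hits = {tf: [(int(rng.integers(0, 300)), "+", 0.0) for _ in range(5)]
                for tf in lengths}
        got = motif_span(hits, lengths)
        best = min(max(o + lengths[tf] for tf, (o, _, _) in zip(lengths, combo))
                   - min(o for o, _, _ in combo)
                   for combo in itertools.product(*hits.values()))
        assert got == best
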