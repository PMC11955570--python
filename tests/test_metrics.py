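"""Diagnostic-accuracy statistics against independent oracles.

Oracles used here: statsmodels' exact binomial interval for the
Clopper–Pearson bounds; brute-force concordant/discordant pair counting for
the Mann–Whitney reading of the AUC; hand-computed structural components on
a four-subject example for the DeLong variance.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from osta_screen.metrics import (
    ConfusionMatrix,
    auc_binary,
    clopper_pearson,
    confusion,
    delong_auc,
    delong_compare,
    evaluate,
    pearson_r,
    proportion_ci,
    wilson,
)

cms = st.tuples(
    st.integers(0, 60), st.integers(0, 400), st.integers(0, 400), st.integers(0, 60),
).filter(lambda t: t[0] + t[3] >= 1 and t[1] + t[2] >= 1).map(
    lambda t: ConfusionMatrix(tp=t[0], fp=t[1], tn=t[2], fn=t[3]))


def auc_by_pair_counting(scores, diseased):
    """Brute-force tie-corrected Mann–Whitney AUC."""
    pos = scores[diseased]
    neg = scores[~diseased]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_test(self):
        d = np.array([True, True, False, False])
        cm = confusion(d, d)
        assert cm.fp == cm.fn == 0 and cm.tp == 2 and cm.tn == 2

    def test_reconstructed_any_site_row(self):
        cm = ConfusionMatrix(tp=36, fp=258, tn=127, fn=6)
        p = evaluate(cm)
        assert round(100 * p.sensitivity, 1) == 85.7
        assert round(100 * p.specificity, 1) == 33.0
        assert round(100 * p.ppv, 1) == 12.2
        assert round(100 * p.npv, 1) == 95.5

    def test_all_negative_predictor(self):
        cm = confusion(np.zeros(5, bool), np.array([1, 1, 0, 0, 0], bool))
        assert evaluate(cm).sensitivity == 0.0

    def test_length_mismatch_and_empty(self):
        with pytest.raises(ValueError):
            confusion([True], [True, False])
        with pytest.raises(ValueError):
            confusion([], [])


class TestMetricRows:
    def test_femoral_neck_likelihood_ratio(self):
        p = evaluate(ConfusionMatrix(tp=20, fp=82, tn=314, fn=11))
        assert round(p.lr_plus, 2) == 3.12
        assert round(p.youden, 3) == 0.438

    def test_perfect_test_sentinels(self):
        p = evaluate(ConfusionMatrix(tp=5, fp=0, tn=5, fn=0))
        assert p.youden == 1.0 and math.isinf(p.lr_plus)

    def test_degenerate_denominators_give_nan_not_failure(self):
        p = evaluate(ConfusionMatrix(tp=0, fp=0, tn=4, fn=2))
        assert math.isnan(p.ppv) and not math.isnan(p.npv)

    @given(cm=cms)
    @settings(max_examples=200, deadline=None)
    def test_identities(self, cm):
        p = evaluate(cm)
        # Youden and the two-point AUC are both affine in sens + spec
        assert p.youden == pytest.approx(2 * p.auc - 1, abs=1e-12)
        # Bayes consistency of PPV at the sample prevalence
        pi = cm.cases / cm.n
        if cm.tp + cm.fp > 0 and not math.isnan(p.ppv):
            denom = p.sensitivity * pi + (1 - p.specificity) * (1 - pi)
            if denom > 0:
                assert p.ppv == pytest.approx(p.sensitivity * pi / denom, abs=1e-12)


class TestProportionCIs:
    @pytest.mark.parametrize("x, n, lo, hi", [
        (4, 5, 28.4, 99.5),
        (1, 5, 0.5, 71.6),
        (41, 41, 91.4, 100.0),
    ])
    def test_printed_small_sample_bounds(self, x, n, lo, hi):
        got = clopper_pearson(x, n)
        assert round(100 * got[0], 1) == lo
        assert round(100 * got[1], 1) == hi

    def test_edge_cases(self):
        assert clopper_pearson(0, 7)[0] == 0.0
        assert clopper_pearson(7, 7)[1] == 1.0

    @given(n=st.integers(1, 200), frac=st.floats(0, 1), alpha=st.sampled_from([0.05, 0.10]))
    @settings(max_examples=150, deadline=None)
    def test_matches_statsmodels_beta_interval(self, n, frac, alpha):
        x = round(frac * n)
        ours = clopper_pearson(x, n, alpha)
        ref = proportion_confint(x, n, alpha=alpha, method="beta")
        assert ours[0] == pytest.approx(0.0 if x == 0 else ref[0], abs=1e-10)
        assert ours[1] == pytest.approx(1.0 if x == n else ref[1], abs=1e-10)

    @given(n=st.integers(1, 300), frac=st.floats(0, 1))
    @settings(max_examples=150, deadline=None)
    def test_contains_point_estimate(self, n, frac):
        x = round(frac * n)
        lo, hi = clopper_pearson(x, n)
        assert lo <= x / n <= hi

    def test_width_shrinks_with_n(self):
        widths = []
        for n in (10, 40, 160, 640):
            lo, hi = clopper_pearson(n // 2, n)
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)

    def test_exact_coverage_at_or_above_nominal(self):
        # exact coverage by binomial enumeration over an (n, p) grid
        for n in (10, 25, 50):
            for p in (0.05, 0.1, 0.3, 0.5, 0.8):
                xs = np.arange(n + 1)
                bounds = np.array([clopper_pearson(int(x), n) for x in xs])
                covered = (bounds[:, 0] <= p) & (p <= bounds[:, 1])
                coverage = stats.binom.pmf(xs, n, p)[covered].sum()
                assert coverage >= 0.95

    def test_wilson_option_differs_and_is_narrower_here(self):
        cp = proportion_ci(4, 5, method="clopper-pearson")
        wl = proportion_ci(4, 5, method="wilson")
        assert wl != cp
        assert (wl[1] - wl[0]) < (cp[1] - cp[0])
        with pytest.raises(ValueError, match="unknown CI method"):
            proportion_ci(4, 5, method="wald")


class TestAUC:
    def test_binary_auc_equals_mean_of_sens_spec(self):
        auc, _ = auc_binary(ConfusionMatrix(tp=36, fp=258, tn=127, fn=6))
        assert round(auc, 3) == 0.594
        auc2, _ = auc_binary(ConfusionMatrix(tp=20, fp=82, tn=314, fn=11))
        assert round(auc2, 3) == 0.719

    def test_chance_line(self):
        auc, _ = auc_binary(ConfusionMatrix(tp=5, fp=5, tn=5, fn=5))
        assert auc == 0.5

    @given(cm=cms)
    @settings(max_examples=100, deadline=None)
    def test_equals_pair_counting_oracle(self, cm):
        small = ConfusionMatrix(tp=min(cm.tp, 8), fp=min(cm.fp, 8),
                                tn=min(cm.tn, 8), fn=min(cm.fn, 8))
        if small.cases == 0 or small.non_cases == 0:
            return
        scores = np.concatenate([np.ones(small.tp), np.zeros(small.fn),
                                 np.ones(small.fp), np.zeros(small.tn)])
        dis = np.concatenate([np.ones(small.cases, bool), np.zeros(small.non_cases, bool)])
        auc, _ = auc_binary(small)
        assert auc == pytest.approx(auc_by_pair_counting(scores, dis), abs=1e-12)
        p = evaluate(small)
        assert auc == pytest.approx((p.sensitivity + p.specificity) / 2, abs=1e-12)


class TestDeLong:
    def test_identical_predictors(self):
        d = np.array([1, 1, 1, 0, 0, 0, 0], bool)
        s = np.array([3.0, 2.0, 0.5, 1.0, 0.2, 0.1, 2.5])
        res = delong_compare(s, s, d)
        assert res.delta == 0.0 and res.p == 1.0

    def test_continuous_auc_matches_pair_counting(self, rng):
        for _ in range(25):
            n = int(rng.integers(6, 20))
            d = np.zeros(n, bool)
            d[: int(rng.integers(1, n - 1))] = True
            rng.shuffle(d)
            s = np.round(rng.normal(size=n) + d, 1)  # induce some ties
            auc, _ = delong_auc(s, d)
            assert auc == pytest.approx(auc_by_pair_counting(s, d), abs=1e-12)

    def test_structural_components_four_subject_example(self):
        # cases scored (1, 0), non-cases scored (1, 0):
        # V10 = [(tn + fp/2)/2, tn/2/2] = [0.75, 0.25]; V01 = [0.25, 0.75]
        s = np.array([1.0, 0.0, 1.0, 0.0])
        d = np.array([True, True, False, False])
        auc, ci = delong_auc(s, d)
        assert auc == 0.5
        var10 = np.var([0.75, 0.25], ddof=1) / 2
        var01 = np.var([0.25, 0.75], ddof=1) / 2
        half = stats.norm.ppf(0.975) * math.sqrt(var10 + var01)
        assert ci == pytest.approx((max(0, 0.5 - half), min(1, 0.5 + half)), abs=1e-12)

    def test_zero_statistic_for_identical_rankings(self, rng):
        d = rng.random(30) < 0.4
        d[0] = True
        d[1] = False
        s = rng.normal(size=30)
        res = delong_compare(s, 2 * s + 5, d)  # monotone transform: same ranking
        assert res.delta == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            delong_compare([1.0, 2.0], [2.0, 1.0], [True, True])


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson_r(x, x)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 2.0], [1.0, 2.0])
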