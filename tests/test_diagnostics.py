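"""ROC/AUC duality, Youden search, exact intervals, rank statistics."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import roc_auc_score

from hxfacs.diagnostics import (
    LabeledScores,
    UndefinedROCError,
    clopper_pearson,
    confusion,
    group_summary,
    mann_whitney,
    pearson_corr,
    roc_auc,
    youden_cutoff,
)


def _scores(pos, neg):
    return LabeledScores.from_arrays(
        list(pos) + list(neg), [True] * len(pos) + [False] * len(neg)
    )


class TestROC:
    def test_surgical_double_pos_auc(self, surgical_scores):
        # 12 vs 11 specimens, no cross-class ties: 112 of 132 pairs ordered
        assert roc_auc(surgical_scores["double_pos"]).auc == pytest.approx(112 / 132)

    def test_surgical_egfr_auc_counts_tie_as_half(self, surgical_scores):
        # one exact cross-class tie at 98.9 contributes one half
        assert roc_auc(surgical_scores["egfr_pos"]).auc == pytest.approx(113.5 / 132)

    def test_perfect_separation(self):
        assert roc_auc(_scores([10, 11, 12], [1, 2, 3])).auc == 1.0

    def test_single_class_is_undefined(self):
        with pytest.raises(UndefinedROCError):
            roc_auc(LabeledScores.from_arrays([1.0, 2.0], [True, True]))

    def test_curve_is_monotone(self, surgical_scores):
        pts = np.asarray(roc_auc(surgical_scores["hx103_pos"]).points)
        assert (np.diff(pts[:, 0]) >= 0).all()
        assert (np.diff(pts[:, 1]) >= 0).all()

    def test_ci_is_not_truncated_at_one(self, tki_scores):
        # a small-sample AUC of 1.0 yields an upper Wald bound above 1
        res = roc_auc(tki_scores["double_pos"])
        assert res.auc == 1.0
        assert res.ci95[1] >= 1.0

    @given(st.data())
    @settings(max_examples=100, derandomize=True)
    def test_pair_statistic_matches_sklearn_with_ties(self, data):
        # tie-rich integer scores exercise the half-credit bookkeeping
        pos = data.draw(st.lists(st.integers(0, 5), min_size=1, max_size=12))
        neg = data.draw(st.lists(st.integers(0, 5), min_size=1, max_size=12))
        sc = _scores([float(v) for v in pos], [float(v) for v in neg])
        expected = roc_auc_score(sc.labels, sc.values)
        assert roc_auc(sc).auc == pytest.approx(expected, abs=1e-12)


class TestYouden:
    def test_double_pos_cutoff_is_midpoint(self, surgical_scores):
        cutoff, j = youden_cutoff(surgical_scores["double_pos"])
        assert cutoff == pytest.approx((22.6 + 37.7) / 2)  # 30.15
        assert j == pytest.approx(10 / 12 + 9 / 11 - 1, abs=1e-12)

    def test_hx103_cutoff(self, surgical_scores):
        cutoff, _ = youden_cutoff(surgical_scores["hx103_pos"])
        assert cutoff == pytest.approx(30.95)

    def test_egfr_cutoff_maximizes_j(self, surgical_scores):
        # the J-maximizing midpoint for total-EGFR staining sits between
        # 59.3 and 64.8 (J = 0.742), above the 36.3% operating threshold
        cutoff, j = youden_cutoff(surgical_scores["egfr_pos"])
        assert cutoff == pytest.approx((59.3 + 64.8) / 2)
        assert j == pytest.approx(10 / 12 + 10 / 11 - 1, abs=1e-12)

    @pytest.mark.parametrize("param", ["double_pos", "egfr_pos", "hx103_pos"])
    @pytest.mark.parametrize("cohort", ["surgical_scores", "biopsy_scores"])
    def test_returned_j_beats_every_midpoint(self, param, cohort, request):
        sc = request.getfixturevalue(cohort)[param]
        cutoff, j = youden_cutoff(sc)
        pos, neg = sc.pos, sc.neg
        values = np.unique(np.asarray(sc.values))
        for c in (values[:-1] + values[1:]) / 2:
            j_other = (pos >= c).mean() + (neg < c).mean() - 1
            assert j >= j_other - 1e-12

    def test_identical_values_have_no_cutoff(self):
        with pytest.raises(ValueError, match="no cut-off"):
            youden_cutoff(_scores([5.0, 5.0], [5.0, 5.0]))


class TestConfusion:
    def test_surgical_double_pos_at_operating_threshold(self, surgical_scores):
        c = confusion(surgical_scores["double_pos"], 30.1)
        assert (c.tp, c.fn, c.tn, c.fp) == (10, 2, 9, 2)
        assert c.sensitivity == pytest.approx(83.3, abs=0.05)
        assert c.accuracy == pytest.approx(82.6, abs=0.05)
        assert c.sensitivity_ci95 == pytest.approx((51.6, 97.9), abs=0.05)

    def test_biopsy_double_pos_at_operating_threshold(self, biopsy_scores):
        c = confusion(biopsy_scores["double_pos"], 30.1)
        assert (c.tp, c.fn) == (11, 4)      # 11/15 mutants flagged
        assert (c.tn, c.fp) == (16, 0)      # all wild-type negative

    def test_all_correct_toy(self):
        c = confusion(_scores([50, 60], [10, 20]), 30.0)
        assert c.sensitivity == c.specificity == c.accuracy == 100.0

    def test_counts_invariant_under_monotone_transform(self, surgical_scores):
        sc = surgical_scores["double_pos"]
        raw = confusion(sc, 30.1)
        transform = lambda v: np.log1p(np.asarray(v) + 100.0)
        warped = LabeledScores.from_arrays(transform(sc.values), sc.labels)
        out = confusion(warped, float(transform(30.1)))
        assert (out.tp, out.fp, out.tn, out.fn) == (raw.tp, raw.fp, raw.tn, raw.fn)


class TestClopperPearson:
    def test_published_interval_for_10_of_12(self):
        assert clopper_pearson(10, 12) == pytest.approx((51.6, 97.9), abs=0.05)

    def test_degenerate_ends(self):
        assert clopper_pearson(12, 12)[1] == 100.0
        assert clopper_pearson(0, 12)[0] == 0.0

    def test_against_direct_beta_quantiles(self):
        lo, hi = clopper_pearson(7, 10)
        assert lo == pytest.approx(100 * stats.beta.ppf(0.025, 7, 4), abs=1e-9)
        assert hi == pytest.approx(100 * stats.beta.ppf(0.975, 8, 3), abs=1e-9)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)

    @pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
    def test_coverage_at_least_nominal(self, p):
        rng = np.random.default_rng(int(p * 1000))
        n = 12
        ks = rng.binomial(n, p, size=10_000)
        covered = 0
        interval = {k: clopper_pearson(k, n) for k in range(n + 1)}
        for k in ks:
            lo, hi = interval[int(k)]
            covered += lo <= 100 * p <= hi
        assert covered / len(ks) >= 0.95


class TestMannWhitney:
    def test_tki_egfr_comparison(self, tki_scores):
        # 9 responders vs 4 non-responders, tie-free: exact path
        u, p = mann_whitney(tki_scores["egfr_pos"].pos, tki_scores["egfr_pos"].neg)
        assert u == 29.0
        assert p == pytest.approx(2 * 38 / 715)   # doubled exact tail

    def test_identical_samples_on_approximation_path(self):
        x = [1.0, 2.0, 3.0, 4.0]
        _, p = mann_whitney(x, x)
        assert p == pytest.approx(1.0, abs=0.01)

    def test_exact_path_matches_brute_force_enumeration(self):
        x = [3.1, 7.4, 9.9, 12.0]
        y = [1.0, 4.2, 5.5, 8.8]
        _, p = mann_whitney(x, y)
        pool = x + y
        u_obs = sum(a > b for a in x for b in y)
        us = [
            sum(pool[i] > pool[j] for i in c for j in set(range(8)) - set(c))
            for c in combinations(range(8), 4)
        ]
        ge = sum(u >= u_obs for u in us) / len(us)
        le = sum(u <= u_obs for u in us) / len(us)
        assert p == pytest.approx(min(1.0, 2 * min(ge, le)), abs=1e-12)


class TestGroupSummary:
    def test_tki_double_pos_groups(self, tki_scores):
        g = group_summary(tki_scores["double_pos"])
        assert g["positive"]["mean"] == pytest.approx(43.5, abs=0.05)
        assert g["positive"]["sem"] == pytest.approx(2.8, abs=0.05)
        assert g["negative"]["mean"] == pytest.approx(9.5, abs=0.05)
        assert g["negative"]["sem"] == pytest.approx(5.6, abs=0.05)

    def test_tki_egfr_nonresponders_sd(self, tki_scores):
        # inputs are printed-precision roundings, so spreads recomputed from
        # them can drift by up to one display unit from the published values
        g = group_summary(tki_scores["egfr_pos"])
        assert g["negative"]["mean"] == pytest.approx(21.6, abs=0.05)
        assert g["negative"]["sd"] == pytest.approx(28.9, abs=0.1)

    def test_singleton_class_has_no_spread(self):
        g = group_summary(_scores([5.0], [1.0, 2.0]))
        assert g["positive"]["sd"] is None and g["positive"]["sem"] is None


class TestPearson:
    def test_exact_linear_relations(self):
        x = np.arange(10.0)
        assert pearson_corr(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_corr(x, -x)[0] == pytest.approx(-1.0)

    def test_against_direct_covariance_formula(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r, _ = pearson_corr(x, y)
        manual = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(manual, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
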