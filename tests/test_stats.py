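"""Statistics layer: MWU, ROC/Youden, contingency tests, agreement."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from strictureqmri import (
    chi2_test,
    chi2_trend,
    compare_groups,
    icc_absolute,
    mann_whitney_u,
    roc_youden,
    weighted_kappa,
)


def exact_mwu_oracle(x, y):
    """Two-sided exact MWU p by full enumeration of rank assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = pooled.argsort().argsort() + 1  # no ties assumed
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = [
        sum(ranks[list(comb)]) - n1 * (n1 + 1) / 2
        for comb in itertools.combinations(range(len(pooled)), n1)
    ]
    us = np.array(us)
    p = 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs))
    return u_obs, min(1.0, p)


class TestMannWhitney:
    def test_fully_separated_small_sample(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_identical_groups_are_symmetric(self):
        x = [3.0, 1.0, 7.0, 2.0]
        u, p = mann_whitney_u(x, x)
        assert u == len(x) ** 2 / 2
        assert p > 0.99

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @given(seed=st.integers(0, 500))
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=4)
        y = rng.normal(size=4)
        u, p = mann_whitney_u(x, y)
        u_oracle, p_oracle = exact_mwu_oracle(x, y)
        assert u == pytest.approx(u_oracle)
        assert p == pytest.approx(p_oracle, rel=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=20), rng.normal(0.5, 1, size=15)
        u1, p1 = mann_whitney_u(x, y)
        u2, p2 = mann_whitney_u(rng.permutation(x), rng.permutation(y))
        assert (u1, p1) == (u2, p2)


class TestCompareGroups:
    def _cohort(self, seed=0, delta=0.3):
        rng = np.random.default_rng(seed)
        x = rng.lognormal(np.log(25.4), 0.41, 33)
        y = rng.lognormal(np.log(25.4) - delta, 0.48, 26)
        return pd.DataFrame({
            "group": ["inflammatory"] * 33 + ["noninflammatory"] * 26,
            "t2star": np.r_[x, y],
        })

    def test_matches_scalar_op_on_extracted_columns(self):
        df = self._cohort(seed=12)
        comp = compare_groups(df, "t2star", alpha=0.01)
        x = df.loc[df.group == "inflammatory", "t2star"].to_numpy()
        y = df.loc[df.group == "noninflammatory", "t2star"].to_numpy()
        u, p = mann_whitney_u(x, y)
        assert comp.u_statistic == u
        assert comp.p_value == p
        assert comp.n_positive == 33 and comp.n_negative == 26
        assert comp.iqr_positive[0] <= comp.median_positive \
            <= comp.iqr_positive[1]
        assert comp.alpha == 0.01

    def test_identical_groups_not_significant(self):
        values = list(range(10))
        df = pd.DataFrame({
            "group": ["inflammatory"] * 10 + ["noninflammatory"] * 10,
            "d": values + values,
        })
        comp = compare_groups(df, "d")
        assert not comp.significant

    def test_nonstrict_significance_boundary(self):
        # p == alpha counts as significant (a primary endpoint at exactly
        # the adjusted alpha is declared positive)
        df = self._cohort(seed=1)
        comp = compare_groups(df, "t2star", alpha=1.0)
        assert comp.significant

    def test_empty_group_names_parameter(self):
        df = pd.DataFrame({"group": ["inflammatory"] * 3,
                           "f": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError, match="'f'"):
            compare_groups(df, "f")

    def test_auto_selection_uses_t_test_on_gaussian_data(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "group": ["inflammatory"] * 30 + ["noninflammatory"] * 30,
            "d": rng.normal(10, 1, 60),
        })
        comp = compare_groups(df, "d", test="auto")
        assert comp.test == "t-test"


class TestRocYouden:
    def test_perfect_separation(self):
        scores = np.r_[np.ones(5) * 10, np.zeros(5)]
        labels = np.r_[np.ones(5), np.zeros(5)].astype(bool)
        roc = roc_youden(scores, labels, "higher")
        assert roc.auc == 1.0
        assert roc.youden_j == pytest.approx(1.0)
        assert roc.sensitivity == 1.0 and roc.specificity == 1.0
        assert 0 < roc.threshold < 10
        assert roc.ci_low <= roc.auc <= roc.ci_high

    @given(seed=st.integers(0, 200))
    def test_auc_equals_u_over_n1n2(self, seed):
        rng = np.random.default_rng(seed)
        n1, n0 = 12, 9
        scores = np.round(rng.normal(size=n1 + n0), 1)  # ties likely
        labels = np.r_[np.ones(n1), np.zeros(n0)].astype(bool)
        roc = roc_youden(scores, labels, "higher")
        u, _ = mann_whitney_u(scores[labels], scores[~labels])
        assert abs(roc.auc - u / (n1 * n0)) <= 1e-12

    def test_threshold_matches_exhaustive_midpoint_sweep(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.5
        labels[0], labels[1] = True, False
        roc = roc_youden(scores, labels, "higher")
        uniq = np.unique(scores)
        best = (-np.inf, -np.inf)
        best_t = None
        for t in (uniq[:-1] + uniq[1:]) / 2:
            sens = np.mean(scores[labels] > t)
            spec = np.mean(scores[~labels] <= t)
            if (sens + spec - 1, sens) > best:
                best = (sens + spec - 1, sens)
                best_t = t
        assert roc.youden_j == pytest.approx(best[0])
        assert roc.threshold == pytest.approx(best_t)

    def test_lower_orientation_flips_direction(self):
        # lower scores mark the positive class (as for diffusion D)
        scores = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        labels = np.array([True, True, True, False, False, False])
        roc = roc_youden(scores, labels, "lower")
        assert roc.auc == 1.0
        assert 3.0 < roc.threshold < 10.0  # positive when score < threshold

    def test_auc_agrees_with_reference_implementation(self):
        sklearn = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(14)
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.4
        labels[:2] = [True, False]
        roc = roc_youden(scores, labels, "higher")
        assert roc.auc == pytest.approx(
            sklearn.roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_youden([1.0, 2.0], [True, True], "higher")


class TestContingency:
    def test_balanced_table_has_zero_statistic(self):
        chi2, p = chi2_test([[10, 10], [10, 10]])
        assert chi2 == 0.0
        assert p == 1.0

    def test_closed_form_2x2(self):
        # chi2 = n (ad - bc)^2 / (r1 r2 c1 c2)
        chi2, _ = chi2_test([[3, 1], [1, 3]])
        assert chi2 == pytest.approx(8 * (3 * 3 - 1 * 1) ** 2 / 256)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi2_test([[0, 0], [5, 3]])

    def test_trend_fixture_matches_frozen_oracle(self):
        # score test on proportions 2/20, 5/20, 9/20, 14/20 across four
        # ordered categories; value frozen from an independent computation
        table = [[2, 18], [5, 15], [9, 11], [14, 6]]
        chi2, p = chi2_trend(table)
        assert chi2 == pytest.approx(17.066666666666666, rel=1e-12)
        assert p == pytest.approx(3.609023236748e-05, rel=1e-9)

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    def test_trend_invariant_to_affine_score_rescaling(self, a, b):
        table = [[2, 18], [5, 15], [9, 11], [14, 6]]
        base, _ = chi2_trend(table, scores=[0, 1, 2, 3])
        scaled, _ = chi2_trend(table,
                               scores=a * np.arange(4.0) + b)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_trend_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            chi2_trend([[3, 1]])


class TestAgreement:
    def test_perfect_agreement_kappa_is_one(self):
        a = np.array([0, 1, 2, 3, 2, 1])
        assert weighted_kappa(a, a).value == pytest.approx(1.0)

    def test_fixture_confusion_table_matches_frozen_oracle(self):
        table = np.array([[2, 1, 0, 0], [1, 2, 1, 0],
                          [0, 1, 2, 1], [0, 0, 1, 2]])
        a, b = [], []
        for i in range(4):
            for j in range(4):
                a += [i] * table[i, j]
                b += [j] * table[i, j]
        res = weighted_kappa(a, b, n_categories=4)
        assert res.value == pytest.approx(0.8064516129032259, rel=1e-12)

    def test_matches_reference_implementation(self):
        metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(2)
        a = rng.integers(0, 4, 60)
        b = np.clip(a + rng.integers(-1, 2, 60), 0, 3)
        assert weighted_kappa(a, b, 4).value == pytest.approx(
            metrics.cohen_kappa_score(a, b, weights="quadratic"), rel=1e-12)

    def test_two_category_weighted_equals_unweighted(self):
        metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(6)
        a = rng.integers(0, 2, 50)
        b = rng.integers(0, 2, 50)
        assert weighted_kappa(a, b, 2).value == pytest.approx(
            metrics.cohen_kappa_score(a, b), rel=1e-12)

    def test_constant_identical_raters_defined_as_one(self):
        with pytest.warns(UserWarning):
            res = weighted_kappa([1, 1, 1], [1, 1, 1], n_categories=3)
        assert res.value == 1.0

    def test_icc_identical_columns_is_one(self):
        y = np.tile(np.array([3.0, 7.0, 5.0, 9.0])[:, None], (1, 2))
        assert icc_absolute(y).value == pytest.approx(1.0)

    def test_icc_fixture_matches_frozen_anova_oracle(self):
        y = np.array([[9., 10.], [6., 7.], [8., 9.],
                      [7., 9.], [10., 12.], [6., 8.]])
        res = icc_absolute(y)
        assert res.measure == "icc"
        assert res.value == pytest.approx(0.6808510638297874, rel=1e-9)

    def test_rater_offset_lowers_absolute_vs_consistency(self):
        # a constant inter-rater offset penalises absolute agreement but
        # not consistency: ICC(2,1) < ICC(3,1) on the same data
        y = np.array([[9., 10.], [6., 7.], [8., 9.],
                      [7., 9.], [10., 12.], [6., 8.]])
        assert icc_absolute(y).value < 0.9467455621301774  # frozen ICC(C,1)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            icc_absolute(np.ones((4, 2)))
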