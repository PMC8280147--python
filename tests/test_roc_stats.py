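import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import delong_variance_loops, pair_count_auc, trapezoid_area
from scipy.stats import norm

from validstab.roc_stats import (
    ScoredPredictions,
    accuracy_f1,
    auc,
    confusion_counts,
    delong_ci,
    delong_variance,
    hanley_mcneil_se,
    independent_roc_test,
    roc_curve,
)


def random_preds(rng, n_max=50):
    n1 = rng.integers(2, n_max // 2 + 1)
    n0 = rng.integers(2, n_max // 2 + 1)
    # coarse grid of score values forces plenty of ties
    scores = rng.choice(np.linspace(0, 1, 11), size=n1 + n0)
    y = np.r_[np.ones(n1, dtype=int), np.zeros(n0, dtype=int)]
    return ScoredPredictions(y, scores)


class TestAuc:
    def test_perfect_separation(self):
        preds = ScoredPredictions([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc(preds) == 1.0

    def test_all_ties(self):
        preds = ScoredPredictions([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert auc(preds) == 0.5

    def test_half_concordant(self):
        # pairs: (.2,.3) discordant, (.2,.6) d, (.9,.3) c, (.9,.6) c -> 2/4
        preds = ScoredPredictions([0, 1, 0, 1], [0.3, 0.2, 0.6, 0.9])
        assert auc(preds) == 0.5

    def test_matches_pair_count_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            preds = random_preds(rng)
            assert auc(preds) == pytest.approx(
                pair_count_auc(preds.y_true, preds.scores), abs=1e-12
            )

    def test_negate_and_flip_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            preds = random_preds(rng)
            flipped = ScoredPredictions(1 - preds.y_true, -preds.scores)
            assert auc(flipped) == pytest.approx(auc(preds), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc(ScoredPredictions([1, 1, 1], [0.1, 0.2, 0.3]))


class TestRocCurve:
    def test_perfect_passes_corner(self):
        preds = ScoredPredictions([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        pts = roc_curve(preds)
        assert any(np.allclose(p, [0.0, 1.0]) for p in pts)

    def test_endpoints(self):
        rng = np.random.default_rng(1)
        preds = random_preds(rng)
        pts = roc_curve(preds)
        assert np.allclose(pts[0], [0.0, 0.0])
        assert np.allclose(pts[-1], [1.0, 1.0])

    def test_all_ties_diagonal(self):
        preds = ScoredPredictions([0, 1, 0, 1], [0.3, 0.3, 0.3, 0.3])
        pts = roc_curve(preds)
        assert pts.shape == (2, 2)
        assert trapezoid_area(pts) == pytest.approx(0.5)

    def test_area_equals_auc(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            preds = random_preds(rng)
            assert trapezoid_area(roc_curve(preds)) == pytest.approx(
                auc(preds), abs=1e-12
            )


class TestDelong:
    def test_perfect_separation_zero_variance(self):
        preds = ScoredPredictions([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert delong_variance(preds) == 0.0

    def test_all_ties_zero_variance(self):
        preds = ScoredPredictions([0, 0, 1, 1], [0.5, 0.5, 0.5, 0.5])
        assert delong_variance(preds) == 0.0

    def test_matches_double_loop_oracle_small(self):
        preds = ScoredPredictions(
            [1, 1, 1, 1, 0, 0, 0, 0],
            [0.9, 0.7, 0.55, 0.3, 0.6, 0.5, 0.2, 0.1],
        )
        assert delong_variance(preds) == pytest.approx(
            delong_variance_loops(preds.y_true, preds.scores), abs=1e-14
        )

    def test_matches_double_loop_oracle_random(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            preds = random_preds(rng, n_max=30)
            assert delong_variance(preds) == pytest.approx(
                delong_variance_loops(preds.y_true, preds.scores), abs=1e-13
            )

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            delong_variance(ScoredPredictions([1, 0, 0], [0.9, 0.1, 0.2]))


class TestDelongCi:
    def test_degenerate_interval(self):
        preds = ScoredPredictions([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        est = delong_ci(preds)
        assert est.ci_low == est.ci_high == est.auc == 1.0

    def test_wald_arithmetic(self):
        # 0.5 +/- 1.959964 * 0.1 -> [0.304, 0.696]
        half = norm.ppf(0.975) * 0.1
        assert 0.5 - half == pytest.approx(0.30400, abs=5e-5)
        preds = ScoredPredictions([0, 1, 0, 1], [0.3, 0.2, 0.6, 0.9])
        est = delong_ci(preds, level=0.95)
        expected_half = norm.ppf(0.975) * np.sqrt(est.variance)
        assert est.ci_low == pytest.approx(max(0.0, est.auc - expected_half))
        assert est.ci_high == pytest.approx(min(1.0, est.auc + expected_half))

    def test_interval_brackets_auc_and_clips(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            preds = random_preds(rng)
            est = delong_ci(preds)
            assert 0.0 <= est.ci_low <= est.auc <= est.ci_high <= 1.0


class TestHanleyMcNeil:
    def test_perfect_auc_zero_se(self):
        assert hanley_mcneil_se(1.0, 8, 8) == 0.0

    def test_hand_computed_value(self):
        # A=0.5: Q1=Q2=1/3; numerator = 0.25 + 8 * (1/3 - 0.25) = 11/12
        expected = np.sqrt((11 / 12) / 25)
        assert hanley_mcneil_se(0.5, 5, 5) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("n_small,n_big", [(10, 50), (50, 100)])
    def test_decreases_with_n(self, n_small, n_big):
        assert hanley_mcneil_se(0.8, n_big, n_big) < hanley_mcneil_se(0.8, n_small, n_small)


class TestIndependentRocTest:
    def _preds(self, auc_target, n=10, seed=0):
        rng = np.random.default_rng(seed)
        mu = norm.ppf(auc_target) * np.sqrt(2)
        return ScoredPredictions(
            np.r_[np.ones(n, dtype=int), np.zeros(n, dtype=int)],
            np.r_[rng.normal(mu, 1, n), rng.normal(0, 1, n)],
        )

    def test_identical_inputs(self):
        p = self._preds(0.8, seed=1)
        cmp = independent_roc_test(p, p)
        assert cmp.z == 0.0
        assert cmp.p_two_sided == 1.0

    def test_swap_symmetry(self):
        a, b = self._preds(0.9, seed=2), self._preds(0.6, seed=3)
        fwd = independent_roc_test(a, b)
        rev = independent_roc_test(b, a)
        assert rev.z == pytest.approx(-fwd.z)
        assert rev.p_two_sided == pytest.approx(fwd.p_two_sided)

    def test_hand_computed_example(self):
        # A_a=0.9, A_b=0.6, n1=n0=10, Hanley-McNeil SEs -> z ~ 2.016, p ~ 0.044
        se_a = hanley_mcneil_se(0.9, 10, 10)
        se_b = hanley_mcneil_se(0.6, 10, 10)
        z = (0.9 - 0.6) / np.hypot(se_a, se_b)
        assert z == pytest.approx(2.02, abs=0.01)
        assert 2 * norm.sf(z) == pytest.approx(0.044, abs=0.001)
        # route the same AUCs through the public API with tie-free scores
        a = ScoredPredictions(
            np.r_[np.ones(10, int), np.zeros(10, int)],
            # 9 clean wins + one positive below all negatives = 90 of 100 pairs
            np.r_[np.linspace(0.6, 0.9, 9), [0.05], np.linspace(0.2, 0.5, 10)],
        )
        assert auc(a) == pytest.approx(0.9)

    def test_zero_se_equal_aucs(self):
        p = ScoredPredictions([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        cmp = independent_roc_test(p, p, method="delong")
        assert cmp.z == 0.0 and cmp.p_two_sided == 1.0

    def test_zero_se_unequal_aucs(self):
        a = ScoredPredictions([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        b = ScoredPredictions([0, 0, 1, 1], [0.8, 0.9, 0.1, 0.2])
        cmp = independent_roc_test(a, b, method="delong")
        assert np.isinf(cmp.z)
        assert cmp.p_two_sided == 0.0

    def test_p_is_two_sided_normal(self):
        a, b = self._preds(0.85, seed=4), self._preds(0.7, seed=5)
        cmp = independent_roc_test(a, b)
        assert cmp.p_two_sided == pytest.approx(2 * norm.sf(abs(cmp.z)))

    def test_unknown_method(self):
        p = self._preds(0.8, seed=6)
        with pytest.raises(ValueError):
            independent_roc_test(p, p, method="bogus")


class TestAccuracyF1:
    def test_perfect(self):
        preds = ScoredPredictions([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert accuracy_f1(preds) == (1.0, 1.0)

    def test_all_negative_zero_f1(self):
        preds = ScoredPredictions([0, 1, 1], [0.1, 0.2, 0.3])
        acc, f1 = accuracy_f1(preds, threshold=0.5)
        assert f1 == 0.0

    def test_hand_computed(self):
        preds = ScoredPredictions([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1])
        acc, f1 = accuracy_f1(preds, threshold=0.5)
        assert acc == 0.5 and f1 == 0.5

    def test_confusion_totals(self):
        preds = ScoredPredictions([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1])
        c = confusion_counts(preds, 0.5)
        assert c.tp + c.fn == 2 and c.fp + c.tn == 2


@given(
    st.lists(st.tuples(st.integers(0, 1), st.floats(0, 1)), min_size=4, max_size=40).filter(
        lambda rows: 0 < sum(r[0] for r in rows) < len(rows)
    )
)
@settings(max_examples=60, deadline=None)
def test_auc_property_matches_oracle(rows):
    y = np.array([r[0] for r in rows])
    s = np.array([r[1] for r in rows])
    preds = ScoredPredictions(y, s)
    assert auc(preds) == pytest.approx(pair_count_auc(y, s), abs=1e-12)
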