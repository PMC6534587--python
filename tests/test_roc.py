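"""ROC curves, AUC/U equivalence, Youden cutoffs, Gaussian oracle."""

import numpy as np
import pytest
from scipy import stats as sps

from fvquant import (
    auc_trapezoid,
    gaussian_auc_oracle,
    mann_whitney_auc,
    roc_points,
    stage_comparison,
    youden_cutoff,
)


class TestRocCurve:
    def test_identical_groups_diagonal(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        c = roc_points(v, v)
        assert np.allclose(c.tpr, c.fpr)
        assert auc_trapezoid(c) == pytest.approx(0.5)

    def test_separated_groups_through_corner(self):
        c = roc_points([3.0, 4.0], [1.0, 2.0])
        assert any((f == 0.0) and (t == 1.0) for f, t in zip(c.fpr, c.tpr))
        assert auc_trapezoid(c) == pytest.approx(1.0)

    def test_curve_endpoints(self):
        rng = np.random.default_rng(0)
        c = roc_points(rng.normal(1, 1, 30), rng.normal(0, 1, 30))
        assert (c.fpr[0], c.tpr[0]) == (0.0, 0.0)
        assert (c.fpr[-1], c.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(c.fpr) >= 0) and np.all(np.diff(c.tpr) >= 0)

    def test_u_statistic_oracle_small_case(self):
        # {1,2} vs {3,4}: lesion side lower, direction auto -> AUC 1.0 = U/(n1 n2)
        c = roc_points([1.0, 2.0], [3.0, 4.0])
        u = sps.mannwhitneyu([3.0, 4.0], [1.0, 2.0], alternative="two-sided").statistic
        assert auc_trapezoid(c) == pytest.approx(u / 4.0) == pytest.approx(1.0)
        assert c.direction == -1

    def test_auc_equals_tie_corrected_u_on_random_instances(self):
        # 1000 small instances with heavy ties
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n1, n2 = rng.integers(1, 9, size=2)
            x = rng.integers(0, 8, size=n1).astype(float)
            y = rng.integers(0, 8, size=n2).astype(float)
            c = roc_points(x, y, direction=1)
            assert auc_trapezoid(c) == pytest.approx(mann_whitney_auc(x, y), abs=1e-12)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 40), rng.normal(0.5, 1, 40)
        a_xy = auc_trapezoid(roc_points(x, y, direction=1))
        a_yx = auc_trapezoid(roc_points(y, x, direction=1))
        assert a_xy + a_yx == pytest.approx(1.0)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        x, y = rng.normal(1, 2, 100), rng.normal(0, 1, 120)
        c = roc_points(x, y, direction=1)
        ref = roc_auc_score([1] * 100 + [0] * 120, np.concatenate([x, y]))
        assert auc_trapezoid(c) == pytest.approx(ref, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            roc_points([], [1.0])


class TestYouden:
    def test_separated_cutoff_inside_gap(self):
        c = roc_points([20.0, 21.0], [10.0, 11.0])
        y = youden_cutoff(c)
        assert 11.0 < y.cutoff <= 20.0
        assert y.youden_j == pytest.approx(1.0)
        assert not y.degenerate

    def test_identical_groups_degenerate(self):
        v = np.array([5.0, 6.0, 7.0])
        y = youden_cutoff(roc_points(v, v))
        assert y.degenerate
        assert y.youden_j == pytest.approx(0.0, abs=1e-9)

    def test_gaussian_classes_cutoff_near_density_intersection(self):
        # Control-like vs LGD-like Gaussians; oracle = grid search over the
        # closed-form Youden index Phi((t-mu1)/sd1) - Phi((t-mu2)/sd2)
        mu1, sd1, mu2, sd2 = 32.5, 4.02, 54.6, 8.40
        grid = np.linspace(20, 70, 5001)
        j = (1 - sps.norm.cdf(grid, mu2, sd2)) - (1 - sps.norm.cdf(grid, mu1, sd1))
        t_star = grid[np.argmax(j)]
        rng = np.random.default_rng(11)
        y = youden_cutoff(
            roc_points(rng.normal(mu2, sd2, 20000), rng.normal(mu1, sd1, 20000))
        )
        assert y.cutoff == pytest.approx(t_star, abs=2.0)
        assert 38.0 <= y.cutoff <= 42.0


class TestStageComparison:
    def test_group_vs_itself_auc_half(self):
        g = {"A": np.array([1.0, 2.0, 3.0])}
        (c,) = stage_comparison(g, [("A vs A", ["A"], ["A"])])
        assert c.auc == pytest.approx(0.5)
        assert c.degenerate

    def test_brute_force_threshold_enumeration(self):
        # exhaustive check of cutoff/sens/spec on 3 values per group
        pos, neg = np.array([5.0, 7.0, 9.0]), np.array([4.0, 6.0, 6.0])
        (c,) = stage_comparison({"P": pos, "N": neg}, [("P vs N", ["P"], ["N"])])
        best = (-1.0, None)
        for t in np.arange(3.5, 10.0, 0.5):
            tpr = (pos >= t).mean()
            fpr = (neg >= t).mean()
            if tpr - fpr > best[0] + 1e-12:
                best = (tpr - fpr, t, tpr, fpr)
        assert c.auc == pytest.approx(mann_whitney_auc(pos, neg))
        assert c.sensitivity == pytest.approx(best[2] * 100)
        assert c.specificity == pytest.approx((1 - best[3]) * 100)
        assert (pos >= c.cutoff).mean() == pytest.approx(best[2])

    def test_pooled_positive_class_union(self):
        g = {"A": [1.0, 2.0], "B": [8.0, 9.0], "C": [10.0, 11.0]}
        (c,) = stage_comparison(g, [("A vs B, C", ["B", "C"], ["A"])])
        assert c.n_pos == 4 and c.n_neg == 2
        assert c.auc == pytest.approx(1.0)

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError, match="unknown stage"):
            stage_comparison({"A": [1.0]}, [("A vs B", ["B"], ["A"])])


class TestGaussianOracle:
    def test_equal_means_half(self):
        assert gaussian_auc_oracle(10, 2, 10, 3) == pytest.approx(0.5)

    def test_published_control_lgd_parameters(self):
        # mu diff 22.1, total SDs 4.02 and 8.40 -> Phi(2.373) ~ 0.991
        assert gaussian_auc_oracle(32.5, 4.02, 54.6, 8.40) == pytest.approx(0.991, abs=5e-4)

    def test_degenerate_limit_one(self):
        assert gaussian_auc_oracle(0, 0, 50, 0) == 1.0
        assert gaussian_auc_oracle(0, 1e-9, 50, 0) == pytest.approx(1.0)

    def test_both_sds_zero_equal_means_rejected(self):
        with pytest.raises(ValueError):
            gaussian_auc_oracle(5, 0, 5, 0)

    def test_empirical_auc_converges_to_oracle(self):
        # two-layer generator marginal (between + within), 10^4 px/class
        rng = np.random.default_rng(3)
        n = 10_000
        ctrl = rng.normal(32.5, 3.2, n) + rng.normal(0, 2.43, n)
        lgd = rng.normal(54.6, 7.5, n) + rng.normal(0, 3.79, n)
        emp = mann_whitney_auc(lgd, ctrl)
        oracle = gaussian_auc_oracle(
            32.5, np.hypot(3.2, 2.43), 54.6, np.hypot(7.5, 3.79)
        )
        # Hanley-McNeil SE at this AUC and n
        a = oracle
        q1, q2 = a / (2 - a), 2 * a**2 / (1 + a)
        se = np.sqrt(
            (a * (1 - a) + (n - 1) * (q1 - a**2) + (n - 1) * (q2 - a**2)) / (n * n)
        )
        assert abs(emp - oracle) < 3 * se
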