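import math

import numpy as np
import pytest

from dielbal import (
    PredictionSet,
    UndefinedCorrelationError,
    bootstrap_metric,
    dynamic_range,
    error_profile,
    error_stats,
    evaluate,
    kendall_tau,
    pearson_r,
)


def ps_from(pred, exp):
    ids = [f"S{i}" for i in range(len(pred))]
    return PredictionSet.from_arrays(ids, pred, exp)


def kendall_tau_b_bruteforce(x, y):
    """O(n^2) pair enumeration of tau-b, the independent oracle."""
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                ties_x += 1
                ties_y += 1
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - ties_x) * (n0 - ties_y))
    return (concordant - discordant) / denom


class TestErrorStats:
    def test_perfect_predictions(self):
        assert error_stats(ps_from([1, 2, 3], [1, 2, 3])) == (0.0, 0.0, 0.0)

    def test_hand_computed_three_point_set(self):
        mse, aue, rmse = error_stats(ps_from([1.0, -1.0, 2.0], [0.0, 0.0, 0.0]))
        assert mse == pytest.approx(2.0 / 3.0)
        assert aue == pytest.approx(4.0 / 3.0)
        assert rmse == pytest.approx(math.sqrt(2.0))

    @pytest.mark.parametrize("seed", range(10))
    def test_ordering_inequalities(self, seed):
        rng = np.random.default_rng(seed)
        mse, aue, rmse = error_stats(ps_from(rng.normal(size=20), rng.normal(size=20)))
        assert rmse >= aue >= abs(mse)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        p, e = rng.normal(size=15), rng.normal(size=15)
        base = error_stats(ps_from(p, e))
        scaled = error_stats(ps_from(3.0 * p, 3.0 * e))
        for a, b in zip(base, scaled):
            assert b == pytest.approx(3.0 * a)


class TestCorrelations:
    def test_affine_relation_gives_unit_pearson(self):
        e = np.array([-2.0, -1.0, 0.0, 1.5, 3.0])
        assert pearson_r(ps_from(2.0 * e + 1.0, e)) == pytest.approx(1.0)
        assert pearson_r(ps_from(-e, e)) == pytest.approx(-1.0)

    def test_pearson_matches_direct_formula(self):
        rng = np.random.default_rng(7)
        p, e = rng.normal(size=5), rng.normal(size=5)
        direct = np.mean((p - p.mean()) * (e - e.mean())) / (p.std() * e.std())
        assert pearson_r(ps_from(p, e)) == pytest.approx(direct, abs=1e-12)

    def test_zero_variance_raises_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r(ps_from([0.0, 0.0, 0.0], [1.0, 2.0, 3.0]))
        with pytest.raises(UndefinedCorrelationError):
            kendall_tau(ps_from([0.0, 0.0], [1.0, 2.0]))

    def test_kendall_identical_order(self):
        assert kendall_tau(ps_from([1, 2, 3, 4], [10, 20, 30, 40])) == pytest.approx(1.0)

    def test_kendall_one_adjacent_swap(self):
        # 3 pairs: 2 concordant, 1 discordant -> tau = 1/3
        assert kendall_tau(ps_from([1, 3, 2], [1, 2, 3])) == pytest.approx(1.0 / 3.0)

    @pytest.mark.parametrize("seed", range(30))
    def test_kendall_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        # half-integer grid forces ties in both columns
        p = rng.integers(0, 6, size=10) / 2.0
        e = rng.integers(0, 6, size=10) / 2.0
        if np.ptp(p) == 0 or np.ptp(e) == 0:
            pytest.skip("degenerate draw")
        assert kendall_tau(ps_from(p, e)) == pytest.approx(
            kendall_tau_b_bruteforce(p, e), abs=1e-12
        )

    def test_scale_invariance(self):
        rng = np.random.default_rng(11)
        p, e = rng.normal(size=12), rng.normal(size=12)
        assert pearson_r(ps_from(4 * p, 4 * e)) == pytest.approx(
            pearson_r(ps_from(p, e)), abs=1e-12
        )
        assert kendall_tau(ps_from(4 * p, 4 * e)) == pytest.approx(
            kendall_tau(ps_from(p, e)), abs=1e-12
        )


class TestBootstrap:
    def test_zero_error_predictions_have_zero_spread(self):
        e = np.linspace(-4, 3, 20)
        _, std = bootstrap_metric(ps_from(e, e), "mse", n_boot=200, seed=1)
        assert std == 0.0

    def test_determinism_under_seed(self):
        rng = np.random.default_rng(5)
        ps = ps_from(rng.normal(size=15), rng.normal(size=15))
        a = bootstrap_metric(ps, "rmse", n_boot=300, seed=42)
        b = bootstrap_metric(ps, "rmse", n_boot=300, seed=42)
        assert a == b
        c = bootstrap_metric(ps, "rmse", n_boot=300, seed=43)
        assert a != c

    def test_mse_spread_matches_standard_error(self):
        # n=53 iid Gaussian errors, sigma=2.2: bootstrap stddev ~ sigma/sqrt(53) ~ 0.30
        sigma, n = 2.2, 53
        expected = sigma / math.sqrt(n)
        stds = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            e = rng.uniform(-4, 3, size=n)
            p = e + rng.normal(0, sigma, size=n)
            _, std = bootstrap_metric(ps_from(p, e), "mse", n_boot=200, seed=seed)
            stds.append(std)
        assert np.mean(stds) == pytest.approx(expected, rel=0.2)

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="unknown metric"):
            bootstrap_metric(ps_from([1, 2], [1, 2]), "mae", n_boot=100, seed=0)

    def test_small_n_boot_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_metric(ps_from([1, 2], [1, 2]), "mse", n_boot=10, seed=0)


class TestErrorProfile:
    def test_sorted_by_experimental_then_id(self):
        ps = PredictionSet.from_arrays(
            ["b", "a", "c"], [1.0, 2.0, 3.0], [0.5, 0.5, -1.0]
        )
        prof = error_profile(ps)
        assert [r[0] for r in prof] == ["c", "a", "b"]

    def test_positive_error_slope_sign_pattern(self):
        # predictions exaggerate the trend: errors negative at low logD,
        # positive at high logD
        e = np.linspace(-4, 3, 21)
        p = 2.0 * e  # slope 2, no bias
        prof = error_profile(ps_from(p, e))
        errors = [r[2] for r in prof]
        assert all(x < 0 for x in errors[:8])
        assert all(x > 0 for x in errors[-8:])


class TestDynamicRange:
    @pytest.mark.parametrize(
        "values, expected",
        [([-4.0, 3.0], 7.0), ([2.0, 2.0, 2.0], 0.0), ([1.5, -2.5, 0.0], 4.0)],
    )
    def test_max_minus_min(self, values, expected):
        assert dynamic_range(values) == pytest.approx(expected)


class TestEvaluate:
    def test_perfect_predictions_report(self):
        e = np.linspace(-4, 3, 10)
        rep = evaluate(ps_from(e, e), n_boot=200, seed=0)
        assert rep.mse == rep.aue == rep.rmse == 0.0
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.ols_slope == pytest.approx(1.0)
        assert rep.ols_intercept == pytest.approx(0.0, abs=1e-9)

    def test_null_baseline_report(self):
        e = np.array([-3.0, -1.0, 0.5, 2.0, 3.0])
        rep = evaluate(ps_from(np.zeros_like(e), e), n_boot=200, seed=0)
        assert rep.aue == pytest.approx(np.abs(e).mean())
        assert rep.rmse == pytest.approx(np.sqrt((e**2).mean()))
        assert rep.pearson_r is None
        assert rep.kendall_tau is None
        assert rep.dynamic_range_pred == 0.0

    def test_known_slope_and_bias_recovered(self):
        rng = np.random.default_rng(2)
        e = rng.uniform(-4, 3, size=40)
        p = 1.0 + 2.0 * e
        rep = evaluate(ps_from(p, e), n_boot=200, seed=0)
        assert rep.ols_slope == pytest.approx(2.0, abs=1e-9)
        assert rep.mse == pytest.approx(1.0 + np.mean(e), abs=1e-9)

    def test_report_serializes_to_json_dict(self):
        rng = np.random.default_rng(4)
        rep = evaluate(ps_from(rng.normal(size=8), rng.normal(size=8)), n_boot=200, seed=0)
        d = rep.to_dict()
        assert set(d["bootstrap"]) == {"mse", "aue", "rmse"}
        assert d["n"] == 8
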