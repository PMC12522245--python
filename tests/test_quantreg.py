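"""Quantile regression: exact-LP optimality against brute-force oracles."""

import itertools

import numpy as np
import pytest

from pasenorm import quantreg as qr
from pasenorm.quantreg import (QuantRegBasis, QuantRegSpec,
                               expand_fractional_polynomial,
                               fit_quantile, fit_smoothed_additive_quantile,
                               pinball_loss, rearrange_noncrossing)


def brute_force_loss(X, y, w, tau):
    """Optimal pinball loss by enumeration: some optimum of the quantile LP
    interpolates p observations, so searching all size-p subsets of points
    (plus all single-point flats for p=1 designs) is exhaustive."""
    n, p = X.shape
    best = np.inf
    for idx in itertools.combinations(range(n), p):
        A = X[list(idx)]
        if abs(np.linalg.det(A)) < 1e-12:
            continue
        beta = np.linalg.solve(A, y[list(idx)])
        best = min(best, pinball_loss(y - X @ beta, tau, w))
    return best


class TestFitQuantile:
    def test_intercept_median_is_sample_median(self):
        beta, loss = fit_quantile([1, 2, 3, 4, 5], [1.0, 2, 3, 4, 5],
                                  basis=QuantRegBasis("intercept"), tau=0.5)
        assert beta[0] == 3.0
        assert loss == pytest.approx(3.0)  # |1-3|+|2-3|+|4-3|+|5-3| halved at tau=.5

    def test_exact_linear_data_zero_loss(self):
        age = np.array([46.0, 52, 60, 71, 84])
        beta, loss = fit_quantile(age, 2 * age, basis=QuantRegBasis("linear"),
                                  tau=0.3)
        assert loss == pytest.approx(0.0, abs=1e-8)
        pred = QuantRegBasis("linear").design(np.array([60.0])) @ beta
        assert pred[0] == pytest.approx(120.0, abs=1e-8)

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("kind", ["intercept", "linear"])
    def test_matches_enumeration_oracle_small_instances(self, seed, kind):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 9)
        age = np.sort(rng.uniform(45, 85, n))
        y = rng.normal(100, 30, n)
        w = rng.uniform(0.5, 2.0, n)
        tau = rng.choice([0.1, 0.25, 0.5, 0.75, 0.9])
        basis = QuantRegBasis(kind)
        beta, loss = fit_quantile(age, y, w, basis, tau)
        oracle = brute_force_loss(basis.design(age), y, w, tau)
        assert loss == pytest.approx(oracle, abs=1e-6)

    def test_residual_fraction_below_within_discreteness(self, rng):
        y = rng.normal(size=201)
        for tau in (0.1, 0.5, 0.9):
            beta, _ = fit_quantile(np.arange(201.0) / 4 + 45, y,
                                   basis=QuantRegBasis("intercept"), tau=tau)
            frac = np.mean(y < beta[0])
            assert abs(frac - tau) <= 1.0 / len(y) + 1e-12

    def test_integer_weight_equals_replication(self, rng):
        age = rng.uniform(45, 85, 30)
        y = rng.normal(150, 40, 30)
        w = rng.integers(1, 4, 30).astype(float)
        b1, _ = fit_quantile(age, y, w, QuantRegBasis("linear"), 0.5)
        rep = np.repeat(np.arange(30), w.astype(int))
        b2, _ = fit_quantile(age[rep], y[rep], None, QuantRegBasis("linear"), 0.5)
        X = QuantRegBasis("linear").design(np.array([50.0, 70.0]))
        np.testing.assert_allclose(X @ b1, X @ b2, atol=1e-6)

    def test_collinear_columns_named(self):
        age = np.full(6, 60.0)  # constant age makes the slope collinear
        with pytest.raises(ValueError, match="age"):
            fit_quantile(age, np.arange(6.0), basis=QuantRegBasis("linear"))

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError, match="tau"):
            fit_quantile([45.0, 50], [1.0, 2], tau=1.0)


class TestFractionalPolynomial:
    def test_power_one_is_scaled_identity(self):
        ages = np.array([45.0, 65.0, 85.0])
        M = expand_fractional_polynomial(ages, (1.0,))
        np.testing.assert_allclose(M[:, 0], ages / 10.0)

    def test_power_zero_is_log(self):
        M = expand_fractional_polynomial(np.array([10.0 * np.e]), (0.0,))
        assert M[0, 0] == pytest.approx(1.0)

    def test_repeated_power_convention(self):
        ages = np.array([45.0, 60.0, 85.0])
        M = expand_fractional_polynomial(ages, (1.0, 1.0))
        x = ages / 10.0
        np.testing.assert_allclose(M, np.column_stack([x, x * np.log(x)]))

    def test_nonpositive_age_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            expand_fractional_polynomial(np.array([-1.0]), (1.0,))

    def test_unconventional_power_rejected(self):
        with pytest.raises(ValueError, match="conventional"):
            expand_fractional_polynomial(np.array([50.0]), (1.5,))


class TestSmoothedAdditive:
    def test_huge_penalty_recovers_linear_fit(self, rng):
        age = rng.uniform(45, 85, 150)
        y = 300 - 3 * age + 20 * np.sin(age / 5) + rng.normal(0, 5, 150)
        knots, theta, loss_s = fit_smoothed_additive_quantile(
            age, y, tau=0.5, penalty=1e8)
        beta, loss_l = fit_quantile(age, y, basis=QuantRegBasis("linear"), tau=0.5)
        grid = np.linspace(46, 84, 20)
        lin = QuantRegBasis("linear").design(grid) @ beta
        smooth = np.interp(grid, knots, theta)
        np.testing.assert_allclose(smooth, lin, atol=1e-4)

    def test_zero_penalty_interpolates_small_data(self):
        age = np.array([45.0, 55, 65, 75, 85])
        y = np.array([200.0, 120, 160, 90, 70])
        knots, theta, loss = fit_smoothed_additive_quantile(age, y, tau=0.5,
                                                           penalty=0.0)
        assert loss == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(np.interp(age, knots, theta), y, atol=1e-6)

    def test_decreasing_truth_gives_decreasing_fit(self, rng):
        age = rng.uniform(45, 85, 2000)
        y = 400 - 2.5 * age + rng.normal(0, 20, 2000)
        knots, theta, _ = fit_smoothed_additive_quantile(age, y, tau=0.5,
                                                        penalty=50.0)
        assert np.all(np.diff(theta) < 0)

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError, match="penalty"):
            fit_smoothed_additive_quantile([45.0, 50], [1.0, 2], penalty=-1.0)


class TestRearrangement:
    def test_monotone_input_unchanged(self):
        curves = {0.05: np.array([1.0, 2]), 0.5: np.array([3.0, 4]),
                  0.95: np.array([5.0, 6])}
        out = rearrange_noncrossing(curves)
        for t in curves:
            np.testing.assert_array_equal(out[t], curves[t])

    def test_crossed_constants_swapped(self):
        out = rearrange_noncrossing({0.05: np.full(3, 10.0),
                                     0.95: np.full(3, 5.0)})
        np.testing.assert_array_equal(out[0.05], np.full(3, 5.0))
        np.testing.assert_array_equal(out[0.95], np.full(3, 10.0))

    def test_equals_per_age_sort_oracle(self, rng):
        taus = [0.1, 0.5, 0.9]
        raw = {t: rng.normal(size=15) for t in taus}
        out = rearrange_noncrossing(raw)
        stacked = np.vstack([raw[t] for t in taus])
        want = np.sort(stacked, axis=0)
        for i, t in enumerate(taus):
            np.testing.assert_array_equal(out[t], want[i])

    def test_never_increases_total_pinball_loss(self, rng):
        """Rearranged curves fit the data at least as well in total check
        loss (the classic rearrangement improvement)."""
        age = np.linspace(45, 85, 41)
        y = rng.normal(150 - 2 * (age - 45), 30)
        taus = (0.2, 0.5, 0.8)
        raw = {t: 150 - 2 * (age - 45) + rng.normal(0, 25, 41) for t in taus}
        out = rearrange_noncrossing(raw)
        before = sum(pinball_loss(y - raw[t], t) for t in taus)
        after = sum(pinball_loss(y - out[t], t) for t in taus)
        assert after <= before + 1e-9


class TestQuantRegSpec:
    def test_fit_predict_and_serialization_round_trip(self, rng, tmp_path):
        age = rng.uniform(45, 85, 400)
        y = 300 - 2 * age + rng.normal(0, 15, 400)
        spec = QuantRegSpec(QuantRegBasis("polynomial", order=2),
                            taus=(0.05, 0.5, 0.95))
        fitted = spec.fit(age, y)
        ages = np.arange(45.0, 86.0)
        p = tmp_path / "m.json"
        fitted.to_json(p)
        back = qr.QuantileModelSet.from_json(p)
        for t in (0.05, 0.5, 0.95):
            np.testing.assert_array_equal(fitted.centile_curve(ages, t),
                                          back.centile_curve(ages, t))
        # quantile ordering after rearrangement
        assert np.all(fitted.centile_curve(ages, 0.05)
                      <= fitted.centile_curve(ages, 0.95))

    def test_unfitted_tau_rejected(self, rng):
        spec = QuantRegSpec(QuantRegBasis("linear"), taus=(0.5,))
        fitted = spec.fit(rng.uniform(45, 85, 50), rng.normal(size=50))
        with pytest.raises(KeyError):
            fitted.centile(60.0, 0.25)
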