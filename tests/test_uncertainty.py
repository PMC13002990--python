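"""Penalized profile bounds and prediction bands against closed-form oracles."""

import numpy as np
import pytest

import alcotwin as at
from alcotwin.inference import EstimationConfig
from alcotwin.uncertainty import (InfeasibleStartError, _penalty,
                                  penalized_extremum)

CHI2_1DF = 3.8414588206941245  # 95% quantile, 1 degree of freedom


class TestPenalty:
    def test_zero_inside_feasible_region(self):
        for cost in (0.0, 1.0, 10.0):
            assert _penalty(5.0, 5.0, cost, threshold=10.0) == 0.0

    def test_positive_and_growing_outside(self):
        p1 = _penalty(5.0, 5.0, 11.0, threshold=10.0)
        p2 = _penalty(5.0, 5.0, 20.0, threshold=10.0)
        assert 0 < p1 < p2
        assert p1 == pytest.approx(abs(5.0) + abs(5.0) * (1 + 1.0))


class TestQuadraticToy:
    """V(θ) = (θ-1)² with the 1-df χ² threshold: bounds are 1 ± √T."""

    def _bound(self, direction, seed=1):
        val, x, cost = penalized_extremum(
            property_fn=lambda x: x[0],
            cost_fn=lambda x: (x[0] - 1.0) ** 2,
            bounds=[(-10.0, 10.0)], x0=np.array([1.0]),
            threshold=CHI2_1DF, direction=direction, seed=seed)
        return val, cost

    def test_lower_crossing(self):
        val, cost = self._bound("min")
        assert val == pytest.approx(1.0 - np.sqrt(CHI2_1DF), abs=1e-2)
        assert cost <= CHI2_1DF * 1.001

    def test_upper_crossing(self):
        val, cost = self._bound("max")
        assert val == pytest.approx(1.0 + np.sqrt(CHI2_1DF), abs=1e-2)

    def test_min_bound_below_best(self):
        val, _ = self._bound("min")
        assert val <= 1.0

    def test_monotone_in_threshold(self):
        """A wider threshold never narrows the feasible interval."""
        widths = []
        for thr in (1.0, CHI2_1DF, 9.0):
            lo, _, _ = penalized_extremum(lambda x: x[0],
                                          lambda x: (x[0] - 1.0) ** 2,
                                          [(-10, 10)], np.array([1.0]),
                                          thr, "min", seed=2)
            hi, _, _ = penalized_extremum(lambda x: x[0],
                                          lambda x: (x[0] - 1.0) ** 2,
                                          [(-10, 10)], np.array([1.0]),
                                          thr, "max", seed=2)
            widths.append(hi - lo)
        assert widths[0] <= widths[1] + 1e-6 <= widths[2] + 2e-6

    def test_agrees_with_grid_search(self):
        """The relaxation matches hard-constrained brute force on a grid."""
        grid = np.linspace(-10, 10, 20001)
        feasible = grid[(grid - 1.0) ** 2 <= CHI2_1DF]
        lo, _, _ = penalized_extremum(lambda x: x[0],
                                      lambda x: (x[0] - 1.0) ** 2,
                                      [(-10, 10)], np.array([1.0]),
                                      CHI2_1DF, "min", seed=3)
        assert lo == pytest.approx(feasible.min(), abs=2e-3)

    def test_infeasible_start_raises(self):
        with pytest.raises(InfeasibleStartError):
            penalized_extremum(lambda x: x[0], lambda x: (x[0] - 1.0) ** 2,
                               [(-10, 10)], np.array([9.0]),
                               threshold=CHI2_1DF, direction="min", seed=1)


# frozen 5-point synthetic design for the straight-line model y = a t + b
LIN_T = np.array([0.0, 60.0, 120.0, 180.0, 240.0])
LIN_Y = np.array([1.02, 3.98, 7.10, 9.94, 13.05])
LIN_SEM = np.full(5, 0.2)


def _linear_cost(theta):
    resid = (LIN_Y - (theta[0] * LIN_T + theta[1])) / LIN_SEM
    return float(resid @ resid)


def _linear_envelope_oracle(threshold):
    """Closed-form profile envelope for the weighted linear model.

    With quadratic cost V = V_min + (θ-θ̂)ᵀH(θ-θ̂), the extremal prediction
    at x = (t, 1) under V ≤ T is ŷ(t) ± sqrt((T - V_min)·xᵀH⁻¹x).
    """
    X = np.column_stack([LIN_T, np.ones_like(LIN_T)])
    W = np.diag(1.0 / LIN_SEM ** 2)
    H = X.T @ W @ X
    theta_hat = np.linalg.solve(H, X.T @ W @ LIN_Y)
    v_min = _linear_cost(theta_hat)
    radius = threshold - v_min
    best = X @ theta_hat
    half = np.sqrt(radius * np.einsum("ij,jk,ik->i", X, np.linalg.inv(H), X))
    return theta_hat, best - half, best + half


class TestLinearModelBand:
    def test_band_matches_analytic_envelope(self):
        """Per-point penalized optimization reproduces the closed-form
        profile envelope of a straight-line fit within 2%."""
        threshold = float(at.chi2_threshold(0.05, len(LIN_T)))
        theta_hat, lo_ref, hi_ref = _linear_envelope_oracle(threshold)
        bounds = [(-1.0, 1.0), (-20.0, 20.0)]
        for j, t in enumerate(LIN_T):
            def prop(x, tt=t):
                return float(x[0] * tt + x[1])
            lo, _, _ = penalized_extremum(prop, _linear_cost, bounds,
                                          theta_hat, threshold, "min", seed=4,
                                          maxiter=120, popsize=20)
            hi, _, _ = penalized_extremum(prop, _linear_cost, bounds,
                                          theta_hat, threshold, "max", seed=4,
                                          maxiter=120, popsize=20)
            assert lo == pytest.approx(lo_ref[j], rel=0.02, abs=0.02)
            assert hi == pytest.approx(hi_ref[j], rel=0.02, abs=0.02)

    def test_band_contains_best_fit(self):
        threshold = float(at.chi2_threshold(0.05, len(LIN_T)))
        theta_hat, lo_ref, hi_ref = _linear_envelope_oracle(threshold)
        best = theta_hat[0] * LIN_T + theta_hat[1]
        assert np.all(lo_ref <= best) and np.all(best <= hi_ref)


class TestModelBands:
    @pytest.fixture(scope="class")
    def calibration(self, male, params):
        sched = at.build_wang_protocol(male.weight)
        return at.generate_study(sched, male, params, seed=21,
                                 sampling=at.SamplingPlan(end=300.0),
                                 noise=at.NoiseModel(sem_mode="known"))

    def test_ensemble_band_envelopes_best_fit(self, calibration, male, params):
        thr = at.chi2_threshold(0.05, len(calibration))
        sched = at.build_wang_protocol(male.weight)
        t_grid = np.arange(0.0, 361.0, 30.0)
        band = at.ensemble_band(calibration, "yEtOH", t_grid, thr, sched, male,
                                ("VmaxADH", "k_EtOHuptake"), params,
                                EstimationConfig(seed=5))
        assert np.all(band.lower <= band.best + 1e-12)
        assert np.all(band.best <= band.upper + 1e-12)
        assert np.all(band.width >= 0)
        # the constraint actually admits more than the best fit
        assert band.width.max() > 0

    def test_ensemble_band_deterministic_given_seed(self, calibration, male,
                                                    params):
        thr = at.chi2_threshold(0.05, len(calibration))
        sched = at.build_wang_protocol(male.weight)
        t_grid = np.arange(0.0, 361.0, 60.0)
        kwargs = dict(n_draws=20)
        b1 = at.ensemble_band(calibration, "yEtOH", t_grid, thr, sched, male,
                              ("VmaxADH",), params, EstimationConfig(seed=9),
                              **kwargs)
        b2 = at.ensemble_band(calibration, "yEtOH", t_grid, thr, sched, male,
                              ("VmaxADH",), params, EstimationConfig(seed=9),
                              **kwargs)
        assert np.array_equal(b1.lower, b2.lower)
        assert np.array_equal(b1.upper, b2.upper)

    def test_optimized_prediction_band_on_dataset(self, calibration, male,
                                                  params):
        """The per-point penalized band on the simulator itself envelopes
        the best-fit prediction with non-trivial width."""
        thr = at.chi2_threshold(0.05, len(calibration))
        sched = at.build_wang_protocol(male.weight)
        t_grid = np.array([60.0, 180.0])
        band = at.prediction_band(calibration, "yEtOH", t_grid, thr,
                                  schedule=sched, anthro=male,
                                  free_names=("VmaxADH",), base_params=params,
                                  config=EstimationConfig(seed=3, budget=8,
                                                          popsize=6),
                                  method="optimize")
        assert np.all(band.lower <= band.best + 1e-12)
        assert np.all(band.best <= band.upper + 1e-12)
        assert band.width.max() > 0

    def test_profile_parameter_bound_brackets_truth(self, calibration, params):
        thr = at.chi2_threshold(0.05, len(calibration))
        bound = at.parameter_bounds(
            calibration, "VmaxADH", thr, base_params=params,
            config=EstimationConfig(seed=7, budget=15, popsize=8))
        assert bound.lower <= params["VmaxADH"] <= bound.upper
        assert bound.lower < bound.upper
        tol = thr * 1.001
        assert bound.lower_cost <= tol and bound.upper_cost <= tol
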