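"""Maximum-entropy reweighting: dual optimization, θ scan, data preparation."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from idpre.bme import (
    PRETable,
    build_error_model,
    chi2,
    fit_weights,
    smooth_experimental,
    state_contributions,
    theta_scan,
)


class TestFitWeights:
    def test_two_frame_analytic_oracle(self):
        # max-entropy weights matching mean 40 from frames (10, 50): (1/4, 3/4)
        r = fit_weights(
            np.array([[10.0, 50.0]]), np.array([40.0]), np.array([1.0]), 1e-8
        )
        assert np.allclose(r.weights, [0.25, 0.75], atol=1e-6)

    def test_large_theta_returns_priors(self):
        priors = np.array([0.2, 0.3, 0.5])
        r = fit_weights(
            np.array([[10.0, 50.0, 90.0]]), np.array([80.0]), np.array([1.0]),
            1e9, priors=priors,
        )
        assert np.allclose(r.weights, priors, atol=1e-5)

    def test_consistent_data_keeps_prior_and_zero_chi2(self):
        # target equals the prior-weighted average: lambda = 0 is optimal
        mat = np.array([[10.0, 30.0], [5.0, 15.0]])
        target = mat @ np.array([0.5, 0.5])
        r = fit_weights(mat, target, np.ones(2), 1.0)
        assert np.allclose(r.weights, [0.5, 0.5], atol=1e-8)
        assert r.chi2 < 1e-12
        assert np.allclose(r.lambdas, 0.0, atol=1e-6)

    def test_three_frame_single_constraint_matches_brentq_oracle(self):
        # independent 1-D solve of the max-entropy condition <G>_lam = target
        g = np.array([[5.0, 20.0, 65.0]])
        target = 30.0

        def avg(lam):
            w = np.exp(-lam * g[0])
            w /= w.sum()
            return float(g[0] @ w) - target

        lam_star = brentq(avg, -5, 5, xtol=1e-14)
        w_star = np.exp(-lam_star * g[0])
        w_star /= w_star.sum()
        r = fit_weights(g, np.array([target]), np.array([1.0]), 1e-9)
        assert np.allclose(r.weights, w_star, atol=1e-6)

    def test_weights_nonnegative_and_normalized(self):
        rng = np.random.default_rng(1)
        mat = rng.uniform(0, 100, size=(6, 40))
        target = rng.uniform(20, 80, size=6)
        r = fit_weights(mat, target, np.full(6, 4.0), 0.5)
        assert np.all(r.weights >= 0)
        assert r.weights.sum() == pytest.approx(1.0)

    def test_bad_sigma_errors(self):
        with pytest.raises(ValueError):
            fit_weights(np.ones((1, 2)), np.array([1.0]), np.array([0.0]), 1.0)


class TestChi2:
    def test_exact_prediction_is_zero(self):
        assert chi2(np.array([3.0]), np.array([3.0]), np.array([1.0])) == 0.0

    def test_hand_value(self):
        assert chi2(np.array([40.0]), np.array([30.0]), np.array([25.0])) == 4.0

    def test_inverse_scaling_in_sigma2(self):
        pred, obs = np.array([1.0, 2.0]), np.array([2.0, 4.0])
        s = np.array([1.0, 2.0])
        assert chi2(pred, obs, 2 * s) == pytest.approx(chi2(pred, obs, s) / 2)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            chi2(np.array([]), np.array([]), np.array([]))


class TestThetaScan:
    def _toy_problem(self):
        rng = np.random.default_rng(5)
        mat = rng.uniform(0, 100, size=(8, 30))
        target = rng.uniform(0, 100, size=8)  # deliberately inconsistent
        return mat, target, np.full(8, 25.0)

    def test_chi2_non_increasing(self):
        mat, target, s2 = self._toy_problem()
        scan = theta_scan(mat, target, s2, thetas=np.logspace(4, -2, 20))
        assert np.all(np.diff(scan.chi2_values) <= scan.chi2_values[:-1] * 1e-6 + 1e-9)

    def test_relative_entropy_increases_as_theta_decreases(self):
        mat, target, s2 = self._toy_problem()
        scan = theta_scan(mat, target, s2, thetas=np.logspace(4, -2, 20))
        assert np.all(np.diff(scan.relative_entropies) >= -1e-9)

    def test_flat_curve_selects_largest_theta(self):
        # data consistent with priors: chi2 stays ~0 over the whole grid
        mat = np.array([[10.0, 30.0]])
        target = np.array([20.0])
        scan = theta_scan(mat, target, np.array([1.0]),
                          thetas=np.logspace(3, -2, 11))
        assert scan.selected_theta == scan.thetas[0]

    def test_elbow_found_on_inconsistent_data(self):
        mat, target, s2 = self._toy_problem()
        scan = theta_scan(mat, target, s2, thetas=np.logspace(4, -4, 17))
        # selected theta is on the grid and past it chi2 barely improves
        i = int(np.argmin(np.abs(scan.thetas - scan.selected_theta)))
        assert scan.selected_theta in scan.thetas
        assert scan.chi2_values[i] <= scan.chi2_values[0]

    def test_increasing_grid_rejected(self):
        with pytest.raises(ValueError):
            theta_scan(np.ones((1, 2)), np.ones(1), np.ones(1),
                       thetas=np.array([1.0, 10.0]))


class TestStateContributions:
    def test_delta_weights(self):
        w = np.array([1.0, 0.0, 0.0, 0.0])
        s = np.array(["I", "II", "III", "IV"])
        assert state_contributions(w, s) == {"I": 1.0, "II": 0.0, "III": 0.0, "IV": 0.0}

    def test_uniform_equal_sizes(self):
        w = np.full(8, 1 / 8)
        s = np.repeat(["I", "II", "III", "IV"], 2)
        out = state_contributions(w, s)
        assert all(v == pytest.approx(0.25) for v in out.values())
        assert sum(out.values()) == pytest.approx(1.0)

    def test_unlabelled_frames_error(self):
        with pytest.raises(ValueError):
            state_contributions(np.array([0.5, 0.5]), np.array(["I", None]))


class TestPreparation:
    def _table(self, residues, ratios, site="s1"):
        return PRETable(
            pd.DataFrame({"site": site, "residue": residues, "ratio": ratios})
        )

    def test_loess_preserves_constants(self):
        t = self._table(np.arange(30), np.full(30, 0.7))
        out = smooth_experimental(t)
        assert np.allclose(out.df["smoothed"], 0.7, atol=1e-9)

    def test_loess_preserves_lines(self):
        x = np.arange(30, dtype=float)
        y = 0.01 * x + 0.2
        out = smooth_experimental(self._table(x, y), span=0.5)
        assert np.allclose(out.df["smoothed"], y, atol=1e-6)

    def test_loess_flattens_spike(self):
        y = np.full(31, 0.8)
        y[15] = 0.1
        out = smooth_experimental(self._table(np.arange(31), y), span=0.3)
        sm = out.df["smoothed"].to_numpy()
        assert 0.1 < sm[15] < 0.8
        assert abs(sm[15] - 0.8) < abs(y[15] - 0.8)

    def test_small_site_skipped_with_warning(self):
        t = self._table(np.arange(3), [0.5, 0.6, 0.7])
        with pytest.warns(UserWarning, match="fewer than 5"):
            out = smooth_experimental(t)
        assert np.allclose(out.df["smoothed"], out.df["ratio"])

    def test_error_model_inverse_ratios(self):
        t = self._table([1, 2], [0.1, 0.5])
        df = build_error_model(t).df
        assert df["sigma2"].iloc[0] / df["sigma2"].iloc[1] == pytest.approx(5.0)

    def test_error_model_floor(self):
        t = self._table([1], [0.01])
        df = build_error_model(t, scale=1.0, floor=0.05).df
        assert df["sigma2"].iloc[0] == pytest.approx(1 / 0.05)

    def test_error_model_constant_mode(self):
        t = self._table([1, 2, 3], [0.1, 0.5, 0.9])
        df = build_error_model(t, scale=2.5, mode="constant").df
        assert np.allclose(df["sigma2"], 2.5)
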