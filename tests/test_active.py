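"""Scaling function, templates, the nested ML fit and the collapse."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import wormescape as we
from wormescape.active import _active_neg_loglik_profile


class TestScalingFunction:
    @pytest.mark.parametrize(
        "I,I1,I2,expected",
        [
            (0.0, -4.5, 45.0, -4.5),  # f(0) = I1
            (45.0, -4.5, 45.0, 18.0),  # -4.5 + 45/2
            (100.0, 66.5, np.inf, 166.5),  # linear limit
            (12.0, -4.5, 12.0, 1.5),  # ibuprofen half-saturation
        ],
    )
    def test_closed_form_values(self, I, I1, I2, expected):
        assert we.scaling_function(I, I1, I2) == pytest.approx(expected)

    @given(st.floats(0.0, 190.0), st.floats(0.01, 10.0), st.floats(1.0, 500.0))
    def test_strictly_increasing_and_saturating(self, I, dI, I2):
        f = lambda x: we.scaling_function(x, -4.5, I2)
        assert f(I + dI) > f(I)
        assert f(1e9) < -4.5 + I2 + 1e-3  # saturates at I1 + I2

    def test_unit_slope_at_zero_current(self):
        h = 1e-6
        for I2 in (12.0, 45.0, np.inf):
            slope = (we.scaling_function(h, 3.0, I2) - 3.0) / h
            assert slope == pytest.approx(1.0, abs=1e-6)

    def test_invalid_saturation_raises(self):
        with pytest.raises(ValueError):
            we.scaling_function(10.0, 0.0, -3.0)
        with pytest.raises(ValueError):
            we.ScalingParams(I1=0.0, I2=0.0)


class TestPausedTemplate:
    def test_identical_profiles_give_zero_covariance_plus_ridge(self):
        v = np.linspace(0, 1, 28)
        u, S = we.fit_paused_template(np.vstack([v, v]))
        np.testing.assert_array_equal(u, v)
        assert np.abs(S - S[0, 0] * np.eye(28)).max() < 1e-12
        assert S[0, 0] > 0  # ridge keeps it positive definite

    def test_two_point_variance(self):
        V = np.vstack([np.ones(28), -np.ones(28)])
        u, S = we.fit_paused_template(V)
        np.testing.assert_allclose(u, 0.0, atol=1e-14)
        np.testing.assert_allclose(np.diag(S), 1.0, rtol=1e-5)  # + ridge

    def test_monte_carlo_recovery_within_3_se(self):
        rng = np.random.default_rng(1)
        u_true = np.sin(np.linspace(0, 3, 28))
        L = np.diag(np.full(28, 2.0))
        V = u_true + rng.normal(size=(200, 28)) @ L.T
        u, S = we.fit_paused_template(V)
        se = 2.0 / np.sqrt(200)
        assert np.abs(u - u_true).max() < 3.5 * se
        np.testing.assert_allclose(np.diag(S), 4.0, rtol=0.35)

    def test_single_profile_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            we.fit_paused_template(np.ones((1, 28)))


class TestTemplateUpdate:
    def test_single_trial_with_unit_scaling_returns_it(self):
        v = np.linspace(-1, 1, 28)
        # I1 = 1, I2 = inf, I = 0 gives f = 1
        u, S = we.template_update(v[None, :], np.array([0.0]), 1.0, np.inf)
        np.testing.assert_allclose(u, v, rtol=1e-12)
        assert np.abs(S - S[0, 0] * np.eye(28)).max() < 1e-12  # zero residual

    def test_noise_free_model_data_is_exact(self, control_template):
        rng = np.random.default_rng(2)
        I = rng.uniform(0, 200, 50)
        f = we.scaling_function(I, -4.5, 45.0)
        V = f[:, None] * control_template
        u, S = we.template_update(V, I, -4.5, 45.0)
        np.testing.assert_allclose(u, control_template, rtol=1e-10)
        assert np.linalg.norm(S - np.diag(np.diag(S))) < 1e-10

    def test_matches_independent_least_squares_oracle(self):
        rng = np.random.default_rng(3)
        I = rng.uniform(0, 200, 40)
        V = rng.normal(size=(40, 28))
        u, _ = we.template_update(V, I, -4.5, 45.0)
        f = we.scaling_function(I, -4.5, 45.0)
        u_ls, *_ = np.linalg.lstsq(f[:, None], V, rcond=None)
        np.testing.assert_allclose(u, u_ls[0], rtol=1e-9)

    def test_is_stationary_point_of_the_likelihood(self):
        """Finite-difference gradient of the Gaussian log-lik vanishes at u_a."""
        rng = np.random.default_rng(4)
        I = rng.uniform(10, 200, 60)
        V = rng.normal(size=(60, 28)) + we.scaling_function(I, 0.0, 50.0)[:, None]
        u, S = we.template_update(V, I, 0.0, 50.0)
        f = we.scaling_function(I, 0.0, 50.0)
        Sinv = np.linalg.inv(S)

        def loglik(uu):
            R = V - f[:, None] * uu
            return -0.5 * np.sum(R @ Sinv * R)

        g = np.empty(28)
        for k in range(28):
            e = np.zeros(28)
            e[k] = 1e-6
            g[k] = (loglik(u + e) - loglik(u - e)) / 2e-6
        assert np.abs(g).max() < 1e-3 * abs(loglik(u))

    def test_update_is_idempotent_at_fixed_parameters(self):
        rng = np.random.default_rng(5)
        I = rng.uniform(0, 200, 30)
        V = rng.normal(size=(30, 28))
        u1, S1 = we.template_update(V, I, -4.5, 45.0)
        u2, S2 = we.template_update(V, I, -4.5, 45.0)
        np.testing.assert_array_equal(u1, u2)
        np.testing.assert_array_equal(S1, S2)

    def test_all_zero_scaling_raises(self):
        with pytest.raises(ValueError, match="zero"):
            we.template_update(np.ones((3, 28)), np.zeros(3), 0.0, 45.0)


class TestActiveFit:
    def test_recovers_generating_parameters(self, control_template):
        V, I = we.simulate_active_profiles(
            800, -4.5, 45.0, control_template, noise_sigma_px_s=1.0, seed=6
        )
        m = we.ActiveResponseModel(n_restarts=4, random_state=0).fit(V, I)
        assert m.I1_ == pytest.approx(-4.5, abs=0.5)
        assert m.I2_ == pytest.approx(45.0, rel=0.1)
        # template recovered up to noise
        assert np.corrcoef(m.u_a_, control_template)[0, 1] > 0.999

    def test_linear_regime_recovers_infinite_saturation(self, control_template):
        V, I = we.simulate_active_profiles(
            600, 66.5, np.inf, control_template, noise_sigma_px_s=1.0, seed=7
        )
        m = we.ActiveResponseModel(n_restarts=4, random_state=0).fit(V, I)
        assert m.I1_ == pytest.approx(66.5, abs=1.5)
        assert 1.0 / m.I2_ == pytest.approx(0.0, abs=1e-4)

    def test_optimum_beats_parameter_grid(self, control_template):
        V, I = we.simulate_active_profiles(
            200, -4.5, 45.0, control_template, noise_sigma_px_s=2.0, seed=8
        )
        m = we.ActiveResponseModel(n_restarts=3, random_state=0).fit(V, I)
        inv_best = 0.0 if np.isinf(m.I2_) else 1.0 / m.I2_
        best = _active_neg_loglik_profile(np.array([m.I1_, inv_best]), V, I, 1e-6)
        for i1 in np.linspace(-100, 100, 20):
            for inv_i2 in np.linspace(0, 0.2, 20):
                val = _active_neg_loglik_profile(np.array([i1, inv_i2]), V, I, 1e-6)
                assert best <= val + 1e-9


class TestCollapse:
    def test_noise_free_profiles_collapse_onto_template(self, control_template):
        rng = np.random.default_rng(9)
        I = rng.uniform(30, 200, 25)  # keep f well away from zero
        f = we.scaling_function(I, -4.5, 45.0)
        V = f[:, None] * control_template
        C, kept = we.collapse_profiles(V, I, -4.5, 45.0)
        assert kept.size == 25
        np.testing.assert_allclose(C, np.tile(control_template, (25, 1)), rtol=1e-10)

    def test_zero_scaling_trials_are_excluded_with_warning(self):
        V = np.ones((3, 28))
        I = np.array([0.0, 50.0, 100.0])  # f(0) = 0 when I1 = 0
        with pytest.warns(UserWarning, match="excluding 1"):
            C, kept = we.collapse_profiles(V, I, 0.0, 45.0)
        np.testing.assert_array_equal(kept, [1, 2])

    def test_collapse_shrinks_between_bin_spread(self, control_template):
        V, I = we.simulate_active_profiles(
            500, -4.5, 45.0, control_template, noise_sigma_px_s=1.0, seed=10
        )
        keep = I > 30
        V, I = V[keep], I[keep]
        ids, _ = we.quantile_bins(I, 5)
        raw_means = np.vstack([V[ids == b].mean(axis=0) for b in range(5)])
        C, kept = we.collapse_profiles(V, I, -4.5, 45.0)
        col_means = np.vstack([C[ids[kept] == b].mean(axis=0) for b in range(5)])
        assert col_means.var(axis=0).mean() < 0.05 * raw_means.var(axis=0).mean()
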