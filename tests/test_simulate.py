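"""Generative simulator: presets, template geometry, noise and determinism."""

import dataclasses

import numpy as np
import pytest

import wormescape as we
from wormescape.simulate import TemplateShape, _ou_noise


class TestPresets:
    @pytest.mark.parametrize(
        "label,I0,I1,I2",
        [
            ("control", 25.9, -4.5, 45.0),
            ("ibuprofen", 26.6, -4.5, 12.0),
            ("mutant", 51.6, 66.5, np.inf),
        ],
    )
    def test_published_parameter_values(self, label, I0, I1, I2):
        spec = we.paper_preset(label)
        assert (spec.I0_mA, spec.I1, spec.I2) == (I0, I1, I2)

    def test_mutant_lags_one_frame(self):
        assert we.paper_preset("mutant").template.lag_frames == 1
        assert we.paper_preset("control").template.lag_frames == 0

    def test_unknown_label_raises(self):
        with pytest.raises(ValueError, match="unknown preset"):
            we.paper_preset("unknown")

    def test_one_frame_lag_is_83_ms(self):
        assert we.frame_lag_ms(1) == 83
        assert we.frame_lag_ms(2) == 167


class TestCanonicalTemplate:
    def test_minimum_is_exactly_minus_one(self, control_template):
        assert control_template.min() == -1.0
        assert control_template.size == 28

    def test_reversal_timing_in_plausible_range(self, control_template):
        grid = we.VelocityPreprocessor().model_grid_s
        t_min = grid[control_template.argmin()]
        assert 1.5 <= t_min <= 2.0

    def test_lagged_template_is_shifted_by_one_frame(self, control_spec):
        lagged = dataclasses.replace(
            control_spec, template=TemplateShape(lag_frames=1)
        )
        u0 = we.canonical_template(control_spec)
        u1 = we.canonical_template(lagged)
        np.testing.assert_allclose(u1[1:], u0[:-1], atol=1e-12)

    def test_zero_depth_shape_is_flat_baseline(self, control_spec):
        flat = dataclasses.replace(
            control_spec, template=TemplateShape(reversal_depth_rel=0.0)
        )
        u = we.canonical_template(flat)
        np.testing.assert_allclose(u, u[0], atol=1e-12)
        assert u[0] > 0

    def test_reversal_outside_window_raises(self, control_spec):
        bad = dataclasses.replace(
            control_spec, template=TemplateShape(reversal_center_s=5.0)
        )
        with pytest.raises(ValueError, match="outside the model window"):
            we.canonical_template(bad)


class TestCorrelatedNoise:
    def test_variance_and_correlation_time(self):
        rng = np.random.default_rng(0)
        X = _ou_noise(rng, 2000, 600, sigma=3.0, corr_time_s=0.2, rate_hz=60.0)
        assert X.var() == pytest.approx(9.0, rel=0.05)
        lag = 12  # 0.2 s at 60 Hz
        r = np.mean(X[:, :-lag] * X[:, lag:]) / X.var()
        assert r == pytest.approx(np.exp(-1.0), rel=0.1)

    def test_estimator_recovers_generator_correlation_time(self):
        """The preprocessing-side correlation-time estimator agrees with the
        generator's corr_time within 20%."""
        rng = np.random.default_rng(1)
        V = _ou_noise(rng, 500, 28, sigma=1.0, corr_time_s=0.2, rate_hz=12.0)
        T = we.effective_independent_points(V, 12.0, duration_s=2.3)
        tau_hat = 2.3 / T
        assert tau_hat == pytest.approx(0.2, rel=0.2)


class TestSimulateCohort:
    def test_same_seed_is_bit_identical(self, control_spec):
        a, ta = we.simulate_cohort(control_spec, 20, seed=9)
        b, tb = we.simulate_cohort(control_spec, 20, seed=9)
        np.testing.assert_array_equal(a.velocity_matrix, b.velocity_matrix)
        np.testing.assert_array_equal(a.currents_mA, b.currents_mA)
        assert ta.equals(tb)

    def test_pause_fraction_near_half_at_pause_current(self, control_spec):
        _, truth = we.simulate_cohort(control_spec, 10_000, seed=10)
        I = truth.applied_current_mA.to_numpy()
        near = np.abs(I - control_spec.I0_mA) < 4.0
        assert truth.paused.to_numpy()[near].mean() == pytest.approx(0.5, abs=0.08)

    def test_pause_fraction_traces_the_sigmoid(self, control_spec):
        _, truth = we.simulate_cohort(control_spec, 10_000, seed=11)
        I = truth.applied_current_mA.to_numpy()
        paused = truth.paused.to_numpy()
        ids, _ = we.quantile_bins(I, 10)
        for b in range(10):
            m = ids == b
            p_hat = paused[m].mean()
            p_true = we.pause_probability(I[m], control_spec.I0_mA).mean()
            se = np.sqrt(p_true * (1 - p_true) / m.sum()) + 1e-6
            assert abs(p_hat - p_true) < 4 * se

    def test_noise_free_active_trial_processes_to_scaled_template(
        self, control_spec, control_template
    ):
        """sigma -> 0, no forward baseline: the preprocessed profile is
        exactly f(I) times the canonical template (smoothing is linear)."""
        quiet = dataclasses.replace(
            control_spec,
            noise_sigma_px_s=1e-9,
            forward_mean_px_s=0.0,
            forward_sd_px_s=0.0,
            I0_mA=1e-2,  # essentially everyone escapes
        )
        cohort, truth = we.simulate_cohort(quiet, 6, seed=12)
        V = we.VelocityPreprocessor().transform(cohort.velocity_matrix)
        f = we.scaling_function(cohort.currents_mA, quiet.I1, quiet.I2)
        active = ~truth.paused.to_numpy()
        np.testing.assert_allclose(
            V[active], f[active, None] * control_template, atol=1e-6
        )

    def test_truth_table_matches_cohort(self, control_sim):
        cohort, truth, _, _ = control_sim
        assert truth.trial_id.tolist() == cohort.trial_ids
        np.testing.assert_array_equal(
            truth.applied_current_mA.to_numpy(), cohort.currents_mA
        )

    def test_simulate_dataset_spawns_distinct_cohorts(self):
        ds = we.simulate_dataset(
            [we.paper_preset("control"), we.paper_preset("mutant")], 15, seed=13
        )
        assert [c.worm_type for c in ds.cohorts] == ["control", "mutant"]
        assert set(ds.truth.worm_type) == {"control", "mutant"}
        assert not np.array_equal(
            ds.cohorts[0].currents_mA, ds.cohorts[1].currents_mA
        )


class TestEndToEndRecovery:
    def test_full_pipeline_recovers_control_parameters(self, control_spec):
        """simulate (60 Hz) -> preprocess -> fit recovers the generating
        pause current and scaling parameters."""
        cohort, _ = we.simulate_cohort(control_spec, 1000, seed=14)
        V = we.VelocityPreprocessor().transform(cohort.velocity_matrix)
        model = we.EscapeResponseModel(n_restarts=4, random_state=0).fit(
            V, cohort.currents_mA
        )
        # tolerances cover the estimator's sampling scatter plus the small
        # bias induced by cutoff-based state classification (trials near the
        # 10 px/s threshold are selected by their noise realisation)
        assert model.I0_mA_ == pytest.approx(25.9, rel=0.15)
        assert model.active_.I1_ == pytest.approx(-4.5, abs=3.5)
        assert model.active_.I2_ == pytest.approx(45.0, rel=0.2)
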