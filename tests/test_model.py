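"""Intensity matrices, transition probabilities and the panel likelihood."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from healthspan import (
    IllnessDeathSpec,
    IntensityParameters,
    InvalidParametersError,
    compile_panel,
    fit,
    intensity_matrix,
    subject_loglik,
    transition_probability,
)
from healthspan.model import PanelLikelihood

from conftest import panel_frame


class TestIntensityMatrix:
    def test_zero_betas_give_unit_rates(self):
        p = IntensityParameters(beta0={"12": 0.0, "13": 0.0, "23": 0.0}, ref_age=80.0)
        Q = intensity_matrix(p, 80.0)
        assert np.allclose(Q, [[-2, 1, 1], [0, -1, 1], [0, 0, 0]])

    def test_rows_sum_to_zero_and_absorbing_dead_state(self, gompertz_params):
        Q = intensity_matrix(gompertz_params, 93.2)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-14)
        assert np.all(Q[2] == 0.0)
        assert Q[1, 0] == 0.0  # no recovery

    def test_positive_age_slope_makes_onset_rate_increase(self, gompertz_params):
        q = gompertz_params.intensity("12", np.array([70.0, 80.0, 95.0]))
        assert np.all(np.diff(q) > 0)

    def test_nonfinite_coefficients_rejected(self):
        with pytest.raises(InvalidParametersError):
            IntensityParameters(beta0={"12": np.nan, "13": 0.0, "23": 0.0})
        with pytest.raises(InvalidParametersError):
            IntensityParameters(
                beta0={"12": 0.0, "13": 0.0, "23": 0.0}, beta_age={"12": np.inf}
            )

    def test_minus_inf_baseline_means_zero_intensity(self):
        p = IntensityParameters(beta0={"12": -np.inf, "13": 0.0, "23": 0.0})
        assert p.intensity("12", 80.0) == 0.0


class TestTransitionProbability:
    def test_zero_length_interval_is_identity(self, const_params):
        assert np.array_equal(transition_probability(const_params, 70.0, 70.0), np.eye(3))

    def test_negative_interval_rejected(self, const_params):
        with pytest.raises(ValueError):
            transition_probability(const_params, 70.0, 69.0)

    def test_constant_rate_oracle_values(self, const_params):
        # closed forms for q12=.1, q13=.05, q23=.2 over one year
        P = transition_probability(const_params, 80.0, 81.0)
        assert P[0, 0] == pytest.approx(0.860708, abs=5e-7)
        assert P[0, 1] == pytest.approx(0.083954, abs=5e-7)
        assert P[1, 1] == pytest.approx(0.818731, abs=5e-7)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert P[1, 0] == 0.0
        assert np.array_equal(P[2], [0.0, 0.0, 1.0])

    def test_degenerate_rates_use_limit_formula(self):
        # q23 = q12 + q13 exactly: P12 -> q12 * dt * exp(-q23 dt)
        p = IntensityParameters(
            beta0={"12": math.log(0.1), "13": math.log(0.05), "23": math.log(0.15)}
        )
        P = transition_probability(p, 80.0, 81.0)
        assert P[0, 1] == pytest.approx(0.1 * math.exp(-0.15), rel=1e-10)
        Q = intensity_matrix(p, 80.5)

        def ode(_, y):
            return (y.reshape(3, 3) @ Q).ravel()

        sol = solve_ivp(ode, (0, 1.0), np.eye(3).ravel(), rtol=1e-12, atol=1e-14)
        assert np.abs(P - sol.y[:, -1].reshape(3, 3)).max() < 1e-9

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        q=st.tuples(
            st.floats(0.01, 0.8), st.floats(0.01, 0.8), st.floats(0.01, 0.8)
        ),
        dt=st.floats(0.1, 6.0),
    )
    def test_agrees_with_matrix_exponential(self, q, dt):
        q12, q13, q23 = q
        p = IntensityParameters(
            beta0={"12": math.log(q12), "13": math.log(q13), "23": math.log(q23)}
        )
        P = transition_probability(p, 80.0, 80.0 + dt)
        P_ref = expm(intensity_matrix(p, 80.0) * dt)
        # expm itself degrades where the generator is nearly defective
        tol = 1e-9 if abs(q23 - q12 - q13) > 1e-4 else 1e-6
        assert np.abs(P - P_ref).max() < tol

    def test_chapman_kolmogorov_with_aligned_pieces(self, gompertz_params):
        a, b, c = 78.0, 80.5, 84.0  # all multiples of the 0.25y piece
        P_ac = transition_probability(gompertz_params, a, c)
        P_ab = transition_probability(gompertz_params, a, b)
        P_bc = transition_probability(gompertz_params, b, c)
        assert np.abs(P_ac - P_ab @ P_bc).max() < 1e-8

    def test_death_probabilities_monotone_in_interval_length(self, gompertz_params):
        lengths = np.linspace(0.5, 12.0, 24)
        mats = [transition_probability(gompertz_params, 75.0, 75.0 + h) for h in lengths]
        p13 = [m[0, 2] for m in mats]
        p23 = [m[1, 2] for m in mats]
        p11 = [m[0, 0] for m in mats]
        p22 = [m[1, 1] for m in mats]
        assert np.all(np.diff(p13) >= 0) and np.all(np.diff(p23) >= 0)
        assert np.all(np.diff(p11) <= 0) and np.all(np.diff(p22) <= 0)

    def test_piece_step_halving_changes_little(self, gompertz_params):
        P1 = transition_probability(gompertz_params, 70.0, 76.0, piece_step=0.25)
        P2 = transition_probability(gompertz_params, 70.0, 76.0, piece_step=0.125)
        assert np.abs(P1 - P2).max() < 1e-4


class TestSubjectLoglik:
    def test_survival_pair_closed_form(self, const_params):
        # staying CI-free for two years: log e^{-0.15*2} = -0.3
        obs = panel_frame([(1, 80.0, 1, 0), (1, 82.0, 1, 0)])
        assert subject_loglik(const_params, obs) == pytest.approx(-0.3, abs=1e-12)

    def test_exact_death_contribution(self, const_params):
        obs = panel_frame([(1, 80.0, 1, 0), (1, 81.0, 3, 1)])
        P = transition_probability(const_params, 80.0, 81.0)
        expected = math.log(P[0, 0] * 0.05 + P[0, 1] * 0.2)
        assert subject_loglik(const_params, obs) == pytest.approx(expected, rel=1e-10)

    def test_weight_scales_contribution_linearly(self, const_params):
        obs = panel_frame([(1, 80.0, 1, 0), (1, 83.0, 2, 0), (1, 84.5, 3, 1)])
        ll1 = subject_loglik(const_params, obs, weight=1.0)
        ll2 = subject_loglik(const_params, obs, weight=2.0)
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)

    def test_missing_living_state_between_knowns_changes_nothing(self, gompertz_params):
        without = panel_frame([(1, 80.0, 1, 0), (1, 86.0, 2, 0)])
        with_missing = panel_frame(
            [(1, 80.0, 1, 0), (1, 83.0, np.nan, 0), (1, 86.0, 2, 0)]
        )
        assert subject_loglik(gompertz_params, with_missing) == pytest.approx(
            subject_loglik(gompertz_params, without), rel=1e-12
        )

    def test_trailing_missing_is_right_censoring(self, const_params):
        obs = panel_frame([(1, 80.0, 1, 0), (1, 83.0, np.nan, 0)])
        P = transition_probability(const_params, 80.0, 83.0)
        assert subject_loglik(const_params, obs) == pytest.approx(
            math.log(P[0, 0] + P[0, 1]), rel=1e-10
        )

    def test_impossible_path_gives_minus_inf_with_warning(self, const_params):
        # an observed recovery (2 then 1) has probability zero
        obs = panel_frame([(1, 80.0, 2, 0), (1, 83.0, 1, 0)])
        with pytest.warns(RuntimeWarning):
            assert subject_loglik(const_params, obs) == -np.inf


class TestCompilePanel:
    def test_interval_bridges_missing_states(self):
        panel = panel_frame([(1, 80.0, 1, 0), (1, 83.0, np.nan, 0), (1, 86.0, 2, 0)])
        c = compile_panel(panel)
        assert c.n_intervals == 1
        assert c.a0[0] == 80.0 and c.a1[0] == 86.0 and c.from_state[0] == 1

    def test_death_without_prior_state_contributes_nothing(self):
        panel = panel_frame([(1, 80.0, np.nan, 0), (1, 81.0, 3, 1)])
        assert compile_panel(panel).n_intervals == 0

    def test_transition_counts(self):
        panel = panel_frame(
            [
                (1, 80.0, 1, 0), (1, 83.0, 2, 0), (1, 85.0, 3, 1),
                (2, 70.0, 1, 0), (2, 72.5, 3, 1),
            ]
        )
        counts = compile_panel(panel).transition_counts()
        assert counts == {"12": 1, "13": 1, "23": 1}


class TestFit:
    def test_estimate_beats_truth_loglik(self, const_params, const_spec, small_cohort_config):
        from healthspan import generate_cohort

        panel, _ = generate_cohort(small_cohort_config)
        res = fit(panel, const_spec, compute_covariance=False)
        lik = PanelLikelihood(compile_panel(panel), const_spec)
        assert res.loglik >= lik.loglik(const_spec.pack(const_params)) - 1e-6

    def test_zero_rate_boundary(self, const_spec):
        # no CI onsets in truth: fitted onset intensity collapses toward zero
        from healthspan import SimulationConfig, generate_cohort

        truth = IntensityParameters(
            beta0={"12": -np.inf, "13": math.log(0.05), "23": math.log(0.2)}
        )
        config = SimulationConfig(
            n_subjects=400, true_params=truth, seed=5, wave_offsets=(0.0, 3.0, 6.0)
        )
        panel, _ = generate_cohort(config)
        res = fit(panel, const_spec, compute_covariance=False, maxiter=2000)
        assert math.exp(res.theta[0]) < 1e-4
        assert "12" in res.non_identified

    def test_covariance_symmetric_psd_and_loglik_finite(self, const_spec, small_cohort_config):
        from healthspan import generate_cohort

        panel, _ = generate_cohort(small_cohort_config)
        res = fit(panel, const_spec)
        assert np.isfinite(res.loglik)
        assert np.allclose(res.covariance, res.covariance.T, atol=1e-12)
        assert np.linalg.eigvalsh(res.covariance).min() > -1e-10

    def test_piecewise_age_bands_shift_intensity_stepwise(self):
        p = IntensityParameters(
            beta0={"12": math.log(0.1), "13": math.log(0.05), "23": math.log(0.2)},
            age_band_knots=(85.0,),
            age_band_offsets={"12": (math.log(2.0),)},
        )
        assert p.intensity("12", 84.9) == pytest.approx(0.1)
        assert p.intensity("12", 85.1) == pytest.approx(0.2)
        assert p.is_age_varying()

    def test_fit_recovers_banded_age_step(self):
        # truth doubles the onset hazard at 85; the banded fit finds the step
        from healthspan import SimulationConfig, generate_cohort

        truth = IntensityParameters(
            beta0={"12": math.log(0.08), "13": math.log(0.05), "23": math.log(0.2)},
            age_band_knots=(85.0,),
            age_band_offsets={"12": (math.log(2.0),)},
        )
        config = SimulationConfig(
            n_subjects=2000, true_params=truth, seed=17, wave_offsets=(0.0, 3.0, 6.0, 9.0)
        )
        panel, _ = generate_cohort(config)
        spec = IllnessDeathSpec(age_effect=False, age_bands=(85.0,), ref_age=80.0)
        res = fit(panel, spec, compute_covariance=False)
        est = dict(zip(spec.parameter_names(), res.theta))
        assert est["beta_12_age85plus"] == pytest.approx(math.log(2.0), abs=0.35)
        assert abs(est["beta_13_age85plus"]) < 0.35
        assert est["beta0_12"] == pytest.approx(math.log(0.08), abs=0.25)

    def test_banded_spec_rejects_simultaneous_loglinear_age(self):
        with pytest.raises(ValueError):
            IllnessDeathSpec(age_effect=True, age_bands=(85.0,))

    def test_fit_result_roundtrips_to_json(self, const_spec, small_cohort_config, tmp_path):
        import json

        from healthspan import generate_cohort

        panel, _ = generate_cohort(small_cohort_config)
        res = fit(panel, const_spec)
        res.to_json(tmp_path / "fit.json")
        payload = json.loads((tmp_path / "fit.json").read_text())
        assert payload["estimates"]["beta0_12"] == pytest.approx(res.theta[0])
        assert payload["n_subjects"] == res.n_subjects
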