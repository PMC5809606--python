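"""Model fitting, RMSE objective, and the 5% model-selection rule."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytoaml.calibration import (
    FitBounds,
    FitResult,
    GroupLabel,
    Observation,
    ObservationKind,
    ObservationTable,
    fit_model,
    load_observations,
    objective,
    observations_to_frame,
    residuals,
    select_model,
)
from cytoaml.model import ModelVariant, SystemState, default_params, healthy_equilibrium, simulate

M1 = ModelVariant.CYTOKINE_DEPENDENT
M2 = ModelVariant.CYTOKINE_INDEPENDENT


def exact(t, v):
    return Observation(t=t, kind=ObservationKind.EXACT, value=v)


def interval(t, lo, hi):
    return Observation(t=t, kind=ObservationKind.INTERVAL, lower=lo, upper=hi)


def synthetic_course(params, l1_0, times):
    """Noise-free blast fractions of a simulated course at given days."""
    eq = healthy_equilibrium(params)
    init = SystemState(c1=eq.c1, c2=eq.c2, l1=l1_0, l2=0.0)
    traj = simulate(params, init, float(times[-1]), t_eval=np.asarray(times, dtype=float))
    return np.interp(times, traj.times, traj.blast_fractions())


class TestObservationTypes:
    def test_interval_residual_zero_inside_distance_outside(self):
        o = interval(10.0, 0.0, 0.05)
        assert o.residual(0.03) == 0.0
        assert o.residual(0.08) == pytest.approx(0.03)
        assert o.residual(-0.01) == pytest.approx(-0.01)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            exact(0.0, 1.5)
        with pytest.raises(ValueError):
            interval(0.0, 0.2, 0.1)
        with pytest.raises(ValueError):
            ObservationTable("p", (exact(0.0, 0.1),))  # fewer than two points
        with pytest.raises(ValueError):
            ObservationTable("p", (exact(10.0, 0.1), exact(10.0, 0.2)))  # ties


class TestObjective:
    def test_two_point_rmse_by_hand(self):
        """Residuals 0.03 and 0.04 give rmse sqrt((9+16)e-4/2) = 0.0354."""
        params = default_params(M2, a_l=0.9, p_l=0.5)
        times = np.array([30.0, 40.0])
        truth = synthetic_course(params, 1e3, times)
        obs = ObservationTable(
            "p", (exact(30.0, truth[0] + 0.03), exact(40.0, truth[1] + 0.04))
        )
        assert objective(params, M2, obs, l1_0=1e3) == pytest.approx(0.035355, rel=1e-3)

    def test_zero_when_curve_passes_through_points(self):
        params = default_params(M2, a_l=0.9, p_l=0.5)
        times = np.array([20.0, 30.0, 40.0])
        truth = synthetic_course(params, 1e3, times)
        obs = ObservationTable("p", tuple(exact(t, v) for t, v in zip(times, truth)))
        # the objective path integrates at fitting tolerance (rtol 1e-6),
        # so "exact" agreement is bounded by that, far below data noise
        assert objective(params, M2, obs, l1_0=1e3) < 1e-4

    def test_zero_when_inside_all_intervals(self):
        params = default_params(M1, a_l=0.96, p_l=0.5)
        obs = ObservationTable("p", (interval(10.0, 0.0, 0.05), interval(40.0, 0.0, 0.05)))
        assert objective(params, M1, obs, l1_0=1.0) == 0.0

    def test_variant_mismatch_rejected(self):
        params = default_params(M1)
        obs = ObservationTable("p", (exact(1.0, 0.1), exact(2.0, 0.2)))
        with pytest.raises(ValueError):
            objective(params, M2, obs)

    @given(scale=st.floats(0.1, 5.0))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_rmse_scales_with_residuals(self, scale):
        """Scaling every residual by c scales the rmse by c."""
        r = np.array([0.01, -0.03, 0.02])
        rmse = float(np.sqrt(np.mean(r**2)))
        rmse_scaled = float(np.sqrt(np.mean((scale * r) ** 2)))
        assert rmse_scaled == pytest.approx(scale * rmse)

    def test_reordering_observations_leaves_residuals_invariant(self):
        params = default_params(M2, a_l=0.9, p_l=0.5)
        times = np.array([15.0, 30.0, 40.0])
        truth = synthetic_course(params, 1e3, times)
        obs = ObservationTable("p", tuple(exact(t, v + 0.01) for t, v in zip(times, truth)))
        r = residuals(params, 1e3, obs)
        # the table enforces time order; each residual is model - value = -0.01
        assert np.allclose(r, -0.01, atol=1e-5)


class TestFitModel:
    def test_recovers_noiseless_model2_course(self):
        """Self-consistency: a noiseless 6-point course is refit to rmse < 1e-3."""
        gen = default_params(M2, a_l=0.92, p_l=0.6, d_l=4.6)
        times = np.array([0.0, 12.0, 24.0, 36.0, 48.0, 60.0])
        truth = synthetic_course(gen, 1e3, times)
        obs = ObservationTable("p", tuple(exact(t, v) for t, v in zip(times, truth)))
        fit = fit_model(M2, obs, n_starts=8, seed=7)
        assert fit.converged
        assert fit.rmse < 1e-3

    def test_fast_relapse_rejects_cytokine_dependent_model(self):
        """A course reaching 10% blasts well before 200 days cannot be
        matched by the feedback-limited cytokine-dependent model."""
        gen = default_params(M2, a_l=0.95, p_l=0.8)
        times = np.array([0.0, 25.0, 50.0])
        truth = synthetic_course(gen, 1e3, times)
        obs = ObservationTable("p", tuple(exact(t, v) for t, v in zip(times, truth)))
        fit1 = fit_model(M1, obs, n_starts=8, seed=3)
        fit2 = fit_model(M2, obs, n_starts=8, seed=4)
        assert fit1.rmse > 10.0 * max(fit2.rmse, 1e-6)
        _, _, group = select_model(fit1, fit2)
        assert group is GroupLabel.GROUP2_ONLY_CYTOKINE_INDEPENDENT

    def test_deterministic_given_seed(self):
        gen = default_params(M2, a_l=0.9, p_l=0.5)
        times = np.array([0.0, 20.0, 40.0])
        truth = synthetic_course(gen, 1e3, times)
        obs = ObservationTable("p", tuple(exact(t, v) for t, v in zip(times, truth)))
        f1 = fit_model(M2, obs, n_starts=4, seed=11)
        f2 = fit_model(M2, obs, n_starts=4, seed=11)
        assert f1.rmse == f2.rmse
        assert f1.best_params == f2.best_params
        assert f1.l1_0 == f2.l1_0

    def test_best_params_within_bounds(self):
        gen = default_params(M2, a_l=0.9, p_l=0.5)
        times = np.array([0.0, 20.0, 40.0])
        truth = synthetic_course(gen, 1e3, times)
        obs = ObservationTable("p", tuple(exact(t, v) for t, v in zip(times, truth)))
        b = FitBounds()
        fit = fit_model(M2, obs, bounds=b, n_starts=4, seed=2)
        lp = fit.best_params.leukemic
        assert b.a_l[0] <= lp.a <= b.a_l[1]
        assert b.p_l[0] <= lp.p <= b.p_l[1]
        assert b.d_l[0] <= lp.d <= b.d_l[1]
        assert 10 ** b.log10_l1_0[0] <= fit.l1_0 <= 10 ** b.log10_l1_0[1]


def _fit_stub(variant, rmse, converged=True):
    return FitResult(
        variant=variant,
        patient_id="p",
        best_params=None if not converged else default_params(variant),
        l1_0=1.0,
        rmse=rmse,
        n_obs=5,
        converged=converged,
    )


class TestSelectModel:
    @pytest.mark.parametrize(
        "rmse1,rmse2,expected",
        [
            (0.100, 0.100, GroupLabel.GROUP1_CYTOKINE_DEPENDENT_COMPATIBLE),  # tie
            (0.106, 0.100, GroupLabel.GROUP2_ONLY_CYTOKINE_INDEPENDENT),  # 6% worse
            (0.104, 0.100, GroupLabel.GROUP1_CYTOKINE_DEPENDENT_COMPATIBLE),  # within band
            (0.100, 0.106, GroupLabel.GROUP1_CYTOKINE_DEPENDENT_COMPATIBLE),  # model 1 wins
        ],
    )
    def test_five_percent_rule(self, rmse1, rmse2, expected):
        _, _, group = select_model(_fit_stub(M1, rmse1), _fit_stub(M2, rmse2))
        assert group is expected

    def test_near_zero_rmse_differences_do_not_discriminate(self):
        """Both models interpolating the data (rmse ~ 1e-6) must tie even
        though the ratio exceeds 5%."""
        m1c, m2c, group = select_model(_fit_stub(M1, 2e-6), _fit_stub(M2, 1e-6))
        assert m1c and m2c
        assert group is GroupLabel.GROUP1_CYTOKINE_DEPENDENT_COMPATIBLE

    def test_swap_symmetry(self):
        """Swapping the two RMSEs swaps which model is preferred."""
        m1a, m2a, _ = select_model(_fit_stub(M1, 0.20), _fit_stub(M2, 0.10))
        m1b, m2b, _ = select_model(_fit_stub(M1, 0.10), _fit_stub(M2, 0.20))
        assert (m1a, m2a) == (m2b, m1b)

    def test_non_convergence_is_undetermined(self):
        _, _, group = select_model(_fit_stub(M1, math.inf, converged=False), _fit_stub(M2, 0.1))
        assert group is GroupLabel.UNDETERMINED

    def test_wrong_variant_order_rejected(self):
        with pytest.raises(ValueError):
            select_model(_fit_stub(M2, 0.1), _fit_stub(M1, 0.1))


class TestCSVRoundtrip:
    def test_percent_scale_roundtrip(self, tmp_path):
        tab = ObservationTable(
            "P001", (interval(0.0, 0.0, 0.05), exact(90.0, 0.12), exact(150.0, 0.27))
        )
        df = observations_to_frame([tab])
        path = tmp_path / "obs.csv"
        df.to_csv(path, index=False)
        back = load_observations(path)
        assert len(back) == 1
        o = back[0].observations
        assert o[0].kind is ObservationKind.INTERVAL
        assert o[0].upper == pytest.approx(0.05)
        assert o[1].value == pytest.approx(0.12)
        assert o[2].value == pytest.approx(0.27)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("patient_id,t_days\np,0\n")
        with pytest.raises(ValueError):
            load_observations(path)
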