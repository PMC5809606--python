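"""Core model: signal, growth rates, RHS, equilibria, simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytoaml.model import (
    LineageParams,
    ModelParams,
    ModelVariant,
    SystemState,
    blast_fraction,
    default_params,
    effective_growth_rate,
    feedback_signal,
    healthy_equilibrium,
    rhs,
    simulate,
)

M1 = ModelVariant.CYTOKINE_DEPENDENT
M2 = ModelVariant.CYTOKINE_INDEPENDENT


class TestFeedbackSignal:
    @pytest.mark.parametrize(
        "k,consumers,expected",
        [
            (1.0, 0.0, 1.0),  # no consumers -> maximal signal
            (5e-7, 0.0, 1.0),
            (1.0, 1.0, 0.5),
            (2e-9, 1e9, 1.0 / 3.0),
        ],
    )
    def test_values(self, k, consumers, expected):
        assert feedback_signal(k, consumers) == pytest.approx(expected)

    def test_stimulation_clamps_to_max(self):
        assert feedback_signal(1e-9, 5e9, stimulated=True) == 1.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            feedback_signal(0.0, 1.0)
        with pytest.raises(ValueError):
            feedback_signal(1e-9, -1.0)

    @given(
        k=st.floats(1e-12, 1e-6),
        c=st.floats(0, 1e12),
        dc=st.floats(1.0, 1e12),
    )
    @settings(max_examples=50, derandomize=True)
    def test_strictly_decreasing_in_consumers(self, k, c, dc):
        assert feedback_signal(k, c + dc) < feedback_signal(k, c)

    def test_model1_leukemic_mature_lower_signal_model2_independent(self):
        """Leukemic mature cells consume cytokine only in Model 1."""
        from cytoaml.model import _signals

        p1, p2 = default_params(M1), default_params(M2)
        base = np.array([1e9, 5e8, 0.0, 0.0])
        with_l2 = np.array([1e9, 5e8, 0.0, 5e8])
        assert _signals(with_l2, p1, False)[0] < _signals(base, p1, False)[0]
        assert _signals(with_l2, p2, False)[0] == _signals(base, p2, False)[0]


class TestEffectiveGrowthRate:
    @pytest.mark.parametrize(
        "a,p,s,expected",
        [
            (0.5, 3.0, 1.0, 0.0),  # self-renewal of one half is neutral
            (1.0, 1.0, 1.0, 1.0),  # pure expansion at one division/day
            (0.9, 0.2, 1.0, 0.16),  # high self-renewal, slow cycling ...
            (0.58, 1.0, 1.0, 0.16),  # ... equals low self-renewal, fast cycling
            (1.0, 1.0, 0.25, -0.5),
        ],
    )
    def test_values(self, a, p, s, expected):
        assert effective_growth_rate(a, p, s) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            effective_growth_rate(1.2, 1.0, 1.0)
        with pytest.raises(ValueError):
            effective_growth_rate(0.9, -0.1, 1.0)


class TestRHS:
    def test_zero_at_healthy_equilibrium_without_crowding(self, nocrowding_params):
        eq = healthy_equilibrium(nocrowding_params)
        dy = rhs(eq, nocrowding_params)
        assert np.max(np.abs(dy)) < 1e-6 * eq.c1

    def test_pure_doubling_growth_model2(self):
        """Fully self-renewing blasts at 1/day with no crowding double at rate 1."""
        params = default_params(M2, a_l=1.0, p_l=1.0, dbar=1e-30)
        params = ModelParams(
            healthy=params.healthy, leukemic=params.leukemic, k=params.k, dbar=0.0, variant=M2
        )
        state = SystemState(c1=1e9, c2=5e8, l1=1e3, l2=0.0)
        dy = rhs(state, params)
        assert dy[2] == pytest.approx(1e3)

    def test_invasion_sign_follows_self_renewal_difference(self, nocrowding_params):
        """At the healthy steady state s* = 1/(2 a_c), a seeded leukemic
        clone grows iff its self-renewal exceeds the healthy one."""
        from dataclasses import replace

        eq = healthy_equilibrium(nocrowding_params)
        a_c = nocrowding_params.healthy.a
        for a_l, sign in [(a_c + 0.05, 1), (a_c - 0.05, -1), (a_c, 0)]:
            params = replace(
                nocrowding_params, leukemic=replace(nocrowding_params.leukemic, a=a_l)
            )
            state = SystemState(c1=eq.c1, c2=eq.c2, l1=1.0, l2=0.0)
            dl1 = rhs(state, params)[2]
            assert np.sign(round(dl1, 12)) == sign

    def test_rejects_negative_state(self, nocrowding_params):
        with pytest.raises(ValueError):
            rhs(np.array([-1.0, 1e8, 0.0, 0.0]), nocrowding_params)


class TestHealthyEquilibrium:
    def test_closed_form_mature_density(self, nocrowding_params):
        # (2*0.87 - 1)/1e-9
        eq = healthy_equilibrium(nocrowding_params)
        assert eq.c2 == pytest.approx(0.74e9)
        assert eq.c1 == pytest.approx(2.3 * 0.74e9 / 0.42)

    def test_numeric_root_matches_closed_form_as_dbar_vanishes(self, nocrowding_params):
        from dataclasses import replace

        closed = healthy_equilibrium(nocrowding_params)
        tiny = replace(nocrowding_params, dbar=1e-22)
        numeric = healthy_equilibrium(tiny)
        assert numeric.c1 == pytest.approx(closed.c1, rel=1e-8)
        assert numeric.c2 == pytest.approx(closed.c2, rel=1e-8)

    def test_residual_small_with_crowding(self):
        params = default_params(M1)
        eq = healthy_equilibrium(params)
        dy = rhs(eq, params)
        assert np.max(np.abs(dy)) < 1e-6 * eq.c1

    def test_no_equilibrium_below_half_self_renewal(self):
        with pytest.raises(ValueError):
            ModelParams(
                healthy=LineageParams(a=0.5, p=0.42, d=2.3),
                leukemic=LineageParams(a=0.9, p=1.0, d=4.6),
                k=1e-9,
                dbar=0.0,
                variant=M1,
            ).validate()


class TestSimulate:
    def test_equilibrium_persists(self, healthy_eq):
        params = default_params(M1)
        traj = simulate(params, healthy_eq, 1000.0, points_per_day=0.05)
        assert np.allclose(traj.states[:, 0], healthy_eq.c1, rtol=1e-5)
        assert np.allclose(traj.states[:, 1], healthy_eq.c2, rtol=1e-5)

    def test_subcritical_clone_dies_out(self, healthy_eq):
        params = default_params(M1, a_l=0.85, p_l=1.0)  # a_l < a_c
        init = SystemState(c1=healthy_eq.c1, c2=healthy_eq.c2, l1=1.0, l2=0.0)
        traj = simulate(params, init, 400.0)
        assert traj.final_state.l1 < 1e-3

    def test_positivity_from_boundary_states(self):
        """All compartments stay nonnegative from states with empty pools."""
        params = default_params(M2, a_l=0.95, p_l=0.8)
        for init in [
            SystemState(c1=0.0, c2=0.0, l1=1.0, l2=0.0),
            SystemState(c1=1e3, c2=0.0, l1=0.0, l2=0.0),
            SystemState(c1=0.0, c2=1e9, l1=0.0, l2=1e9),
        ]:
            traj = simulate(params, init, 200.0)
            assert np.all(traj.states >= 0.0)
            assert np.all(np.isfinite(traj.states))

    def test_times_strictly_increasing(self, healthy_eq):
        traj = simulate(default_params(M1), healthy_eq, 50.0)
        assert np.all(np.diff(traj.times) > 0)

    def test_stimulation_window_raises_signal(self, healthy_eq):
        from cytoaml.model import StimulationProtocol

        params = default_params(M1)
        traj = simulate(
            params,
            healthy_eq,
            90.0,
            protocol=StimulationProtocol(t_start=30.0, duration=30.0),
            points_per_day=4.0,
        )
        s = traj.signal()
        inside = (traj.times > 30.0) & (traj.times < 60.0)
        outside_before = traj.times < 29.9
        assert np.all(s[inside] == 1.0)
        assert np.all(s[outside_before] < 1.0)
        # healthy mitotic pool expands under the clamped signal
        i_end = np.searchsorted(traj.times, 60.0)
        assert traj.states[i_end, 0] > 2.0 * healthy_eq.c1

    def test_rejects_nonpositive_horizon(self, healthy_eq):
        with pytest.raises(ValueError):
            simulate(default_params(M1), healthy_eq, 0.0)


class TestBlastFraction:
    @pytest.mark.parametrize(
        "c1,l1,expected",
        [(1e9, 0.0, 0.0), (5e8, 5e8, 0.5), (9e8, 1e8, 0.10)],
    )
    def test_values(self, c1, l1, expected):
        state = SystemState(c1=c1, c2=1e8, l1=l1, l2=0.0)
        assert blast_fraction(state) == pytest.approx(expected)

    def test_empty_marrow_is_undefined(self):
        with pytest.raises(ValueError):
            blast_fraction(SystemState(c1=0.0, c2=1e8, l1=0.0, l2=0.0))


class TestTrajectoryExport:
    def test_tidy_frame_columns(self, healthy_eq):
        traj = simulate(default_params(M1), healthy_eq, 10.0)
        df = traj.to_frame()
        assert list(df.columns) == ["t_days", "c1", "c2", "l1", "l2", "s", "blast_fraction"]
        assert len(df) == len(traj.times)
        assert (df.blast_fraction == 0).all()
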