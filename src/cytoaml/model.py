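"""Core four-compartment ODE models of leukemic vs. healthy hematopoiesis.

Two model variants describe how an expanding leukemic cell population
interacts with healthy granulopoiesis:

* ``CYTOKINE_DEPENDENT`` (Model 1): leukemic cells rely on the same
  endogenous cytokine (G-CSF-like) feedback as healthy cells.  Both
  lineages' mature compartments consume the cytokine, so the signal
  ``s = 1/(1 + k*(c2 + l2))`` couples them.
* ``CYTOKINE_INDEPENDENT`` (Model 2): leukemic cells self-renew at their
  intrinsic fraction regardless of the cytokine level; the signal is
  computed from healthy mature cells only, ``s = 1/(1 + k*c2)``, and
  growth is limited by crowding-induced death in the marrow.

Each lineage has a mitotic compartment (stem + progenitor cells, resident
in the marrow) and a post-mitotic compartment (mature cells).  A division
in the mitotic pool keeps both progeny there with probability ``a*s``
(self-renewal, modulated by the signal for cytokine-responsive cells) and
releases them to the post-mitotic pool otherwise.  Crowding adds a death
term ``dbar*(c1 + l1)`` acting on both mitotic pools, modelling
competition for marrow space.

Units: time in days, cell densities in cells per kg body weight.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "ModelVariant",
    "SystemState",
    "LineageParams",
    "ModelParams",
    "StimulationProtocol",
    "Trajectory",
    "SimulationError",
    "DEFAULT_HEALTHY",
    "default_params",
    "feedback_signal",
    "effective_growth_rate",
    "rhs",
    "healthy_equilibrium",
    "simulate",
    "blast_fraction",
]

#: densities below this are treated as extinct (cells/kg)
EXTINCTION_THRESHOLD = 1e-12


class ModelVariant(enum.Enum):
    """Mode of leukemic cytokine response."""

    CYTOKINE_DEPENDENT = "model1"
    CYTOKINE_INDEPENDENT = "model2"


@dataclass(frozen=True)
class SystemState:
    """Compartment densities (cells/kg) at time ``t`` (days)."""

    c1: float  # healthy mitotic
    c2: float  # healthy post-mitotic
    l1: float  # leukemic mitotic (blasts)
    l2: float  # leukemic post-mitotic
    t: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.c1, self.c2, self.l1, self.l2], dtype=float)

    @staticmethod
    def from_array(y: Sequence[float], t: float = 0.0) -> "SystemState":
        return SystemState(c1=float(y[0]), c2=float(y[1]), l1=float(y[2]), l2=float(y[3]), t=t)

    def validate(self) -> None:
        y = self.as_array()
        if not np.all(np.isfinite(y)):
            raise ValueError(f"non-finite state: {self}")
        if np.any(y < 0):
            raise ValueError(f"negative density in state: {self}")


@dataclass(frozen=True)
class LineageParams:
    """Kinetic parameters of one cell lineage.

    a : fraction of self-renewal, probability in [0, 1] that a progeny
        cell stays in its parent's (mitotic) compartment.
    p : proliferation rate, divisions per day of the mitotic pool.
    d : death rate (1/day) of the post-mitotic pool.  Mitotic cells do
        not die except through crowding.
    """

    a: float
    p: float
    d: float

    def validate(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ValueError(f"self-renewal fraction must be in [0,1], got {self.a}")
        if self.p < 0:
            raise ValueError(f"proliferation rate must be >= 0, got {self.p}")
        if self.d <= 0:
            raise ValueError(f"post-mitotic death rate must be > 0, got {self.d}")


@dataclass(frozen=True)
class ModelParams:
    """Full parameterisation of either model variant.

    k    : cytokine feedback strength, 1/(cells/kg); the signal halves
           when the consuming mature pool reaches 1/k.
    dbar : crowding death coefficient, 1/(cells/kg * day); both mitotic
           pools die at rate dbar*(c1+l1).
    """

    healthy: LineageParams
    leukemic: LineageParams
    k: float
    dbar: float
    variant: ModelVariant

    def validate(self) -> None:
        self.healthy.validate()
        self.leukemic.validate()
        if self.k <= 0:
            raise ValueError(f"feedback strength k must be > 0, got {self.k}")
        if self.dbar < 0:
            raise ValueError(f"crowding coefficient dbar must be >= 0, got {self.dbar}")
        if self.healthy.a <= 0.5:
            raise ValueError(
                "healthy self-renewal must exceed 1/2 for a positive equilibrium, "
                f"got {self.healthy.a}"
            )


@dataclass(frozen=True)
class StimulationProtocol:
    """Exogenous cytokine administration window.

    During [t_start, t_start + duration] the feedback signal experienced
    by cytokine-responsive compartments is clamped to its maximum s = 1
    (saturating exogenous dose).
    """

    t_start: float
    duration: float = 30.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("stimulation duration must be > 0")

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration


class SimulationError(RuntimeError):
    """Raised when the integrator fails; carries the last valid state."""

    def __init__(self, message: str, last_state: Optional[SystemState] = None):
        super().__init__(message)
        self.last_state = last_state


# ---------------------------------------------------------------------------
# Default parameterisation.
#
# Healthy-lineage values are package defaults in the range used by
# feedback models of granulopoiesis: mature (granulocyte) half-life of
# ~7 h gives d_c = 2.3/day; mitotic turnover p_c = 0.42/day; healthy
# self-renewal a_c = 0.93 sets the homeostatic signal s* ~= 1/(2*a_c)
# and thereby the maximal net expansion rate a cytokine-dependent clone
# can achieve.  k = 1e-9 pins the mature equilibrium at
# (2*a_c - 1)/k ~= 8.6e8 cells/kg; dbar = 1e-12 makes crowding death
# negligible at homeostasis (~0.005/day) while still bounding
# cytokine-independent expansion.
# ---------------------------------------------------------------------------

DEFAULT_HEALTHY = LineageParams(a=0.93, p=0.42, d=2.3)
DEFAULT_K = 1e-9
DEFAULT_DBAR = 1e-12
#: default leukemic post-mitotic death rate (blast half-life = leukocyte half-life / 2)
DEFAULT_LEUKEMIC_D = 2 * DEFAULT_HEALTHY.d


def default_params(
    variant: ModelVariant,
    a_l: float = 0.9,
    p_l: float = 1.0,
    d_l: float = DEFAULT_LEUKEMIC_D,
    healthy: LineageParams = DEFAULT_HEALTHY,
    k: float = DEFAULT_K,
    dbar: float = DEFAULT_DBAR,
) -> ModelParams:
    """Convenience constructor using the packaged healthy defaults."""
    params = ModelParams(
        healthy=healthy,
        leukemic=LineageParams(a=a_l, p=p_l, d=d_l),
        k=k,
        dbar=dbar,
        variant=variant,
    )
    params.validate()
    return params


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def feedback_signal(k: float, consuming_mature: float, stimulated: bool = False) -> float:
    """Cytokine feedback signal s in (0, 1].

    ``s = 1/(1 + k*C)`` where C is the mature-cell density consuming the
    cytokine (receptor-mediated endocytosis): ``c2 + l2`` under Model 1,
    ``c2`` under Model 2.  Under exogenous stimulation the signal is
    clamped to its maximum, s = 1.
    """
    if k <= 0:
        raise ValueError(f"feedback strength k must be > 0, got {k}")
    if consuming_mature < 0:
        raise ValueError(f"consuming mature density must be >= 0, got {consuming_mature}")
    if stimulated:
        return 1.0
    return 1.0 / (1.0 + k * consuming_mature)


def effective_growth_rate(a: float, p: float, s: float = 1.0) -> float:
    """Net per-capita production rate (1/day) of a mitotic compartment.

    ``(2*a*s - 1)*p``: each division produces two progeny, each staying
    mitotic with probability ``a*s``.  Positive iff ``a*s > 1/2``.  For
    cytokine-independent leukemic cells s is identically 1.
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"self-renewal fraction must be in [0,1], got {a}")
    if p < 0:
        raise ValueError(f"proliferation rate must be >= 0, got {p}")
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"signal must be in [0,1], got {s}")
    return (2.0 * a * s - 1.0) * p


def _signals(y: np.ndarray, params: ModelParams, stimulated: bool) -> tuple[float, float]:
    """Signal experienced by (healthy, leukemic) mitotic cells."""
    c2, l2 = max(y[1], 0.0), max(y[3], 0.0)
    if params.variant is ModelVariant.CYTOKINE_DEPENDENT:
        s = feedback_signal(params.k, c2 + l2, stimulated)
        return s, s
    s = feedback_signal(params.k, c2, stimulated)
    return s, 1.0  # leukemic cells ignore the cytokine in Model 2


def rhs(state, params: ModelParams, stimulated: bool = False) -> np.ndarray:
    """Time derivatives (cells/kg/day) of the four compartments."""
    if isinstance(state, SystemState):
        state.validate()
        y = state.as_array()
    else:
        y = np.asarray(state, dtype=float)
        if np.any(y < 0):
            raise ValueError(f"negative density in state: {y}")
    return _rhs_raw(y, params, stimulated)


def _rhs_raw(y: np.ndarray, params: ModelParams, stimulated: bool) -> np.ndarray:
    """Derivatives without validation; tolerates tiny solver undershoot."""
    c1, c2, l1, l2 = (max(v, 0.0) for v in y)
    s_h, s_l = _signals(y, params, stimulated)
    hp, lp = params.healthy, params.leukemic
    crowd = params.dbar * (c1 + l1)
    return np.array(
        [
            (2.0 * hp.a * s_h - 1.0) * hp.p * c1 - crowd * c1,
            2.0 * (1.0 - hp.a * s_h) * hp.p * c1 - hp.d * c2,
            (2.0 * lp.a * s_l - 1.0) * lp.p * l1 - crowd * l1,
            2.0 * (1.0 - lp.a * s_l) * lp.p * l1 - lp.d * l2,
        ]
    )


# ---------------------------------------------------------------------------
# Healthy equilibrium
# ---------------------------------------------------------------------------

def healthy_equilibrium(params: ModelParams, tol: float = 1e-10) -> SystemState:
    """Positive steady state of the leukemia-free healthy subsystem.

    For ``dbar = 0`` the closed form is ``s* = 1/(2*a_c)``,
    ``c2* = (2*a_c - 1)/k``, ``c1* = d_c*c2*/p_c``.  For ``dbar > 0`` the
    steady state solves ``(2*a_c*s - 1)*p_c = dbar*c1`` together with the
    signal and mature-cell balance; it is found by bracketed root finding
    and verified against the RHS.
    """
    params.validate()
    hp = params.healthy
    a_c, p_c, d_c, k, dbar = hp.a, hp.p, hp.d, params.k, params.dbar
    if a_c <= 0.5:
        raise ValueError("no positive healthy equilibrium for a_c <= 1/2")

    if dbar == 0.0:
        c2 = (2.0 * a_c - 1.0) / k
        c1 = d_c * c2 / p_c
        eq = SystemState(c1=c1, c2=c2, l1=0.0, l2=0.0)
    else:
        # s(c1) from the mitotic balance; match the two expressions for c2.
        def mismatch(c1: float) -> float:
            s = (1.0 + dbar * c1 / p_c) / (2.0 * a_c)
            c2_from_signal = (1.0 - s) / (k * s)
            c2_from_flux = 2.0 * (1.0 - a_c * s) * p_c * c1 / d_c
            return c2_from_flux - c2_from_signal

        c1_max = (2.0 * a_c - 1.0) * p_c / dbar  # where s(c1) reaches 1
        lo = c1_max * 1e-12
        if mismatch(lo) >= 0 or mismatch(c1_max * (1 - 1e-12)) <= 0:
            raise ValueError("crowding too strong: no positive healthy equilibrium")
        c1 = brentq(mismatch, lo, c1_max * (1 - 1e-12), xtol=1e-6, rtol=1e-14)
        s = (1.0 + dbar * c1 / p_c) / (2.0 * a_c)
        c2 = (1.0 - s) / (k * s)
        eq = SystemState(c1=c1, c2=c2, l1=0.0, l2=0.0)

    resid = _rhs_raw(eq.as_array(), params, stimulated=False)
    scale = max(eq.c1, eq.c2)
    if np.max(np.abs(resid)) > max(tol * scale, 1e-6):
        raise RuntimeError(f"equilibrium residual too large: {resid}")
    return eq


# ---------------------------------------------------------------------------
# Trajectory simulation
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Simulated time course: ``states[i]`` is the state at ``times[i]``."""

    times: np.ndarray  # (n,), days, strictly increasing
    states: np.ndarray  # (n, 4): c1, c2, l1, l2
    params: ModelParams
    protocol: Optional[StimulationProtocol] = None

    def state_at(self, i: int) -> SystemState:
        return SystemState.from_array(self.states[i], t=float(self.times[i]))

    @property
    def final_state(self) -> SystemState:
        return self.state_at(len(self.times) - 1)

    def signal(self) -> np.ndarray:
        """Feedback signal along the trajectory (healthy-cell signal)."""
        out = np.empty(len(self.times))
        for i, (t, y) in enumerate(zip(self.times, self.states)):
            stim = self.protocol is not None and self.protocol.t_start <= t <= self.protocol.t_end
            out[i] = _signals(y, self.params, stim)[0]
        return out

    def blast_fractions(self) -> np.ndarray:
        mitotic = self.states[:, 0] + self.states[:, 2]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(mitotic > 0, self.states[:, 2] / mitotic, np.nan)

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per stored time point."""
        return pd.DataFrame(
            {
                "t_days": self.times,
                "c1": self.states[:, 0],
                "c2": self.states[:, 1],
                "l1": self.states[:, 2],
                "l2": self.states[:, 3],
                "s": self.signal(),
                "blast_fraction": self.blast_fractions(),
            }
        )


def _integrate_piece(
    params: ModelParams,
    y0: np.ndarray,
    t0: float,
    t1: float,
    stimulated: bool,
    t_eval: Optional[np.ndarray],
    events: Optional[list],
    rtol: float,
    atol: float,
):
    sol = solve_ivp(
        lambda t, y: _rhs_raw(y, params, stimulated),
        (t0, t1),
        y0,
        method="LSODA",
        t_eval=t_eval,
        events=events,
        rtol=rtol,
        atol=atol,
    )
    if sol.status == -1:
        last = SystemState.from_array(sol.y[:, -1], t=float(sol.t[-1])) if sol.t.size else None
        raise SimulationError(f"integration failed: {sol.message}", last_state=last)
    return sol


def simulate(
    params: ModelParams,
    init: SystemState,
    t_end: float,
    protocol: Optional[StimulationProtocol] = None,
    t_eval: Optional[np.ndarray] = None,
    events: Optional[list] = None,
    rtol: float = 1e-8,
    atol: float = 1e-6,
    points_per_day: float = 1.0,
) -> Trajectory:
    """Integrate a model trajectory on [0, t_end].

    The stimulation flag is active exactly during the protocol window
    (the trajectory is integrated piecewise across the window edges).
    ``events`` are scipy-style event functions ``f(t, y)``; a terminal
    event truncates the trajectory at the crossing.  Stored output has at
    least ``points_per_day`` points per day unless ``t_eval`` is given.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    init.validate()
    params.validate()

    if t_eval is None:
        n = max(int(math.ceil(t_end * points_per_day)) + 1, 2)
        t_eval = np.linspace(0.0, t_end, n)

    # split integration at protocol edges so the clamp is exact
    edges = [0.0, t_end]
    if protocol is not None:
        for e in (protocol.t_start, protocol.t_end):
            if 0.0 < e < t_end:
                edges.append(e)
    edges = sorted(set(edges))

    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    y = init.as_array().copy()
    terminated = False
    for t0, t1 in zip(edges[:-1], edges[1:]):
        stim = protocol is not None and protocol.t_start <= t0 < protocol.t_end
        mask = (t_eval >= t0) & (t_eval <= t1)
        te = t_eval[mask]
        if te.size == 0 or te[0] > t0:
            te = np.concatenate([[t0], te])
        if te[-1] < t1:
            te = np.concatenate([te, [t1]])
        sol = _integrate_piece(params, y, t0, t1, stim, te, events, rtol, atol)
        times.append(sol.t)
        states.append(sol.y.T)
        if sol.status == 1:  # terminal event fired
            if sol.t_events is not None:
                for t_ev, y_ev in zip(sol.t_events, sol.y_events):
                    if len(t_ev):
                        times.append(np.array([t_ev[-1]]))
                        states.append(y_ev[-1][None, :])
            terminated = True
            break
        y = sol.y[:, -1].copy()

    t_all = np.concatenate(times)
    y_all = np.vstack(states)
    # deduplicate stitching points, clamp undershoot / extinct compartments
    keep = np.concatenate([[True], np.diff(t_all) > 0])
    t_all, y_all = t_all[keep], y_all[keep]
    y_all[y_all < EXTINCTION_THRESHOLD] = 0.0
    if not np.all(np.isfinite(y_all)):
        bad = np.argmax(~np.all(np.isfinite(y_all), axis=1))
        last = SystemState.from_array(np.nan_to_num(y_all[max(bad - 1, 0)]), t=float(t_all[max(bad - 1, 0)]))
        raise SimulationError("non-finite state during integration (blow-up)", last_state=last)
    traj = Trajectory(times=t_all, states=y_all, params=params, protocol=protocol)
    traj.terminated_by_event = terminated  # type: ignore[attr-defined]
    return traj


def blast_fraction(state: SystemState) -> float:
    """Leukemic share of mitotic (marrow-resident) cells, l1/(c1+l1)."""
    state.validate()
    mitotic = state.c1 + state.l1
    if mitotic <= 0:
        raise ValueError("blast fraction undefined: empty marrow (c1 + l1 = 0)")
    return state.l1 / mitotic
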