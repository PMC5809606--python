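"""Least-squares calibration of both models to patient blast time courses.

A patient record is a sparse, irregular series of bone-marrow blast
fractions between first remission and relapse.  Values are either exact
("12% blasts") or intervals ("less than 5% blasts", recorded as bounds).
Both model variants are fitted by bounded multistart nonlinear least
squares; the patient is then classified by the relative RMSE rule: a
model is rejected when its RMSE exceeds the competing model's by more
than 5%.  Patients compatible with the cytokine-dependent model form
group 1, patients compatible only with the cytokine-independent model
form group 2.

Fitted per patient and model: leukemic self-renewal ``a_l``,
proliferation rate ``p_l`` (log scale), post-mitotic death rate ``d_l``
and the residual leukemic burden at remission ``l1(0)`` (log scale).
The healthy lineage, the feedback strength ``k`` and the crowding
coefficient ``dbar`` are held at their population defaults: with a
handful of observations of a single scalar observable per patient,
patient-specific feedback parameters are not identifiable.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from cytoaml.model import (
    DEFAULT_DBAR,
    DEFAULT_HEALTHY,
    DEFAULT_K,
    LineageParams,
    ModelParams,
    ModelVariant,
    SimulationError,
    SystemState,
    healthy_equilibrium,
    simulate,
)

__all__ = [
    "ObservationKind",
    "Observation",
    "ObservationTable",
    "FitBounds",
    "FitResult",
    "GroupLabel",
    "objective",
    "fit_model",
    "select_model",
    "classify_patient",
    "load_observations",
    "observations_to_frame",
]


class ObservationKind(enum.Enum):
    EXACT = "exact"
    INTERVAL = "interval"


@dataclass(frozen=True)
class Observation:
    """One marrow blast measurement at ``t`` days since first remission.

    EXACT observations carry a single blast fraction in ``value``;
    INTERVAL observations carry ``(lower, upper)`` bounds (e.g. a report
    of "less than 5% blasts" is the interval (0, 0.05)).
    """

    t: float
    kind: ObservationKind
    value: Optional[float] = None
    lower: Optional[float] = None
    upper: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind is ObservationKind.EXACT:
            if self.value is None or not 0.0 <= self.value <= 1.0:
                raise ValueError(f"exact blast fraction must be in [0,1], got {self.value}")
        else:
            if self.lower is None or self.upper is None:
                raise ValueError("interval observation needs lower and upper bounds")
            if not 0.0 <= self.lower <= self.upper <= 1.0:
                raise ValueError(f"invalid interval ({self.lower}, {self.upper})")

    def residual(self, model_value: float) -> float:
        """Signed residual of a model prediction against this observation.

        EXACT: model - value.  INTERVAL: distance to the interval, zero
        if the prediction lies inside it.
        """
        if self.kind is ObservationKind.EXACT:
            return model_value - self.value  # type: ignore[operator]
        if model_value < self.lower:  # type: ignore[operator]
            return model_value - self.lower  # type: ignore[operator]
        if model_value > self.upper:  # type: ignore[operator]
            return model_value - self.upper  # type: ignore[operator]
        return 0.0


@dataclass(frozen=True)
class ObservationTable:
    """Time-ordered blast observations of one patient."""

    patient_id: str
    observations: tuple[Observation, ...]

    def __post_init__(self) -> None:
        if len(self.observations) < 2:
            raise ValueError("need at least two observations to fit")
        times = [o.t for o in self.observations]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("observation times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([o.t for o in self.observations])


@dataclass(frozen=True)
class FitBounds:
    """Biologically plausible ranges for the patient-specific parameters.

    Proliferation between one division per two years and one per day;
    self-renewal anywhere in [0, 1]; blast half-life between 25% and
    100% of the leukocyte half-life, i.e. d_l in [d_c, 4*d_c]; residual
    leukemic burden at remission spanning minimal residual disease up to
    just-below-detection levels (log scale).
    """

    p_l: tuple[float, float] = (1.0 / 730.0, 1.0)
    a_l: tuple[float, float] = (0.0, 1.0)
    d_l: tuple[float, float] = (DEFAULT_HEALTHY.d, 4.0 * DEFAULT_HEALTHY.d)
    log10_l1_0: tuple[float, float] = (-2.0, 6.0)

    def __post_init__(self) -> None:
        for name in ("p_l", "a_l", "d_l", "log10_l1_0"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"bounds for {name} must satisfy lower < upper")


@dataclass
class FitResult:
    """Best fit of one model variant to one patient."""

    variant: ModelVariant
    patient_id: str
    best_params: Optional[ModelParams]
    l1_0: float
    rmse: float
    n_obs: int
    converged: bool
    multistart_log: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "variant": self.variant.value,
            "patient_id": self.patient_id,
            "rmse": self.rmse,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "l1_0": self.l1_0,
        }
        if self.best_params is not None:
            lp = self.best_params.leukemic
            d.update(a_l=lp.a, p_l=lp.p, d_l=lp.d)
        return d


class GroupLabel(enum.Enum):
    """Prognostic group from the per-model compatibility calls."""

    GROUP1_CYTOKINE_DEPENDENT_COMPATIBLE = "group1"
    GROUP2_ONLY_CYTOKINE_INDEPENDENT = "group2"
    UNDETERMINED = "undetermined"


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def _predicted_blast_fractions(
    params: ModelParams,
    l1_0: float,
    times: np.ndarray,
    rtol: float,
    atol: float,
) -> np.ndarray:
    """Blast fractions at observation times, starting from remission:
    healthy lineage at equilibrium plus residual burden l1_0."""
    eq = healthy_equilibrium(params)
    init = SystemState(c1=eq.c1, c2=eq.c2, l1=l1_0, l2=0.0)
    t_end = float(times[-1])
    t_eval = times
    if times[0] > 0.0:
        t_eval = np.concatenate([[0.0], times])
    traj = simulate(params, init, t_end if t_end > 0 else 1.0, t_eval=t_eval, rtol=rtol, atol=atol)
    bf = traj.blast_fractions()
    return np.interp(times, traj.times, bf)


def residuals(
    params: ModelParams,
    l1_0: float,
    obs: ObservationTable,
    rtol: float = 1e-6,
    atol: float = 1e-3,
) -> np.ndarray:
    """Residual vector (blast-fraction units) of a model against the data."""
    predicted = _predicted_blast_fractions(params, l1_0, obs.times, rtol, atol)
    return np.array([o.residual(p) for o, p in zip(obs.observations, predicted)])


def objective(
    params: ModelParams,
    variant: ModelVariant,
    obs: ObservationTable,
    l1_0: float = 1.0,
) -> float:
    """Root mean square deviation of one model fit, in blast-fraction units.

    Simulation failures yield an infinite objective (the point is
    rejected by the optimiser).
    """
    if params.variant is not variant:
        raise ValueError("params.variant does not match requested variant")
    try:
        r = residuals(params, l1_0, obs)
    except (SimulationError, RuntimeError, ValueError):
        return math.inf
    return float(np.sqrt(np.mean(r**2)))


# ---------------------------------------------------------------------------
# Multistart bounded fit
# ---------------------------------------------------------------------------

def _theta_to_params(
    theta: np.ndarray, variant: ModelVariant, bounds: FitBounds
) -> tuple[ModelParams, float]:
    """Map the unit-cube optimiser vector to model parameters.

    theta = (a_l, log p_l, d_l, log10 l1_0), each scaled to [0, 1];
    proliferation and residual burden vary on log scale.
    """
    a = bounds.a_l[0] + theta[0] * (bounds.a_l[1] - bounds.a_l[0])
    log_p = math.log(bounds.p_l[0]) + theta[1] * (math.log(bounds.p_l[1]) - math.log(bounds.p_l[0]))
    d = bounds.d_l[0] + theta[2] * (bounds.d_l[1] - bounds.d_l[0])
    log10_l1 = bounds.log10_l1_0[0] + theta[3] * (bounds.log10_l1_0[1] - bounds.log10_l1_0[0])
    a = min(max(a, 0.0), 1.0)
    params = ModelParams(
        healthy=DEFAULT_HEALTHY,
        leukemic=LineageParams(a=a, p=math.exp(log_p), d=d),
        k=DEFAULT_K,
        dbar=DEFAULT_DBAR,
        variant=variant,
    )
    return params, 10.0**log10_l1


def _params_to_theta(
    a: float, p: float, d: float, l1_0: float, bounds: FitBounds
) -> np.ndarray:
    """Inverse of ``_theta_to_params`` with clipping into the unit cube."""
    th = np.array(
        [
            (a - bounds.a_l[0]) / (bounds.a_l[1] - bounds.a_l[0]),
            (math.log(max(p, bounds.p_l[0])) - math.log(bounds.p_l[0]))
            / (math.log(bounds.p_l[1]) - math.log(bounds.p_l[0])),
            (d - bounds.d_l[0]) / (bounds.d_l[1] - bounds.d_l[0]),
            (math.log10(max(l1_0, 1e-300)) - bounds.log10_l1_0[0])
            / (bounds.log10_l1_0[1] - bounds.log10_l1_0[0]),
        ]
    )
    return np.clip(th, 1e-3, 1.0 - 1e-3)


def _heuristic_starts(
    obs: ObservationTable, variant: ModelVariant, bounds: FitBounds
) -> list[np.ndarray]:
    """Data-informed starting points from exponential growth matching.

    The expanding-clone region is a small corner of the box (for the
    cytokine-dependent model only ``a_l > 1/(2 s*)`` grows), and outside
    it every residual is flat, so random starts alone stall.  From the
    exact observations (or the interval midpoints as a fallback) the net
    growth rate ``g`` of ``blast ~ (l1_0/c1*) e^{g t}`` is estimated by
    a log-linear fit; for a few candidate proliferation rates the
    matching self-renewal ``a_l`` and anchor burden ``l1_0`` are solved
    and used as extra starts.
    """
    eq = healthy_equilibrium(
        ModelParams(
            healthy=DEFAULT_HEALTHY,
            leukemic=LineageParams(a=0.9, p=1.0, d=2 * DEFAULT_HEALTHY.d),
            k=DEFAULT_K,
            dbar=DEFAULT_DBAR,
            variant=variant,
        )
    )
    pts = [
        (o.t, o.value)
        for o in obs.observations
        if o.kind is ObservationKind.EXACT and o.value and o.value > 0
    ]
    if len(pts) < 2:  # fall back on interval midpoints to anchor a slope
        pts = pts + [
            (o.t, max((o.lower + o.upper) / 2.0, 1e-4))
            for o in obs.observations
            if o.kind is ObservationKind.INTERVAL
        ]
        pts.sort()
    if len(pts) < 2:
        return []
    t_arr = np.array([p[0] for p in pts])
    b_arr = np.array([p[1] for p in pts])
    # log-linear growth of the odds l1/c1 = b/(1-b)
    y = np.log(b_arr / (1.0 - b_arr))
    g, intercept = np.polyfit(t_arr, y, 1)
    l1_0 = eq.c1 * math.exp(intercept)
    s_star = 1.0 / (1.0 + DEFAULT_K * eq.c2) if variant is ModelVariant.CYTOKINE_DEPENDENT else 1.0
    starts = []
    for p_cand in (0.25, 1.0):
        a_cand = (g / p_cand + 1.0) / (2.0 * s_star)
        if not 0.0 <= a_cand <= 1.0:
            a_cand = min(max(a_cand, 0.0), 1.0)
        starts.append(
            _params_to_theta(a_cand, p_cand, 2.0 * DEFAULT_HEALTHY.d, l1_0, bounds)
        )
    return starts


def fit_model(
    variant: ModelVariant,
    obs: ObservationTable,
    bounds: Optional[FitBounds] = None,
    n_starts: int = 32,
    seed: int = 0,
    max_nfev: int = 80,
) -> FitResult:
    """Bounded multistart nonlinear least squares for one model variant.

    Starting points are a seeded Latin hypercube over the (log-scaled)
    bounds plus deterministic growth-matching heuristics; each start
    runs a trust-region-reflective least-squares solve.  Deterministic
    given ``seed``.
    """
    if bounds is None:
        bounds = FitBounds()
    n_obs = len(obs.observations)

    def cost(theta: np.ndarray) -> np.ndarray:
        params, l1_0 = _theta_to_params(theta, variant, bounds)
        try:
            return residuals(params, l1_0, obs)
        except (SimulationError, RuntimeError, ValueError):
            return np.full(n_obs, 1e3)

    sampler = qmc.LatinHypercube(d=4, seed=seed)
    starts = list(sampler.random(n=n_starts)) + _heuristic_starts(obs, variant, bounds)

    best_theta, best_rmse, log = None, math.inf, []
    for i, x0 in enumerate(starts):
        try:
            res = least_squares(
                cost,
                x0,
                bounds=(np.zeros(4), np.ones(4)),
                method="trf",
                diff_step=1e-4,
                max_nfev=max_nfev,
            )
        except Exception as exc:  # defensive: a start must never kill the fit
            log.append({"start": i, "error": str(exc)})
            continue
        rmse = float(np.sqrt(np.mean(res.fun**2)))
        log.append({"start": i, "rmse": rmse, "nfev": res.nfev, "status": res.status})
        if rmse < best_rmse:
            best_rmse, best_theta = rmse, res.x
    if best_theta is None or not math.isfinite(best_rmse) or best_rmse >= 1e3:
        return FitResult(
            variant=variant,
            patient_id=obs.patient_id,
            best_params=None,
            l1_0=math.nan,
            rmse=math.inf,
            n_obs=n_obs,
            converged=False,
            multistart_log=log,
        )
    params, l1_0 = _theta_to_params(best_theta, variant, bounds)
    return FitResult(
        variant=variant,
        patient_id=obs.patient_id,
        best_params=params,
        l1_0=l1_0,
        rmse=best_rmse,
        n_obs=n_obs,
        converged=True,
        multistart_log=log,
    )


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

#: RMSE differences below this (blast-fraction units, half a percentage
#: point of marrow blasts) cannot discriminate between models: far below
#: measurement noise, the relative rule would compare numerical jitter.
RMSE_ABS_FLOOR = 0.005


def select_model(
    fit1: FitResult, fit2: FitResult, tol: float = 0.05, abs_floor: float = RMSE_ABS_FLOOR
) -> tuple[bool, bool, GroupLabel]:
    """Apply the relative-RMSE rule to a pair of fits.

    Returns ``(model1_compatible, model2_compatible, group)``.  Model 2
    fits better iff ``rmse1 > (1 + tol)*rmse2`` and vice versa; within
    the band both models are compatible.  RMSE differences below
    ``abs_floor`` never discriminate (both fits essentially interpolate
    the data).  Patients compatible with the cytokine-dependent model
    (whether or not Model 2 also fits) pool into group 1; only-Model-2
    patients form group 2.
    """
    if fit1.variant is not ModelVariant.CYTOKINE_DEPENDENT:
        raise ValueError("fit1 must be the cytokine-dependent fit")
    if fit2.variant is not ModelVariant.CYTOKINE_INDEPENDENT:
        raise ValueError("fit2 must be the cytokine-independent fit")
    if not (fit1.converged and fit2.converged):
        return False, False, GroupLabel.UNDETERMINED
    model2_better = fit1.rmse > (1.0 + tol) * fit2.rmse and fit1.rmse - fit2.rmse > abs_floor
    model1_better = fit2.rmse > (1.0 + tol) * fit1.rmse and fit2.rmse - fit1.rmse > abs_floor
    model1_compatible = not model2_better
    model2_compatible = not model1_better
    group = (
        GroupLabel.GROUP2_ONLY_CYTOKINE_INDEPENDENT
        if model2_better
        else GroupLabel.GROUP1_CYTOKINE_DEPENDENT_COMPATIBLE
    )
    return model1_compatible, model2_compatible, group


def classify_patient(
    obs: ObservationTable,
    bounds: Optional[FitBounds] = None,
    n_starts: int = 32,
    seed: int = 0,
    tol: float = 0.05,
) -> tuple[FitResult, FitResult, GroupLabel]:
    """Fit both models and assign the prognostic group."""
    fit1 = fit_model(ModelVariant.CYTOKINE_DEPENDENT, obs, bounds, n_starts, seed)
    fit2 = fit_model(ModelVariant.CYTOKINE_INDEPENDENT, obs, bounds, n_starts, seed + 1)
    _, _, group = select_model(fit1, fit2, tol)
    return fit1, fit2, group


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def observations_to_frame(tables: Sequence[ObservationTable]) -> pd.DataFrame:
    """Serialise observation tables (percent scale, interval columns)."""
    rows = []
    for tab in tables:
        for o in tab.observations:
            rows.append(
                {
                    "patient_id": tab.patient_id,
                    "t_days": o.t,
                    "blast_pct_exact": 100 * o.value if o.kind is ObservationKind.EXACT else np.nan,
                    "blast_pct_lower": 100 * o.lower if o.kind is ObservationKind.INTERVAL else np.nan,
                    "blast_pct_upper": 100 * o.upper if o.kind is ObservationKind.INTERVAL else np.nan,
                }
            )
    return pd.DataFrame(rows)


def load_observations(path: str | Path) -> list[ObservationTable]:
    """Read the observation CSV dialect; percentages become fractions."""
    df = pd.read_csv(path)
    required = {"patient_id", "t_days", "blast_pct_exact", "blast_pct_lower", "blast_pct_upper"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"observation CSV missing columns: {sorted(missing)}")
    tables = []
    for pid, grp in df.groupby("patient_id", sort=False):
        obs = []
        for _, row in grp.sort_values("t_days").iterrows():
            if not np.isnan(row["blast_pct_exact"]):
                obs.append(
                    Observation(
                        t=float(row["t_days"]),
                        kind=ObservationKind.EXACT,
                        value=float(row["blast_pct_exact"]) / 100.0,
                    )
                )
            else:
                obs.append(
                    Observation(
                        t=float(row["t_days"]),
                        kind=ObservationKind.INTERVAL,
                        lower=float(row["blast_pct_lower"]) / 100.0,
                        upper=float(row["blast_pct_upper"]) / 100.0,
                    )
                )
        tables.append(ObservationTable(patient_id=str(pid), observations=tuple(obs)))
    return tables
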