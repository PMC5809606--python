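"""Synthetic patient cohort generator.

Emulates the structure of a retrospective AML cohort with documented
remission and marrow relapse: per patient, a generating model variant
and leukemic parameters are drawn, the remission-to-relapse blast
trajectory is simulated from a residual leukemic burden at remission,
and marrow examinations are scheduled at irregular 30-90 day intervals
until relapse is documented (blast fraction above the detection level).
Measured blast fractions carry truncated-Gaussian noise, and values
below the clinical reporting threshold are recorded as interval
observations ("less than 5% blasts").  Overall survival is drawn from a
group-specific exponential distribution with independent exponential
censoring.

Cohort defaults encode the study conditions the downstream analysis
assumes: cytokine-dependent patients relapse slowly (their expansion is
capped by the feedback, self-renewal close to its maximum still yields
net growth below ~0.08/day), while cytokine-independent patients are
drawn with effective growth rates that produce fast relapses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from cytoaml.calibration import Observation, ObservationKind, ObservationTable, observations_to_frame
from cytoaml.model import (
    ModelParams,
    ModelVariant,
    SystemState,
    default_params,
    healthy_equilibrium,
    simulate,
)

__all__ = [
    "CohortConfig",
    "CohortRecord",
    "generate_cohort",
    "draw_survival",
    "cohort_to_frames",
    "write_cohort",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults are the packaged study conditions."""

    n_patients: int = 41
    fraction_model2: float = 17.0 / 41.0
    # leukemic parameter priors (uniform; proliferation shared by both groups)
    a_l_range_model1: tuple[float, float] = (0.95, 1.0)
    a_l_range_model2: tuple[float, float] = (0.85, 1.0)
    p_l_range: tuple[float, float] = (0.3, 1.0)
    d_l_factor_range: tuple[float, float] = (1.0, 4.0)  # x healthy mature death rate
    log10_l1_0_range: tuple[float, float] = (2.0, 3.0)  # residual burden at remission
    # observation schedule
    visit_interval: tuple[float, float] = (30.0, 90.0)
    relapse_detection: float = 0.25  # blast fraction documenting relapse, ends follow-up
    horizon: float = 1500.0  # days; parameter draws not relapsing by then are redrawn
    noise_sd: float = 0.02  # blast-fraction measurement noise (truncated Gaussian)
    reporting_threshold: float = 0.05  # below this, records become "less than" intervals
    # survival model (exponential, group-specific medians in days)
    median_survival_model1: float = 700.0
    median_survival_model2: float = 350.0
    censoring_fraction: float = 0.1
    seed: int = 0
    max_redraws: int = 50

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.fraction_model2 <= 1.0:
            raise ValueError("fraction_model2 must be a probability")
        if self.median_survival_model1 <= 0 or self.median_survival_model2 <= 0:
            raise ValueError("survival medians must be positive")
        if not 0.0 <= self.censoring_fraction < 1.0:
            raise ValueError("censoring_fraction must be in [0,1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class CohortRecord:
    """One synthetic patient with ground truth attached."""

    patient_id: str
    true_variant: ModelVariant
    true_params: ModelParams
    true_l1_0: float
    observations: ObservationTable
    os_days: float
    event: bool
    relapse_day: float


def _draw_params(cfg: CohortConfig, variant: ModelVariant, rng: np.random.Generator):
    if variant is ModelVariant.CYTOKINE_DEPENDENT:
        a_l = rng.uniform(*cfg.a_l_range_model1)
    else:
        a_l = rng.uniform(*cfg.a_l_range_model2)
    p_l = rng.uniform(*cfg.p_l_range)
    d_l_factor = rng.uniform(*cfg.d_l_factor_range)
    params = default_params(variant, a_l=a_l, p_l=p_l)
    params = replace(params, leukemic=replace(params.leukemic, d=d_l_factor * params.healthy.d))
    l1_0 = 10.0 ** rng.uniform(*cfg.log10_l1_0_range)
    return params, l1_0


def _relapse_event(detection: float):
    ratio = detection / (1.0 - detection)

    def event(t, y):
        return y[2] - ratio * y[0]

    event.terminal = True
    event.direction = 1
    return event


def _observe(bf_true: float, cfg: CohortConfig, rng: np.random.Generator, t: float) -> Observation:
    """Noisy measurement + reporting convention for one marrow exam."""
    if cfg.noise_sd > 0:
        # truncated Gaussian: redraw until inside [0, 1]
        for _ in range(100):
            measured = bf_true + rng.normal(0.0, cfg.noise_sd)
            if 0.0 <= measured <= 1.0:
                break
        else:
            measured = min(max(bf_true, 0.0), 1.0)
    else:
        measured = bf_true
    if measured < cfg.reporting_threshold:
        return Observation(
            t=t, kind=ObservationKind.INTERVAL, lower=0.0, upper=cfg.reporting_threshold
        )
    return Observation(t=t, kind=ObservationKind.EXACT, value=measured)


def _simulate_patient(
    cfg: CohortConfig, variant: ModelVariant, rng: np.random.Generator, patient_id: str
) -> Optional[tuple[ModelParams, float, ObservationTable, float]]:
    """One remission-to-relapse course, or None if no relapse in horizon."""
    params, l1_0 = _draw_params(cfg, variant, rng)
    eq = healthy_equilibrium(params)
    init = SystemState(c1=eq.c1, c2=eq.c2, l1=l1_0, l2=0.0)
    traj = simulate(
        params,
        init,
        cfg.horizon,
        events=[_relapse_event(cfg.relapse_detection)],
        points_per_day=1.0,
    )
    if not getattr(traj, "terminated_by_event", False):
        return None
    relapse_day = float(traj.times[-1])

    bf = traj.blast_fractions()
    # marrow exams from remission (t=0) every 30-90 days; the exam documenting
    # relapse (at or past the detection crossing) ends the series
    times = [0.0]
    while times[-1] < relapse_day:
        times.append(times[-1] + rng.uniform(*cfg.visit_interval))
    times[-1] = min(times[-1], relapse_day)  # relapse marrow is examined at documentation
    if len(times) < 2:
        return None
    obs = tuple(
        _observe(float(np.interp(t, traj.times, bf)), cfg, rng, t) for t in times
    )
    table = ObservationTable(patient_id=patient_id, observations=obs)
    return params, l1_0, table, relapse_day


def draw_survival(
    variant: ModelVariant, cfg: CohortConfig, rng: np.random.Generator
) -> tuple[float, bool]:
    """Overall survival (days since remission) and death-observed flag.

    Death times are exponential with the group median; censoring is an
    independent exponential calibrated so the expected censored fraction
    matches ``censoring_fraction``.
    """
    median = (
        cfg.median_survival_model1
        if variant is ModelVariant.CYTOKINE_DEPENDENT
        else cfg.median_survival_model2
    )
    rate_death = LN2 / median
    t_death = rng.exponential(1.0 / rate_death)
    if cfg.censoring_fraction <= 0.0:
        return t_death, True
    f = cfg.censoring_fraction
    rate_cens = rate_death * f / (1.0 - f)
    t_cens = rng.exponential(1.0 / rate_cens)
    return min(t_death, t_cens), t_death <= t_cens


def generate_cohort(config: CohortConfig) -> list[CohortRecord]:
    """Draw a full synthetic cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n2 = int(round(config.n_patients * config.fraction_model2))
    variants = [ModelVariant.CYTOKINE_INDEPENDENT] * n2 + [
        ModelVariant.CYTOKINE_DEPENDENT
    ] * (config.n_patients - n2)
    rng.shuffle(variants)  # type: ignore[arg-type]

    records = []
    for i, variant in enumerate(variants):
        pid = f"P{i + 1:03d}"
        course = None
        for _ in range(config.max_redraws):
            course = _simulate_patient(config, variant, rng, pid)
            if course is not None:
                break
        if course is None:
            raise RuntimeError(
                f"patient {pid}: no relapse within {config.horizon} days after "
                f"{config.max_redraws} parameter redraws"
            )
        params, l1_0, table, relapse_day = course
        os_days, event = draw_survival(variant, config, rng)
        records.append(
            CohortRecord(
                patient_id=pid,
                true_variant=variant,
                true_params=params,
                true_l1_0=l1_0,
                observations=table,
                os_days=os_days,
                event=event,
                relapse_day=relapse_day,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Serialisation: observation CSV + truth sidecar + survival CSV
# ---------------------------------------------------------------------------

def cohort_to_frames(records: list[CohortRecord]) -> dict[str, pd.DataFrame]:
    obs = observations_to_frame([r.observations for r in records])
    truth = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "true_variant": [r.true_variant.value for r in records],
            "a_l": [r.true_params.leukemic.a for r in records],
            "p_l": [r.true_params.leukemic.p for r in records],
            "d_l": [r.true_params.leukemic.d for r in records],
            "l1_0": [r.true_l1_0 for r in records],
            "relapse_day": [r.relapse_day for r in records],
        }
    )
    survival = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "os_days": [r.os_days for r in records],
            "event": [int(r.event) for r in records],
        }
    )
    return {"observations": obs, "truth": truth, "survival": survival}


def write_cohort(records: list[CohortRecord], outdir: str | Path) -> dict[str, Path]:
    """Write the three cohort CSVs; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = cohort_to_frames(records)
    paths = {}
    for name, df in frames.items():
        p = outdir / f"cohort_{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        paths[name] = p
    return paths
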