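import numpy as np
import pytest

from cytoaml.model import (
    DEFAULT_HEALTHY,
    LineageParams,
    ModelParams,
    ModelVariant,
    default_params,
    healthy_equilibrium,
)

M1 = ModelVariant.CYTOKINE_DEPENDENT
M2 = ModelVariant.CYTOKINE_INDEPENDENT


@pytest.fixture(scope="session")
def healthy_eq():
    """Healthy equilibrium under the packaged defaults."""
    return healthy_equilibrium(default_params(M1))


@pytest.fixture(scope="session")
def nocrowding_params():
    """Model 1 parameters with dbar = 0 (closed-form equilibrium regime)."""
    return ModelParams(
        healthy=LineageParams(a=0.87, p=0.42, d=2.3),
        leukemic=LineageParams(a=0.9, p=1.0, d=4.6),
        k=1e-9,
        dbar=0.0,
        variant=M1,
    )


@pytest.fixture(scope="session")
def cohort_classification():
    """Seeded 41-patient synthetic cohort run through the full
    fit-both-models + RMSE-selection pipeline.

    Session-scoped: this is the expensive end-to-end computation shared
    by the recovery and fast-relapse-discriminator tests.
    """
    from cytoaml.calibration import GroupLabel, classify_patient
    from cytoaml.cohort import CohortConfig, generate_cohort

    records = generate_cohort(CohortConfig(seed=1))
    results = []
    for i, rec in enumerate(records):
        fit1, fit2, group = classify_patient(rec.observations, n_starts=6, seed=1 + 101 * i)
        results.append((rec, fit1, fit2, group))
    return results
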