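"""Shared fixtures: simulated cohorts reused across test modules."""

from __future__ import annotations

import dataclasses

import pandas as pd
import pytest

from petpair import default_acquisition_configs, generate_cohort
from petpair.pipeline import RunConfig, quantify_case

COHORT_SEED = 314159
COHORT_N = 20


@pytest.fixture(scope="session")
def cohort_default():
    """20 paired cases under the default (noisy) acquisition configs."""
    return generate_cohort(COHORT_N, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort_noiseless():
    """Same cohort conditions with the acquisition noise switched off."""
    configs = default_acquisition_configs()
    quiet = {
        k: dataclasses.replace(v, noise_coefficient=0.0) for k, v in configs.items()
    }
    return generate_cohort(
        COHORT_N, seed=COHORT_SEED, db_config=quiet["db"], wb_config=quiet["wb"]
    )


@pytest.fixture(scope="session")
def metrics_default(cohort_default):
    """Uptake-metric table (both modalities) for the default cohort."""
    cfg = RunConfig(n_cases=COHORT_N, seed=COHORT_SEED)
    rows = [
        quantify_case(case, modality, cfg)
        for case in cohort_default
        for modality in ("db", "wb")
    ]
    return pd.DataFrame(rows)
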