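"""Shared fixtures.

The expensive session fixtures (full fixture fits, 500-trial simulation runs,
1000-trial null calibrations) are built once and shared across the acceptance
tests; everything else is cheap and local.
"""

import numpy as np
import pytest

import bayesdose as bd
from bayesdose.sampler import SamplerSettings

FIXTURES = ("LargeMonotone", "NBHOnly", "OverDose")
TABLE_MODELS = ("hier_emax", "ndlm1", "ndlm2")
SCENARIOS = ("Large", "NBH", "OverDose")


@pytest.fixture(scope="session")
def fixture_fits():
    """Posterior fits of the three reported models on the three printed datasets."""
    settings = lambda seed: SamplerSettings(n_burn=2500, n_keep=5000, n_chains=4, seed=seed)
    fits = {}
    seed = 101
    for fixture in FIXTURES:
        data = bd.fixture_dataset(fixture)
        for mid in TABLE_MODELS:
            seed += 1
            fits[(fixture, mid)] = bd.model_for(mid, data).fit(settings=settings(seed))
    return fits


@pytest.fixture(scope="session")
def sim_runs():
    """500-trial simulation runs for each (model, scenario) with calibrated beta."""
    runs = {}
    seed = 2000
    for mid in TABLE_MODELS:
        for scen in SCENARIOS:
            seed += 1
            runs[(mid, scen)] = bd.run_trials(mid, scen, 500, seed=seed)
    return runs


@pytest.fixture(scope="session")
def null_calibrations():
    """1000-null-trial beta calibrations per model (target type I error 10%)."""
    return {
        mid: bd.calibrate_beta(mid, target_alpha=0.10, n_trials=1000, seed=3000 + i)
        for i, mid in enumerate(TABLE_MODELS)
    }
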