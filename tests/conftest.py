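"""Shared fixtures: one small simulated world reused across the suite."""

import numpy as np
import pytest

from cvdsynth.fixtures import (
    WorldConfig,
    derive_admin_records,
    derive_biased_cohort,
    derive_census_crosstab,
    make_ground_truth,
)


@pytest.fixture(scope="session")
def world_cfg() -> WorldConfig:
    return WorldConfig(n_truth=20_000, master_seed=11, survey_n=4_000)


@pytest.fixture(scope="session")
def truth(world_cfg):
    return make_ground_truth(world_cfg, np.random.default_rng(11))


@pytest.fixture(scope="session")
def census(truth):
    rng = np.random.default_rng(12)
    return derive_census_crosstab(
        truth, unknown_ethnicity_rate=0.02, unknown_nzdep_rate=0.01, rng=rng
    )


@pytest.fixture(scope="session")
def admin(truth):
    return derive_admin_records(truth)


@pytest.fixture(scope="session")
def cohort(truth, world_cfg):
    return derive_biased_cohort(truth, world_cfg, 4_000, np.random.default_rng(13))
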