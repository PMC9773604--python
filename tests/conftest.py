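import numpy as np
import pytest
from hypothesis import settings

import dentalage as da

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def model() -> da.MaturationModel:
    return da.default_model()


@pytest.fixture(scope="session")
def zero_noise_model() -> da.MaturationModel:
    return da.default_model(sigma_subject=0.0, sigma_tooth=0.0)


@pytest.fixture(scope="session")
def cohort(model) -> da.Dataset:
    """A small default-calibration cohort shared by read-only tests."""
    return da.simulate_cohort(da.CohortSpec(n=200, seed=7), model)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_record(stages_by_tooth=None, default_stage="H", **kwargs) -> da.SubjectRecord:
    stages = {t: default_stage for t in da.TOOTH_IDS}
    if stages_by_tooth:
        stages.update(stages_by_tooth)
    params = dict(subject_id="s1", sex=da.Sex.MALE, ca_years=12.0, stages=stages)
    params.update(kwargs)
    return da.SubjectRecord(**params)


@pytest.fixture(scope="session")
def flat_table() -> da.ScoringTable:
    """Toy complete table scoring every (sex, tooth, stage) as 1.0 year."""
    entries = {
        (sex, tooth, stage): 1.0
        for sex in (da.Sex.MALE, da.Sex.FEMALE)
        for tooth in da.TOOTH_IDS
        for stage in da.STAGES[1:]
    }
    return da.ScoringTable(entries)
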