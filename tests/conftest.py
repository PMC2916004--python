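import numpy as np
import pytest

from crossmeta.data_model import ArmData, Dataset, StudyRecord, StudyType
from crossmeta.mcmc import MCMCConfig


def make_study(
    study_id="s1",
    study_type=StudyType.RANDOMISED,
    r_t=5,
    n_t=100,
    r_c=10,
    n_c=100,
    cov_t=None,
    cov_c=None,
):
    return StudyRecord(
        study_id=study_id,
        study_type=study_type,
        treatment_arm=ArmData(events=r_t, total=n_t, covariates=dict(cov_t or {})),
        control_arm=ArmData(events=r_c, total=n_c, covariates=dict(cov_c or {})),
    )


@pytest.fixture
def tiny_dataset():
    """2 randomised + 4 non-randomised studies with one covariate (age)."""
    rng = np.random.default_rng(42)
    studies = []
    for i in range(2):
        studies.append(
            make_study(
                f"rct_{i}",
                StudyType.RANDOMISED,
                r_t=int(rng.integers(3, 12)),
                n_t=120,
                r_c=int(rng.integers(8, 20)),
                n_c=120,
                cov_t={"age": 70.0 + rng.normal(0, 1)},
                cov_c={"age": 70.0 + rng.normal(0, 1)},
            )
        )
    for i in range(4):
        studies.append(
            make_study(
                f"nrs_{i}",
                StudyType.NON_RANDOMISED,
                r_t=int(rng.integers(3, 12)),
                n_t=150,
                r_c=int(rng.integers(8, 20)),
                n_c=150,
                cov_t={"age": 72.0 + rng.normal(0, 1)},
                cov_c={"age": 69.0 + rng.normal(0, 1)},
            )
        )
    return Dataset(studies=studies, covariate_names=["age"])


@pytest.fixture
def fast_mcmc():
    """A short but adapted configuration for smoke-level posterior checks."""
    return MCMCConfig(burn_in=800, iterations=1500, chains=2, seed=123)
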