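import numpy as np
import pandas as pd
import pytest

from metabotype.containers import StudyMatrix
from metabotype.synth import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Small default-design cohort shared by read-only tests."""
    return generate_cohort(CohortConfig(seed=5).scaled(120))


@pytest.fixture(scope="session")
def planted_cohort():
    """Defaults-at-scale cohort (3 subtypes, effect 0.8, n=200)."""
    return generate_cohort(CohortConfig(seed=11).scaled(200))


def make_study(values, roles, batches, phases, stage="raw"):
    """Hand-build a StudyMatrix from plain lists/arrays."""
    values = pd.DataFrame(values)
    values.index = [f"s{i}" for i in range(len(values))]
    values.columns = [f"m{j}" for j in range(values.shape[1])]
    meta = pd.DataFrame(
        {"role": roles, "batch": batches, "phase": phases}, index=values.index
    )
    return StudyMatrix(values=values, sample_meta=meta, stage=stage)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
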