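import numpy as np
import pytest

from triagesim import BASELINE_TRIANGLE, TriangularParams
from triagesim.population import Cohort


@pytest.fixture
def baseline() -> TriangularParams:
    return BASELINE_TRIANGLE


@pytest.fixture
def hypertension() -> TriangularParams:
    return TriangularParams(minimum=0.19, maximum=0.63, mode=0.23)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_cohort(ids, p, comorbid=None, y=None, condition=None) -> Cohort:
    """Hand-build a cohort from plain lists (test helper)."""
    n = len(ids)
    p = np.asarray(p, dtype=float)
    if comorbid is None:
        comorbid = np.zeros(n, dtype=bool)
    if y is None:
        y = np.zeros(n, dtype=np.int8)
    if condition is None:
        condition = np.where(np.asarray(comorbid, bool), 0, -1).astype(np.int64)
    return Cohort(
        ids=np.asarray(ids, dtype=np.int64),
        comorbid=np.asarray(comorbid, dtype=bool),
        condition=np.asarray(condition, dtype=np.int64),
        p=p,
        y=np.asarray(y, dtype=np.int8),
    )
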