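import numpy as np
import pandas as pd
import pytest

from fibromarker import CohortDesign, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-design cohort (9 patients x 3 sites, 2000 genes), reused
    read-only across tests."""
    design = CohortDesign(seed=11)
    matrix, meta, truth = generate_cohort(design)
    return design, matrix, meta, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_expression():
    """Tiny well-conditioned log-scale samples x genes frame."""
    r = np.random.default_rng(7)
    X = pd.DataFrame(
        r.normal(5, 1, size=(20, 10)),
        columns=[f"G{i}" for i in range(10)],
        index=[f"s{i}" for i in range(20)],
    )
    y = np.array([0] * 10 + [1] * 10)
    X.iloc[:, 0] += y * 2.0
    return X, y
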