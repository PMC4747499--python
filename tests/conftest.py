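import numpy as np
import pandas as pd
import pytest

from ctbayes.qpcr import CtMatrix
from ctbayes.simdata import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default-panel simulated dataset shared across read-only tests."""
    return generate_dataset(SimulationConfig(seed=42))


@pytest.fixture()
def toy_ct():
    """4 samples x 3 assays, fully detected, hand-set values."""
    values = pd.DataFrame(
        {
            "A": [20.0, 21.0, 22.0, 23.0],
            "B": [25.0, 26.5, 27.0, 28.5],
            "C": [30.0, 29.0, 31.0, 30.5],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return CtMatrix(values)


@pytest.fixture()
def small_samples():
    return pd.DataFrame(
        {
            "age_years": [5.0, 6.0, 40.0, 45.0],
            "age_group": ["child", "child", "adult", "adult"],
            "status": ["CD", "control", "CD", "control"],
        },
        index=["s1", "s2", "s3", "s4"],
    )


def make_ct(array, samples=None, assays=None) -> CtMatrix:
    arr = np.asarray(array, dtype=float)
    samples = samples or [f"s{i}" for i in range(arr.shape[0])]
    assays = assays or [f"g{j}" for j in range(arr.shape[1])]
    return CtMatrix(pd.DataFrame(arr, index=samples, columns=assays))
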