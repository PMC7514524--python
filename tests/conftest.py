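import numpy as np
import pandas as pd
import pytest

from casmi import CategoricalTable, build_true_joint


@pytest.fixture(scope="session")
def true_model():
    return build_true_joint()


@pytest.fixture
def small_table():
    """Six rows, two informative-ish features and one noise feature."""
    df = pd.DataFrame(
        {
            "f1": ["a", "a", "b", "b", "c", "c"],
            "f2": ["x", "y", "x", "y", "x", "y"],
            "f3": ["u", "u", "u", "v", "v", "v"],
            "y": ["0", "1", "0", "1", "0", "1"],
        }
    )
    return CategoricalTable(df, "y")


def make_table(columns: dict, outcome: str = "y") -> CategoricalTable:
    return CategoricalTable(pd.DataFrame({k: [str(v) for v in vs] for k, vs in columns.items()}), outcome)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
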