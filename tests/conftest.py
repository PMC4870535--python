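import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ticnet import Comparison, TicTable, paperlike_config

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def comp() -> Comparison:
    return Comparison("condA", "condB")


@pytest.fixture(scope="session")
def paperlike_data():
    """One paperlike dataset shared across tests (read-only)."""
    from ticnet import generate_dataset

    config = paperlike_config(seed=7)
    table, truth = generate_dataset(config)
    return config, table, truth


def make_table(values: np.ndarray, states=("condA", "condB")) -> TicTable:
    """Small TicTable from an (n, 4) array: A1, A2, B1, B2."""
    n = values.shape[0]
    cols = [f"{states[0]}_rep1", f"{states[0]}_rep2",
            f"{states[1]}_rep1", f"{states[1]}_rep2"]
    ids = pd.Index([f"P{i:03d}" for i in range(n)], name="protein_id")
    return TicTable(pd.DataFrame(values, index=ids, columns=cols))


@pytest.fixture
def random_table():
    """100-protein fully detected random table."""
    rng = np.random.default_rng(42)
    return make_table(np.exp2(rng.normal(20, 2, size=(100, 4))))
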