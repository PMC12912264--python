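import numpy as np
import pandas as pd
import pytest

from desmokit.io_core import IntensityTable


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_table():
    """3 proteins x (6 bait + 6 ctrl) replicates with varied peptide counts."""
    df = pd.DataFrame({
        "protein_id": ["P1", "P2", "P3"],
        "gene": ["Dsg2", "Jup", "Gapdh"],
        "unique_peptides": [1, 2, 5],
    })
    base = {"P1": 1000.0, "P2": 2000.0, "P3": 500.0}
    for j in range(1, 7):
        df[f"bait_{j}"] = [base[p] * (1 + 0.01 * j) for p in df["protein_id"]]
    for j in range(1, 7):
        df[f"ctrl_{j}"] = [base[p] * 0.5 * (1 + 0.01 * j) for p in df["protein_id"]]
    return IntensityTable(df=df, n_replicates_per_condition=6)
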