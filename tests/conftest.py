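import numpy as np
import pandas as pd
import pytest

from mirglia.spatial import CellTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cells(counts: dict, coords: dict | None = None) -> CellTable:
    """Build a CellTable from {cell_id: {gene: count}} (+ optional coords)."""
    counts_df = pd.DataFrame(counts).T.fillna(0).astype(int)
    counts_df.index.name = "cell_id"
    obs = pd.DataFrame(index=counts_df.index)
    if coords:
        obs["x"] = [coords[c][0] for c in counts_df.index]
        obs["y"] = [coords[c][1] for c in counts_df.index]
    return CellTable(counts_df, obs)


@pytest.fixture
def gene_table():
    """Small classified-ready gene DE table."""
    return pd.DataFrame(
        {
            "feature_id": [f"g{i}" for i in range(6)],
            "feature_kind": "gene",
            "log2fc": [0.70, 0.69, -1.5, 0.2, 2.0, -0.7],
            "fdr": [0.049, 0.001, 0.01, 0.5, 0.001, 0.06],
        }
    )
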