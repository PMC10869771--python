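import numpy as np
import pandas as pd
import pytest

import spatialniche as sn


def make_cells(xy, types):
    """Minimal cell table from positions and type labels."""
    xy = np.asarray(xy, float)
    return pd.DataFrame({
        "cell_id": np.arange(1, len(xy) + 1, dtype=np.int64),
        "x": xy[:, 0], "y": xy[:, 1],
        "type_label": list(types),
    })


@pytest.fixture(scope="session")
def demo_tissue():
    """One deterministic kidney-like synthetic tissue (shared, read-only)."""
    return sn.simulate_tissue(sn.default_config(42), seed=42)


@pytest.fixture(scope="session")
def csr_cells():
    """Two cell types in complete spatial randomness, 500 cells each."""
    return sn.make_csr_fixture(("A", "B"), n_per_type=500, extent=2000.0, seed=7)
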