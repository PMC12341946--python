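import numpy as np
import pandas as pd
import pytest

from memorytc import SimConfig, simulate_counts


@pytest.fixture(scope="session")
def small_sim():
    """300-gene simulation with the default factorial design."""
    cfg = SimConfig(n_genes=300, seed=7)
    counts, design, truth = simulate_counts(cfg)
    return cfg, counts, design, truth


@pytest.fixture()
def toy_counts():
    """Deterministic 10-gene x 4-sample count matrix."""
    rng = np.random.default_rng(123)
    counts = pd.DataFrame(
        rng.integers(0, 500, size=(10, 4)),
        index=[f"g{i}" for i in range(10)],
        columns=list("ABCD"),
    )
    counts.iloc[0] = 0  # an all-zero gene
    return counts
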