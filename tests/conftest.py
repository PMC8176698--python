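import numpy as np
import pytest

from brackish import (
    NeutralSimConfig,
    OtuTable,
    make_source_pool,
    simulate_neutral_series,
)


@pytest.fixture
def tiny_table() -> OtuTable:
    """3 samples x 4 OTUs with varied occupancy and totals."""
    counts = np.array(
        [
            [5, 0, 3, 1],
            [1, 2, 0, 1],
            [0, 7, 0, 1],
        ]
    )
    return OtuTable(("s1", "s2", "s3"), ("o1", "o2", "o3", "o4"), counts)


@pytest.fixture(scope="session")
def neutral_table() -> OtuTable:
    """Medium neutral-assembly table shared across tests (seeded)."""
    pool = make_source_pool(150, 1.2, seed=42)
    cfg = NeutralSimConfig(S=150, N=3000, m=0.15, n_samples=80, seed=43)
    return simulate_neutral_series(pool, cfg)
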