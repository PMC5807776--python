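import numpy as np
import pandas as pd
import pytest

from heiferseq import CountMatrix, SimConfig, simulate_counts


@pytest.fixture
def rng():
    return np.random.default_rng(20231109)


@pytest.fixture
def small_counts(rng):
    """50 genes x 6 samples of overdispersed counts, no planted signal."""
    mu = rng.lognormal(3.0, 1.0, size=50)
    counts = rng.negative_binomial(10, 10 / (10 + mu[:, None]), size=(50, 6))
    return CountMatrix(
        pd.DataFrame(
            counts,
            index=[f"g{i:03d}" for i in range(50)],
            columns=[f"s{j}" for j in range(6)],
        )
    )


@pytest.fixture
def desk_sim():
    """One desk-scale synthetic dataset with planted DE genes."""
    cfg = SimConfig(
        n_genes=400,
        group_sizes=(6, 6),
        library_size_range=(40_000, 80_000),
        n_de_genes=20,
        de_log2fc_range=(1.5, 2.5),
        seed=7,
        group_labels=("AI_PREGNANT", "NOT_PREGNANT"),
        station="B",
    )
    return simulate_counts(cfg)
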