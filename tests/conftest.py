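import numpy as np
import pandas as pd
import pytest

from annobench import SyntheticConfig, average_profiles, generate_dataset


@pytest.fixture(scope="session")
def small_fixture():
    """A quick 300-gene, 4-type synthetic dataset with its cluster profiles."""
    cfg = SyntheticConfig(
        n_genes=300, n_types=4, markers_per_type=10, cells_per_cluster=20, seed=11
    )
    cells, assign, db, profile, gold = generate_dataset(cfg)
    exy = average_profiles(cells, assign)
    return {"cfg": cfg, "cells": cells, "assign": assign, "db": db,
            "profile": profile, "gold": gold, "exy": exy}


@pytest.fixture
def toy_expression():
    """3 genes x 2 columns, strictly positive and asymmetric."""
    return pd.DataFrame(
        [[5.0, 1.0], [2.0, 4.0], [1.0, 3.0]],
        index=["gA", "gB", "gC"], columns=["c1", "c2"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
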