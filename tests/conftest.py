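import numpy as np
import pytest

from mbstats.core import OtuTable, parse_tree
from mbstats.simulate import SimulationConfig, simulate_counts, simulate_tree


@pytest.fixture(scope="session")
def three_leaf_tree():
    return parse_tree("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def small_sim():
    """Small two-tissue cohort used across modules (deterministic)."""
    cfg = SimulationConfig(
        n_otus=80,
        n_subjects=10,
        sample_types=("breast_tissue", "skin_tissue"),
        depth_log_median=8000,
        depth_min=5000,
        depth_max=15000,
        seed=7,
    )
    tree = simulate_tree(cfg.n_otus, seed=cfg.seed)
    table, metadata, taxonomy = simulate_counts(cfg, tree)
    return cfg, tree, table, metadata, taxonomy


@pytest.fixture
def random_table():
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 60, size=(20, 50))
    counts[counts < 10] = 0  # realistic sparsity
    counts[:, 0] += 1  # no zero-depth samples
    return OtuTable(
        counts,
        [f"S{i}" for i in range(20)],
        [f"OTU_{j + 1}" for j in range(50)],
    )
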