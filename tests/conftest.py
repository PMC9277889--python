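import io as _stdio

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from sibmicro import FeatureTable, SimConfig, simulate_cohort


def random_table_and_tree(rng, n_samples=6, n_taxa=8, depth=200):
    """Small random count table + random tree whose tips cover the taxa."""
    from sibmicro.simulate import generate_tree
    taxa = [f"asv_{i + 1:04d}" for i in range(n_taxa)]
    counts = rng.integers(0, depth, size=(n_samples, n_taxa))
    counts[counts < depth // 4] = 0          # sparsity
    counts[:, 0] += 1                        # no empty samples
    table = FeatureTable(pd.DataFrame(
        counts, index=[f"s{i}" for i in range(n_samples)], columns=taxa))
    tree = generate_tree(n_taxa, rng)
    return table, tree


@pytest.fixture(scope="session")
def small_cohort():
    """One modest cohort shared by read-only tests."""
    return simulate_cohort(SimConfig(n_children=120, n_taxa=60, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tree_from_newick(s):
    return TreeNode.read(_stdio.StringIO(s))
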