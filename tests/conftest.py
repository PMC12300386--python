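import io

import numpy as np
import pytest
from skbio import TreeNode

from hydrobiome.io import CountTable, PhyloTree


@pytest.fixture
def worked_tree() -> PhyloTree:
    """The 3-tip worked example: ((A:1,B:1):1,C:2);"""
    return PhyloTree(TreeNode.read(io.StringIO("((A:1,B:1):1,C:2);")))


@pytest.fixture
def small_table() -> CountTable:
    return CountTable(
        ["A", "B", "C"],
        ["s1", "s2"],
        np.array([[5, 0], [1, 2], [0, 7]]),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_count_table(rng, n_taxa=12, n_samples=6, depth=500) -> CountTable:
    p = rng.dirichlet(np.ones(n_taxa))
    counts = np.column_stack(
        [rng.multinomial(depth, rng.dirichlet(p * n_taxa * 2)) for _ in range(n_samples)]
    )
    counts[0, :] += 1  # guarantee non-empty columns
    return CountTable(
        [f"t{i}" for i in range(n_taxa)],
        [f"s{j}" for j in range(n_samples)],
        counts,
    )
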