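import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from consentree import FixtureSpec, make_pvalues, make_tree, parse_tree


@pytest.fixture
def three_tip_tree():
    return parse_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def random_trees():
    """A batch of small random binary trees with varied length styles."""
    trees = []
    for seed in range(50):
        spec = FixtureSpec(
            n_tips=3 + seed % 12,
            topology="random",
            lengths=("unit", "exponential", "none")[seed % 3],
            seed=seed,
        )
        trees.append((spec, make_tree(spec)))
    return trees


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tree_with_pvalues():
    spec = FixtureSpec(n_tips=12, topology="random", lengths="exponential",
                       pvalues="uniform", seed=7)
    tree = make_tree(spec)
    return tree, make_pvalues(tree, spec)
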