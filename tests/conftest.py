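import numpy as np
import pytest

from phylohaar import EnsembleConfig, load_newick, sample_tree

#: balanced 4-leaf tree with unit edges everywhere, including the planted edge
FIG_NEWICK = "((A:1,B:1):1,(C:1,D:1):1):1;"


@pytest.fixture
def balanced4():
    return load_newick(FIG_NEWICK)


@pytest.fixture
def caterpillar3():
    """3-leaf caterpillar, unit lengths including the planted edge."""
    return load_newick("(A:1,(B:1,C:1):1):1;")


@pytest.fixture
def caterpillar4():
    return load_newick("(A:1,(B:1,(C:1,D:1):1):1):1;")


def random_trees(count, n_max=64, seed=0):
    """Seeded stream of random trees across both ensembles and length rules."""
    rng = np.random.default_rng(seed)
    for k in range(count):
        n = int(rng.integers(2, n_max + 1))
        law = "critical_beta" if k % 2 == 0 else "uniform"
        rule = "unit" if k % 4 < 2 else "exponential"
        yield sample_tree(EnsembleConfig(n=n, law=law, edge_lengths=rule), rng=rng)
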