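import numpy as np
import pytest
from hypothesis import settings

from fishcnv import synthetic_data as sd

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """One complete synthetic study at reduced scale (fast, session-cached)."""
    cfg = sd.SimConfig(seed=11, n_taxa=25, n_tsg=40, n_og=40)
    return sd.simulate_study(cfg)


@pytest.fixture(scope="session")
def default_study():
    """Full-scale study at the generator's default conditions."""
    cfg = sd.SimConfig(seed=7)
    return sd.simulate_study(cfg, with_gene_trees=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_trees(n_trees, n_taxa_range=(3, 8), seed=0):
    """Seeded stream of random ultrametric trees for property tests."""
    trees = []
    for i in range(n_trees):
        lo, hi = n_taxa_range
        n = lo + (i % (hi - lo + 1))
        cfg = sd.SimConfig(seed=seed * 10000 + i, n_taxa=max(n, 3))
        trees.append(sd.simulate_yule_tree(cfg))
    return trees
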