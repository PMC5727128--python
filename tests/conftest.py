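import numpy as np
import pytest

from phyloallometry import (PhyloTree, SimulationConfig, fit_pgls,
                            simulate_allometric_traits, simulate_tree)


@pytest.fixture
def three_tip_tree():
    return PhyloTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree_newick():
    tips = ",".join(f"t{i}:1" for i in range(12))
    return f"({tips});"


@pytest.fixture(scope="session")
def sim_tree20():
    return simulate_tree(SimulationConfig(seed=3, n_tips=20))


@pytest.fixture(scope="session")
def sim_dataset20(sim_tree20):
    cfg = SimulationConfig(seed=3, n_tips=20)
    traits = simulate_allometric_traits(sim_tree20, cfg)
    return cfg, sim_tree20, traits


@pytest.fixture(scope="session")
def fitted20(sim_dataset20):
    cfg, tree, traits = sim_dataset20
    return fit_pgls(tree, traits, cfg.response_name, cfg.predictor_name,
                    lam="ML")


def ols_slope_intercept(x, y):
    """Plain least-squares line, the reference for star-tree/λ=0 checks."""
    X = np.column_stack([np.ones_like(x), x])
    b, *_ = np.linalg.lstsq(X, y, rcond=None)
    return b[1], b[0]
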