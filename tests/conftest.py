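import numpy as np
import pytest

import peakshift as pk


@pytest.fixture(scope="session")
def three_tip_tree():
    return pk.read_newick("((A:1,B:1):1,C:2):0;")


@pytest.fixture(scope="session")
def scenario():
    """Study-scale synthetic bundle shared by the slower integration tests."""
    return pk.phyllostomid_like_fixture(42)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def painted_tree(seed, n_tips=128, depth=30.0, n_regimes=5, switch_rate=0.03):
    """A simulated tree whose regime history expresses every regime at the
    tips (resampled deterministically from the seed until it does)."""
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(50):
        s1, s2 = child.spawn(2)
        tree = pk.simulate_tree(n_tips, depth, s1)
        paint = pk.simulate_regime_history(tree, n_regimes, switch_rate, s2)
        if len(set(paint.node_regime[:n_tips].tolist())) == n_regimes:
            return tree, paint
    raise RuntimeError("no regime history expressed all regimes")
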