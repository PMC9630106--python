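import numpy as np
import pytest

import stemtrace as st


@pytest.fixture(scope="session")
def tree8():
    """8-tip dated tree used across modules."""
    return st.simulate_dated_tree(8, 0.02, 0.0, seed=3)


@pytest.fixture(scope="session")
def tree10():
    return st.simulate_dated_tree(10, 0.02, 0.0, seed=11)


@pytest.fixture(scope="session")
def small_dataset(tree10):
    """60 families under shared DTL rates on the 10-tip tree."""
    cfg = st.SimulationConfig(n_tips=10, n_families=60,
                              dtl_rates=(0.002, 0.001, 0.004), seed=5)
    return st.simulate_dataset(tree10, cfg)


@pytest.fixture(scope="session")
def congruent_family(tree8):
    """Single-copy family with no events, origin at the root."""
    fam = st.simulate_family(tree8, (0.0, 0.0, 0.0),
                             origination_policy="root", seed=1)
    return fam


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
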