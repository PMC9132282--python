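import numpy as np
import pytest

from kinassign import experiments as ex
from kinassign import synthetic as syn


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def default_study():
    """Desk-scale default assay with fitted models (shared, read-only)."""
    return ex.build_study(seed=11)


@pytest.fixture(scope="session")
def small_kinome():
    return syn.generate_kinome(n_kinases=8, motif_sharpness=0.9,
                               family_fraction=0.5, seed=5)


@pytest.fixture(scope="session")
def small_assay(small_kinome):
    return syn.simulate_assay(small_kinome, pool_size=600, seed=6)


@pytest.fixture(scope="session")
def holdout_signal():
    """Held-out in vivo comparison with informative association signal."""
    return ex.holdout_invivo_comparison(seed=1, signal_strength=1.0)


@pytest.fixture(scope="session")
def holdout_nosignal():
    """Held-out in vivo comparison with truth-independent association scores."""
    return ex.holdout_invivo_comparison(seed=1, signal_strength=0.0)
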