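import numpy as np
import pytest

from holodsn.experiments import mini_dsn_cotraining, toy_optics
from holodsn.optics import full_scale_config


@pytest.fixture(scope="session")
def full_cfg():
    return full_scale_config()


@pytest.fixture(scope="session")
def toy_cfg():
    """32 x 32 x 10-coarse-voxel geometry used by the desk-scale experiments."""
    return toy_optics()


@pytest.fixture(scope="session")
def cotraining_result():
    """One full pretrain + co-train run of the miniature mixture network.

    Expensive (about a minute and a half on one CPU); shared by the training
    and acceptance tests.
    """
    return mini_dsn_cotraining(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
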