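import numpy as np
import pytest

from scfc import generate_atlas, generate_ground_truth_sc
from scfc.pipeline import ExperimentConfig, SyntheticStudy


@pytest.fixture(scope="session")
def atlas16():
    return generate_atlas(16)


@pytest.fixture(scope="session")
def atlas40():
    return generate_atlas(40)


@pytest.fixture(scope="session")
def gt16(atlas16):
    return generate_ground_truth_sc(atlas16, seed=3)


@pytest.fixture(scope="session")
def demo_config():
    """Desk-scale study configuration shared by the end-to-end tests."""
    return ExperimentConfig(seed=1)


@pytest.fixture(scope="session")
def demo_study(demo_config):
    """Shared synthetic study; simulations are generated once per session."""
    return SyntheticStudy(demo_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
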