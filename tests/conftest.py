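import numpy as np
import pytest

from drumtl.networks import BackboneConfig
from drumtl.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_backbone_config():
    """3-level 16x16 configuration: fast enough for gradient checks."""
    return BackboneConfig(levels=3, base_channels=4, side=16, dtype="float64")


@pytest.fixture(scope="session")
def small_dataset():
    """Small synthetic triple (pretrain, multitask, test) at 32x32."""
    cfg = SyntheticConfig(
        side=32, n_per_stage=3, n_per_stage_pretrain=2, n_per_stage_test=2, seed=7
    )
    return generate_dataset(cfg)
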