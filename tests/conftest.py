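import numpy as np
import pytest

from clclsa import synthetic
from clclsa.training import Architecture, TrainConfig


@pytest.fixture(scope="session")
def default_ds():
    """The default synthetic benchmark (N=400, M=3, C=3)."""
    return synthetic.generate(synthetic.SimConfig())


@pytest.fixture(scope="session")
def tiny_ds():
    """A small dataset for fast training-path tests."""
    return synthetic.generate(
        synthetic.SimConfig(
            n_subjects=60, n_views=3, n_classes=2, view_dims=(12, 10, 8),
            latent_dim=3, seed=7,
        )
    )


@pytest.fixture()
def tiny_cfg():
    """Fast desk-scale training settings matched to the tiny dataset."""
    return TrainConfig.desk_scale(epochs=30, latent_dim=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
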