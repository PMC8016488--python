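import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_deepnog():
    """A small untrained embedding-network state for fast forward passes."""
    from ognet import architecture

    cfg = architecture.ModelConfig(
        variant="deepnog", n_groups=4, embedding_dim=6,
        filter_sizes=(4, 8, 12), filters_per_size=5, dropout_p=0.3,
    )
    return architecture.build_deepnog(cfg, seed=7)


@pytest.fixture
def tiny_deepfam():
    from ognet import architecture

    cfg = architecture.ModelConfig(
        variant="deepfam", n_groups=4, filter_sizes=(4, 8), filters_per_size=5,
        dropout_p=0.3, hidden_units=9, fixed_length=60,
    )
    return architecture.build_deepfam(cfg, seed=7)
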