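import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from elmseizure import (  # noqa: E402
    ELMConfig,
    SynthConfig,
    fit,
    generate_bonn_like,
    init_hidden,
    relabel_binary,
)


@pytest.fixture(scope="session")
def small_synth():
    """A scaled-down five-class table: 5 classes x 8 subjects x 23 chunks."""
    return generate_bonn_like(SynthConfig(n_subjects_per_class=8, seed=42))


@pytest.fixture(scope="session")
def small_binary(small_synth):
    return relabel_binary(small_synth)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def tiny_trained_model(rng):
    """A binary ELM fit on an easy 2-D problem (for state-dependent APIs)."""
    X = rng.normal(size=(40, 2))
    y = (X[:, 0] > 0).astype(int)
    model = init_hidden(ELMConfig(n_hidden=12, seed=3), 2)
    return fit(model, X, y), X, y
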