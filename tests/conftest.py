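import numpy as np
import pytest

from gliopipe import PhantomSpec, TumorSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic 64x64 GBM phantom shared across tests."""
    return generate_phantom(PhantomSpec(image_side=64, seed=7))


@pytest.fixture(scope="session")
def phantom_per_class():
    """One 64x64 phantom of each tumor class, deterministic."""
    out = {}
    for i, label in enumerate(("AST", "OLI", "GBM")):
        spec = PhantomSpec(
            image_side=64, seed=100 + i,
            tumor=TumorSpec(present=True, label=label),
        )
        out[label] = generate_phantom(spec)
    return out
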