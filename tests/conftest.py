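import numpy as np
import pytest

from hybridseg import build_model, generate_case, tiny_model_config, tiny_spec
from hybridseg.train import _collect_slices


@pytest.fixture(scope="session")
def tiny_cases():
    """Two deterministic 64x64x4 phantom volumes (K=3)."""
    return [generate_case(tiny_spec(seed=s)) for s in range(2)]


@pytest.fixture(scope="session")
def tiny_slices(tiny_cases):
    images, labels = _collect_slices(tiny_cases, 64)
    return images, labels


@pytest.fixture(scope="session")
def tiny_model():
    """A freshly initialised reduced-scale network (do not mutate weights)."""
    return build_model(tiny_model_config(), seed=0).eval()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
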