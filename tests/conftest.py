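import numpy as np
import pytest

from spinocc import SpinGlassModel, SyntheticSpec, make_ground_truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_model():
    """A fixed, well-conditioned 4-node model for sampler/enumeration tests."""
    spec = SyntheticSpec(n_nodes=4, seed=42)
    return make_ground_truth(spec)


@pytest.fixture
def two_node_model():
    return SpinGlassModel.from_upper(h=np.array([0.5, 0.5]), J_upper=np.array([1.0]))
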