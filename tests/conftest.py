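import numpy as np
import pytest

from dentoface.phantom import default_truth, generate_phantom, random_rigid_transform


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_case():
    """Normal-anatomy phantom in the identity pose."""
    return generate_phantom(default_truth())


@pytest.fixture
def posed_case(rng):
    """Normal-anatomy phantom under a random rigid pose."""
    truth = default_truth(pose=random_rigid_transform(rng))
    return generate_phantom(truth)
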