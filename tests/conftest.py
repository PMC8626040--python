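import numpy as np
import pytest

from imugait.kinematics import ChainModel


@pytest.fixture(scope="session")
def model2():
    return ChainModel.default("2dof")


@pytest.fixture(scope="session")
def model1():
    return ChainModel.default("1dof")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def random_quats():
    """1000 seeded uniform-ish unit quaternions."""
    r = np.random.default_rng(42)
    q = r.standard_normal((1000, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)
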