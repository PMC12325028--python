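import numpy as np
import pytest

from umhl import FCMatrix, SimSpec, make_dataset


def random_fc(rng: np.random.Generator, n: int) -> FCMatrix:
    """Random symmetric matrix in [-1, 1] with unit diagonal."""
    a = rng.uniform(-1.0, 1.0, size=(n, n))
    f = (a + a.T) / 2.0
    np.fill_diagonal(f, 1.0)
    return FCMatrix(values=f)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small separable cohort shared by the training-level tests."""
    spec = SimSpec(
        n_rois=40,
        n_subnets=4,
        n_per_class=12,
        effect_size=0.35,
        n_affected=1,
        t_points=120,
        seed=7,
    )
    return make_dataset(spec)
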