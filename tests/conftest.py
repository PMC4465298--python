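import numpy as np
import pytest

from degps import CountMatrix, GroupDesign


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_counts():
    """Small deterministic 6-transcript x 4-sample matrix."""
    values = np.array(
        [
            [10, 12, 30, 28],
            [5, 7, 6, 4],
            [0, 0, 0, 0],
            [100, 90, 110, 95],
            [1, 0, 2, 1],
            [0, 3, 0, 5],
        ]
    )
    return CountMatrix(values, [f"t{i}" for i in range(6)], ["s1", "s2", "s3", "s4"])


@pytest.fixture
def toy_design():
    return GroupDesign(("s1", "s2"), ("s3", "s4"))


@pytest.fixture
def nb_matrix(rng):
    """Moderate overdispersed 200 x 6 matrix for normalization tests."""
    mu = 10.0 ** rng.normal(1.5, 0.8, size=200)
    phi = rng.uniform(0.1, 0.4, size=200)
    lam = rng.gamma(1.0 / phi[:, None], (mu * phi)[:, None] * np.ones((1, 6)))
    vals = rng.poisson(lam)
    vals[0] = [3, 4, 5, 3, 4, 5]  # guarantee at least one modest row
    return CountMatrix(vals, [f"g{i}" for i in range(200)], [f"s{j}" for j in range(6)])
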