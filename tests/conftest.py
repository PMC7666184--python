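import numpy as np
import pytest

from rarepart import CommunityMatrix, EnvMatrix, SiteCoordinates


@pytest.fixture
def small_community():
    rng = np.random.default_rng(42)
    values = rng.poisson(3.0, size=(10, 6)).astype(float)
    values[:, 0] += 1  # keep every site occupied
    return CommunityMatrix(
        [f"s{i}" for i in range(10)], [f"sp{j}" for j in range(6)], values
    )


@pytest.fixture
def small_env(small_community):
    rng = np.random.default_rng(7)
    values = rng.normal(10, 6, size=(10, 4))
    return EnvMatrix(list(small_community.site_ids), [f"e{j}" for j in range(4)], values)


@pytest.fixture
def small_coords(small_community):
    rng = np.random.default_rng(11)
    pts = rng.uniform(0, 5, size=(10, 2))
    return SiteCoordinates(list(small_community.site_ids), pts[:, 0], pts[:, 1])


@pytest.fixture
def vegan_fixture():
    """12x5 community with 2+2 predictors; expected values frozen from
    vegan::varpart 2.7-1 (hellinger-transformed response)."""
    rng = np.random.default_rng(20240917)
    Y = rng.poisson(4.0, size=(12, 5)).astype(float)
    Y[0] += 3
    X = rng.normal(size=(12, 2))
    W = rng.normal(size=(12, 2))
    return Y, X, W
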