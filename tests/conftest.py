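import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from barcodeaudit.k2p import DistanceMatrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20110214)


def make_matrix(species: list[str], d: np.ndarray, ids=None) -> DistanceMatrix:
    """Build a DistanceMatrix directly from a distance array (tests only)."""
    n = len(species)
    ids = tuple(ids) if ids else tuple(f"s{i}" for i in range(n))
    return DistanceMatrix(
        ids=ids,
        species=tuple(species),
        d=np.asarray(d, dtype=float).copy(),
        overlap=np.full((n, n), 658, dtype=np.int64),
    )


@pytest.fixture
def matrix_builder():
    return make_matrix
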