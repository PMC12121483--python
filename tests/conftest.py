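import numpy as np
import pytest

from appcluster import build_smoothed_histogram, normalize_projection
from appcluster import synthetic_data as syn


@pytest.fixture(scope="session")
def four_blob_data():
    """Four unit-variance 3D blobs, 10 sigma apart, n=2000."""
    return syn.make_blobs(syn.four_blob_spec(n_total=2000, separation=10.0, seed=1))


@pytest.fixture(scope="session")
def two_blob_vertical():
    """Two blobs separated only along the second axis (clear y-valley)."""
    spec = syn.MixtureSpec(
        components=(
            syn.Component((0.0, 0.0), (1.0, 1.0), 0.5),
            syn.Component((0.0, 12.0), (1.0, 1.0), 0.5),
        ),
        n_total=400,
        seed=5,
    )
    return syn.make_blobs(spec)


def grid_from_points(X, N=20, sigma=1.0, dims=(0, 1)):
    proj = normalize_projection(np.asarray(X, dtype=float), *dims)
    return proj, build_smoothed_histogram(proj, N, sigma)
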