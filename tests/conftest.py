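import numpy as np
import pytest

from glimap import generate_cells, generate_tissue


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_truth():
    """Moderate synthetic dataset: 36 positions, 12 landmarks, 300 cells."""
    ref = generate_tissue(K=36, n_landmarks=12, pattern_family="mixed", seed=3)
    return generate_cells(ref, N=300, n_nonlandmark=15, seed=4)


@pytest.fixture(scope="session")
def noisefree_truth():
    """Noise-free dataset: every cell sits exactly on a mapped position."""
    ref = generate_tissue(K=25, n_landmarks=10, pattern_family="mixed", seed=7)
    return generate_cells(ref, N=250, true_c=0.0, seed=8)
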