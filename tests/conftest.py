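import numpy as np
import pytest

from smmtransfer import Hyperparams, MatrixDataset, SyntheticTaskSpec, make_transfer_task


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_separable_dataset(seed: int, n: int = 30, p: int = 4, q: int = 4,
                             margin: float = 0.1) -> tuple[MatrixDataset, np.ndarray]:
    """Gaussian trials labeled by a random planted linear matrix classifier."""
    g = np.random.default_rng(seed)
    W = g.standard_normal((p, q))
    W /= np.linalg.norm(W, "fro")
    X = g.standard_normal((n, p, q))
    d = np.einsum("jk,ijk->i", W, X)
    keep = np.abs(d) >= margin
    while keep.sum() < n:
        extra = g.standard_normal((n, p, q))
        X = np.concatenate([X[keep], extra])
        d = np.einsum("jk,ijk->i", W, X)
        keep = np.abs(d) >= margin
    X, d = X[keep][:n], d[keep][:n]
    y = np.sign(d)
    if np.unique(y).size < 2:  # pragma: no cover - vanishing probability
        y[0] = -y[0]
    return MatrixDataset.from_arrays(X, y), W


@pytest.fixture(scope="session")
def small_task():
    """One shared default-spec transfer task (source fit included)."""
    return make_transfer_task(SyntheticTaskSpec(seed=7), n_labeled=8)


@pytest.fixture(scope="session")
def default_hyper():
    return Hyperparams(C=1.0, tau=0.1)
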