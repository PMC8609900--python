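import numpy as np
import pytest

from deepida.datasets import MultiViewDataset, validate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """Two views, three classes, mild planted mean separation."""
    n_k = (12, 12, 12)
    labels = np.repeat([1, 2, 3], n_k)
    means = {1: 1.0, 2: -1.0, 3: 0.0}
    views = []
    for p in (6, 4):
        X = rng.standard_normal((sum(n_k), p))
        X[:, 0] += np.vectorize(means.get)(labels)
        views.append(X)
    return validate_dataset(MultiViewDataset(views=views, labels=labels))


@pytest.fixture
def unbalanced_dataset(rng):
    labels = np.repeat([1, 2], [9, 3])
    views = [rng.standard_normal((12, 5)), rng.standard_normal((12, 3))]
    return validate_dataset(MultiViewDataset(views=views, labels=labels))


def random_psd(rng, o, scale=1.0):
    A = rng.standard_normal((o, o + 2))
    M = A @ A.T / (o + 2)
    return scale * M / np.linalg.eigvalsh(M).max()


def random_instance(rng, D=2, o=2, cap=0.95):
    """Random whitened-scatter instance with association singular values < 1."""
    Ms = [random_psd(rng, o) for _ in range(D)]
    Ns = {}
    for d in range(D):
        for j in range(d + 1, D):
            B = rng.standard_normal((o, o))
            U, s, Vt = np.linalg.svd(B)
            Ns[(d, j)] = (U * np.clip(s, 0, cap) / max(s.max(), 1e-12)) @ Vt * rng.uniform(0.3, 1)
    return Ms, Ns
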