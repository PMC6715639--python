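"""Shared fixtures: small random multilevel networks and model helpers."""

import numpy as np
import pandas as pd
import pytest

from mergm.netdata import MultilevelNetwork


def make_random_mnet(
    rng: np.random.Generator,
    n_a: int = 6,
    n_b: int = 5,
    p: float = 0.3,
    with_attributes: bool = True,
) -> MultilevelNetwork:
    """A random three-layer network with optional categorical attributes."""
    A = (rng.random((n_a, n_a)) < p).astype(np.int8)
    np.fill_diagonal(A, 0)
    B = (rng.random((n_b, n_b)) < p).astype(np.int8)
    np.fill_diagonal(B, 0)
    X = (rng.random((n_a, n_b)) < p).astype(np.int8)
    Y = None
    if with_attributes:
        Y = pd.DataFrame({
            "id": [f"m{i}" for i in range(n_a)],
            "education": rng.choice(
                ["bachelor's degree", "master's degree", ""], size=n_a
            ),
            "organisation": rng.choice(["other", "education"], size=n_a),
        })
    return MultilevelNetwork(
        tuple(f"m{i}" for i in range(n_a)),
        tuple(f"v{i}" for i in range(n_b)),
        A, B, X, Y,
    )


def actors_only_net(n: int) -> MultilevelNetwork:
    """An empty network of n actors and one untouched CLD variable, for
    models that only concern the collaboration layer."""
    return MultilevelNetwork(
        tuple(f"m{i}" for i in range(n)), ("v0",),
        np.zeros((n, n), dtype=np.int8),
        np.zeros((1, 1), dtype=np.int8),
        np.zeros((n, 1), dtype=np.int8),
    )


def net_from_edges(n_a, n_b, a_edges=(), b_edges=(), x_edges=(), Y=None) -> MultilevelNetwork:
    A = np.zeros((n_a, n_a), dtype=np.int8)
    B = np.zeros((n_b, n_b), dtype=np.int8)
    X = np.zeros((n_a, n_b), dtype=np.int8)
    for i, j in a_edges:
        A[i, j] = 1
    for u, v in b_edges:
        B[u, v] = 1
    for i, v in x_edges:
        X[i, v] = 1
    return MultilevelNetwork(
        tuple(f"m{i}" for i in range(n_a)),
        tuple(f"v{i}" for i in range(n_b)),
        A, B, X, Y,
    )


def batch_means_se(samples: np.ndarray, n_batches: int = 40) -> np.ndarray:
    """Monte-Carlo standard error of a chain mean, robust to autocorrelation."""
    n = samples.shape[0] // n_batches * n_batches
    chunks = samples[:n].reshape(n_batches, -1, *samples.shape[1:])
    means = chunks.mean(axis=1)
    return means.std(axis=0, ddof=1) / np.sqrt(n_batches)


@pytest.fixture
def rng():
    return np.random.default_rng(20250920)
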