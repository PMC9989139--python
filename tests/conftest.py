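"""Shared fixtures and simulation helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from threatnet.synthdata import ar2_coefficients

FS = 250.0
THETA_A1, THETA_A2 = ar2_coefficients(6.0, 0.95, FS)


def bivariate_coupled(
    n_trials: int, n_samples: int, coef: float, seed: int,
    step_at: int | None = None,
) -> np.ndarray:
    """Trials x 2 x samples: two theta oscillators with x -> y lag-1 coupling.

    With ``step_at`` the coupling is 0 before that sample and ``coef`` after.
    """
    rng = np.random.default_rng(seed)
    burn = 200
    total = n_samples + burn
    x = np.zeros((n_trials, 2, total))
    w = rng.normal(size=(n_trials, 2, total))
    for t in range(2, total):
        c = coef
        if step_at is not None:
            c = coef if (t - burn) >= step_at else 0.0
        x[:, 0, t] = THETA_A1 * x[:, 0, t - 1] + THETA_A2 * x[:, 0, t - 2] + w[:, 0, t]
        x[:, 1, t] = (
            THETA_A1 * x[:, 1, t - 1]
            + THETA_A2 * x[:, 1, t - 2]
            + c * x[:, 0, t - 1]
            + w[:, 1, t]
        )
    return x[:, :, burn:]


def planted_block_graph(
    rng: np.random.Generator, n: int = 60, k: int = 6,
    p_in: float = 0.6, p_out: float = 0.05,
    labels: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary planted-partition graph and its block labels."""
    if labels is None:
        labels = np.repeat(np.arange(k), n // k)
    n = labels.size
    A = np.zeros((n, n))
    iu, ju = np.triu_indices(n, 1)
    p = np.where(labels[iu] == labels[ju], p_in, p_out)
    edge = rng.random(iu.size) < p
    A[iu[edge], ju[edge]] = 1
    A[ju[edge], iu[edge]] = 1
    return A, labels


def adjusted_rand(a: np.ndarray, b: np.ndarray) -> float:
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(a, b))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def two_triangles() -> np.ndarray:
    A = np.zeros((6, 6))
    for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        A[i, j] = A[j, i] = 1
    return A
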