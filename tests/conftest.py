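"""Shared fixtures and the dense-matrix oracle.

The oracle builds every sensing matrix ``H_ij = Re{conj(u) u^T}`` with
``u = w_j * f_i`` (f_i the rows of the explicit DFT matrix) so that all
matrix-free FFT operators can be checked against dense linear algebra at
small N.
"""

import numpy as np
import pytest
import scipy.linalg

from splitfuse import MaskSet, sample_masks


def dense_H(masks: MaskSet) -> np.ndarray:
    """All sensing matrices as an (N, K, N, N) array: dense_H[i, j] = H_ij."""
    N, K = masks.N, masks.K
    F = scipy.linalg.dft(N)
    flat = masks.masks.reshape(K, N)
    H = np.empty((N, K, N, N))
    for j in range(K):
        for i in range(N):
            u = flat[j] * F[i]
            H[i, j] = np.real(np.outer(np.conj(u), u))
    return H


def dense_sensing_matrix(anchor: np.ndarray, masks: MaskSet) -> np.ndarray:
    """The KN x N matrix whose row (i + N(j-1)) is anchor^T H_ij."""
    H = dense_H(masks)
    a = np.asarray(anchor, dtype=np.float64).ravel()
    rows = [a @ H[i, j] for j in range(masks.K) for i in range(masks.N)]
    return np.asarray(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_masks():
    """N=8, K=3 quaternary mask set, fixed seed."""
    return sample_masks(8, 3, seed=42)


@pytest.fixture
def small_signal(rng):
    return rng.uniform(0.1, 1.0, size=8)
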