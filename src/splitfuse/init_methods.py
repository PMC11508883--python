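"""Initialization strategies for CDP phase retrieval.

Two families:

* a positive random initialization — i.i.d. uniform(0,1) entries rescaled
  to the Parseval energy estimate ``||x||^2 ≈ sum(Y) / (N K)``.  It carries
  no directional information but has the right energy and, crucially for
  nonnegative signals, the right orthant;
* spectral initializations — the leading eigenvector of a data-weighted
  backprojection operator ``v -> sum_ij w_ij y_ij H_ij v``, with the
  weighting of Wirtinger flow (none), truncated Wirtinger flow (discard
  large intensities), or truncated amplitude flow (keep only the largest
  normalized correlations, which promotes orthogonality to the discarded
  rows).  The eigenvector is extracted by matrix-free Lanczos iteration:
  the TAF operator's spectrum is tightly clustered under CDP masks (its
  bulk is pinned by the exact identity ``sum_i H_ij = N I``), where plain
  power iteration cannot separate the leading direction in any practical
  iteration count.

Every initializer is scaled to the same Parseval energy estimate, so for
noise-free data its norm matches ``||x||`` up to rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import BilinearOperator, MaskSet

__all__ = [
    "SpectralInitConfig",
    "energy_estimate",
    "random_positive_init",
    "spectral_init",
]


@dataclass
class SpectralInitConfig:
    """Knobs of the spectral initializers.

    power_iters : eigensolver iteration budget (Lanczos restarts).
    truncation_alpha : TWF's alpha_y — intensities above
        ``alpha_y^2 * lambda^2`` are discarded (lambda^2 the energy
        estimate).
    taf_keep_fraction : fraction of rows with the largest intensities kept
        by TAF's orthogonality-promoting rule (its authors keep 5/6).
    """

    power_iters: int = 50
    truncation_alpha: float = 3.0
    taf_keep_fraction: float = 5.0 / 6.0

    def __post_init__(self) -> None:
        if self.power_iters < 1:
            raise ValueError("power_iters must be >= 1")
        if not self.truncation_alpha > 0:
            raise ValueError("truncation_alpha must be positive")
        if not 0 < self.taf_keep_fraction <= 1:
            raise ValueError("taf_keep_fraction must lie in (0, 1]")


def energy_estimate(Y: np.ndarray, N: int, K: int) -> float:
    """Parseval estimate of ``||x||``: sqrt(sum(Y) / (N K)).

    Exact for noise-free observations since each mask's intensity column
    sums to ``N ||x||^2`` under the unnormalized DFT.
    """
    total = float(np.sum(Y))
    if not total > 0:
        raise ValueError("observations carry no energy")
    return float(np.sqrt(total / (N * K)))


def random_positive_init(
    Y: np.ndarray, masks: MaskSet, seed: int | None = None
) -> np.ndarray:
    """Positive random initialization with Parseval energy calibration.

    Entries are i.i.d. uniform(0,1), then the vector is rescaled so its
    squared norm equals the energy estimate.  All entries stay strictly
    positive.
    """
    lam = energy_estimate(Y, masks.N, masks.K)
    rng = np.random.default_rng(seed)
    v = rng.uniform(size=masks.shape)
    v[v == 0] = np.finfo(float).tiny  # uniform draws in [0,1); keep > 0
    return v * (lam / np.linalg.norm(v))


def _spectral_weights(
    method: str, Y: np.ndarray, lam: float, config: SpectralInitConfig
) -> np.ndarray:
    if method == "wf":
        return Y.copy()
    if method == "twf":
        return Y * (Y <= (config.truncation_alpha * lam) ** 2)
    if method == "taf":
        # Orthogonality-promoting rule: unit weight on the keep-fraction of
        # rows with the largest intensities (row norms are constant for CDP,
        # so intensity order equals normalized-correlation order); the
        # eigenvector is then maximally aligned with the kept rows and
        # near-orthogonal to the discarded, weakly correlated ones.
        k = max(1, int(np.ceil(config.taf_keep_fraction * Y.size)))
        cutoff = np.partition(Y.ravel(), Y.size - k)[Y.size - k]
        return (Y >= cutoff).astype(np.float64)
    raise ValueError(f"unknown spectral method {method!r}")


def spectral_init(
    method: str,
    Y: np.ndarray,
    masks: MaskSet,
    config: SpectralInitConfig | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Leading eigenvector of the weighted backprojection operator.

    Lanczos iteration on ``v -> sum_ij w_ij H_ij v`` with the
    method-specific weights w (see :class:`SpectralInitConfig`), started
    from a seeded Gaussian vector and scaled to the Parseval energy
    estimate.  The operator is applied matrix-free via the cached-spectra
    adjoint and is real-symmetric because every H_ij is real.  If the
    Krylov solve does not reach full accuracy (TAF's clustered spectrum at
    small K), the best available Ritz vector is used — matching the
    regime where that initializer is genuinely uninformative.
    """
    import scipy.sparse.linalg as spla

    config = config or SpectralInitConfig()
    lam = energy_estimate(Y, masks.N, masks.K)
    W = _spectral_weights(method, np.asarray(Y, dtype=np.float64), lam, config)
    N, shape = masks.N, masks.shape

    def matvec(v):
        op = BilinearOperator(v.reshape(shape), masks)
        return op.adjoint(W).ravel()

    A = spla.LinearOperator((N, N), matvec=matvec, dtype=np.float64)
    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal(N)
    ncv = min(N, 64)
    try:
        _, vecs = spla.eigsh(
            A, k=1, which="LA", v0=v0, ncv=ncv,
            maxiter=10 * config.power_iters, tol=1e-8,
        )
        v = vecs[:, 0]
    except spla.ArpackNoConvergence as exc:
        if exc.eigenvectors is not None and exc.eigenvectors.size:
            v = exc.eigenvectors[:, 0]
        else:  # fully degenerate leading subspace: fall back to the start
            v = v0
    nv = np.linalg.norm(v)
    if not (np.isfinite(nv) and nv > 0):
        raise FloatingPointError("eigensolver produced a degenerate vector")
    return (v / nv).reshape(shape) * lam
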