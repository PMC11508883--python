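"""Coded-diffraction-pattern (CDP) forward model.

A real signal ``x`` (1-D vector or 2-D grayscale image) is modulated
elementwise by K random unimodular masks ``W_j`` and the squared magnitude
of the unnormalized DFT of each masked copy is recorded::

    y_ij = |DFT(W_j * x)_i|^2 + eta_ij,   i = 1..N,  j = 1..K.

Everything here is matrix-free: the bilinear sensing operator ``H_a`` whose
rows are ``a^T H_ij`` (with ``H_ij = Re{W_j^* conj(f_i) f_i^T W_j}`` and
``f_i`` the DFT rows) is applied via batched FFTs in O(K N log N), never
materialized.  Dense constructions exist only in the test suite as oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft

__all__ = [
    "MaskSet",
    "BilinearOperator",
    "sample_masks",
    "forward_intensity",
    "bilinear_intensity",
    "apply_adjoint",
    "add_awgn",
    "ALPHABETS",
]

#: Mask alphabets.  "quaternary" is the standard CDP phase-mask dictionary;
#: the two-element variants are allowed as config options.
ALPHABETS = {
    "quaternary": np.array([1, -1, 1j, -1j], dtype=np.complex128),
    "binary": np.array([1, -1], dtype=np.complex128),
    "imaginary": np.array([1j, -1j], dtype=np.complex128),
}


def _fftn(arr: np.ndarray) -> np.ndarray:
    """Unnormalized DFT over the signal axes of a (K, *shape) batch."""
    axes = tuple(range(1, arr.ndim))
    return scipy.fft.fftn(arr, axes=axes)


def _ifftn_unnorm(arr: np.ndarray) -> np.ndarray:
    """N * ifft over the signal axes, i.e. the adjoint F^H of the DFT."""
    axes = tuple(range(1, arr.ndim))
    n = np.prod([arr.shape[a] for a in axes])
    return scipy.fft.ifftn(arr, axes=axes) * n


@dataclass
class MaskSet:
    """K diagonal CDP masks with entries in a unimodular alphabet.

    Parameters
    ----------
    masks : complex ndarray, shape (K, *signal_shape)
        Diagonal entries of each mask, laid out like the signal (1-D or 2-D).
    seed : int or None
        RNG seed the masks were drawn with (metadata only).
    alphabet : str
        Key into :data:`ALPHABETS`.
    """

    masks: np.ndarray
    seed: int | None = None
    alphabet: str = "quaternary"

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=np.complex128)
        if self.masks.ndim < 2:
            raise ValueError("masks must have shape (K, *signal_shape)")

    @property
    def K(self) -> int:
        return self.masks.shape[0]

    @property
    def shape(self) -> tuple[int, ...]:
        """Shape of the signal the masks apply to."""
        return self.masks.shape[1:]

    @property
    def N(self) -> int:
        return int(np.prod(self.shape))

    def save_npz(self, path) -> None:
        np.savez(
            path,
            masks=self.masks,
            seed=np.array(-1 if self.seed is None else self.seed),
            alphabet=np.array(self.alphabet),
        )

    @classmethod
    def load_npz(cls, path) -> "MaskSet":
        with np.load(path, allow_pickle=False) as f:
            seed = int(f["seed"])
            return cls(
                masks=f["masks"],
                seed=None if seed < 0 else seed,
                alphabet=str(f["alphabet"]),
            )

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("masks", data=self.masks)
            f.attrs["seed"] = -1 if self.seed is None else self.seed
            f.attrs["alphabet"] = self.alphabet

    @classmethod
    def load_hdf5(cls, path) -> "MaskSet":
        import h5py

        with h5py.File(path, "r") as f:
            seed = int(f.attrs["seed"])
            return cls(
                masks=f["masks"][...],
                seed=None if seed < 0 else seed,
                alphabet=str(f.attrs["alphabet"]),
            )


def sample_masks(
    shape: int | tuple[int, ...],
    K: int,
    seed: int | None = None,
    alphabet: str = "quaternary",
) -> MaskSet:
    """Draw K masks with i.i.d. entries uniform over the alphabet.

    ``shape`` is the signal shape: an int N for 1-D signals or (H, W) for
    images.  Entries are uniform over {1, -1, i, -i} by default; the draw is
    reproducible given ``seed``.
    """
    if isinstance(shape, (int, np.integer)):
        shape = (int(shape),)
    else:
        shape = tuple(int(s) for s in shape)
    N = int(np.prod(shape))
    if N < 2:
        raise ValueError(f"signal size must be >= 2, got {N}")
    if K < 1:
        raise ValueError(f"mask count K must be >= 1, got {K}")
    letters = ALPHABETS[alphabet]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(letters), size=(K,) + shape)
    return MaskSet(masks=letters[idx], seed=seed, alphabet=alphabet)


def _check_signal(x: np.ndarray, masks: MaskSet, name: str = "x") -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.shape != masks.shape:
        raise ValueError(
            f"{name} has shape {x.shape}, masks expect {masks.shape}"
        )
    return x


def forward_intensity(x: np.ndarray, masks: MaskSet) -> np.ndarray:
    """Noise-free CDP intensities ``y_ij = |DFT(W_j * x)_i|^2``.

    Returns a real (N, K) matrix; column j stacks the (flattened) squared
    DFT magnitudes under mask j.  Uses the unnormalized DFT, so
    ``sum_i y_ij = N * ||x||^2`` for every mask (Parseval).
    """
    x = _check_signal(x, masks)
    z = _fftn(masks.masks * x[None])
    Y = (z.real**2 + z.imag**2).reshape(masks.K, masks.N).T
    return np.ascontiguousarray(Y)


def bilinear_intensity(a: np.ndarray, b: np.ndarray, masks: MaskSet) -> np.ndarray:
    """Entries ``a^T H_ij b`` of the split-variable bilinear measurement.

    Computed matrix-free as ``Re{z_a conj(z_b)}`` with ``z_v = DFT(W_j * v)``;
    this is the unique conjugation convention whose diagonal case
    ``a = b = x`` reproduces :func:`forward_intensity`.  Symmetric in (a, b).
    """
    a = _check_signal(a, masks, "a")
    b = _check_signal(b, masks, "b")
    za = _fftn(masks.masks * a[None])
    zb = _fftn(masks.masks * b[None])
    out = (za * zb.conj()).real.reshape(masks.K, masks.N).T
    return np.ascontiguousarray(out)


class BilinearOperator:
    """The KN x N sensing matrix ``H_a`` of the split formulation, matrix-free.

    Row (i + N(j-1)) of ``H_a`` is ``a^T H_ij``.  The anchor's masked spectra
    ``z_{a,:,j} = DFT(W_j * a)`` are cached once; each application or adjoint
    then costs K batched FFTs.

    The public :meth:`apply`/:meth:`adjoint` use the (N, K) observation
    layout.  The underscore variants work in the internal (K, *shape)
    layout and avoid reshapes — they are the solver's hot path.
    """

    def __init__(self, anchor: np.ndarray, masks: MaskSet):
        self.anchor = _check_signal(anchor, masks, "anchor")
        self.masks = masks
        self.spectra = _fftn(masks.masks * self.anchor[None])

    # -- internal layout (K, *shape) ------------------------------------
    def _apply(self, v: np.ndarray) -> np.ndarray:
        zv = _fftn(self.masks.masks * v[None])
        return (self.spectra * zv.conj()).real

    def _adjoint(self, r: np.ndarray) -> np.ndarray:
        t = _ifftn_unnorm(r * self.spectra)
        return (self.masks.masks.conj() * t).real.sum(axis=0)

    def _normal(self, v: np.ndarray) -> np.ndarray:
        """v -> H_a^T H_a v, the normal-equations operator."""
        return self._adjoint(self._apply(v))

    # -- public layout (N, K) -------------------------------------------
    def to_internal(self, Y: np.ndarray) -> np.ndarray:
        Y = np.asarray(Y, dtype=np.float64)
        if Y.shape != (self.masks.N, self.masks.K):
            raise ValueError(
                f"observations have shape {Y.shape}, expected "
                f"{(self.masks.N, self.masks.K)}"
            )
        return Y.T.reshape((self.masks.K,) + self.masks.shape)

    def apply(self, v: np.ndarray) -> np.ndarray:
        """H_a v as an (N, K) matrix; equals bilinear_intensity(anchor, v)."""
        v = _check_signal(v, self.masks, "v")
        out = self._apply(v).reshape(self.masks.K, self.masks.N).T
        return np.ascontiguousarray(out)

    def adjoint(self, r: np.ndarray) -> np.ndarray:
        """H_a^T r = sum_ij r_ij H_ij a, satisfying <H_a v, r> = <v, H_a^T r>."""
        return self._adjoint(self.to_internal(r))


def apply_adjoint(op: BilinearOperator, r: np.ndarray) -> np.ndarray:
    """Functional alias for ``op.adjoint(r)`` (r in (N, K) layout)."""
    return op.adjoint(r)


def weighted_backprojection(
    masks: MaskSet, anchor: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """``sum_ij c_ij H_ij v`` for an (N, K) weight matrix c and signal v.

    This is the building block of the spectral initializers and of the
    Wirtinger-flow gradient: H_ij v in the i-th frequency bin of mask j is
    back-projected with weight c_ij.
    """
    op = BilinearOperator(anchor, masks)
    return op.adjoint(weights)


def add_awgn(
    Y: np.ndarray, snr_db: float, seed: int | None = None
) -> np.ndarray:
    """Corrupt observations with additive white Gaussian noise at a given SNR.

    The noise variance is set so that ``10 log10(||Y||^2 / ||eta||^2)``
    equals ``snr_db`` in expectation, globally over the stacked observation
    vector.  ``snr_db = inf`` returns Y unchanged (a copy is not made).
    """
    if not snr_db > 0:
        raise ValueError(f"snr_db must be positive, got {snr_db}")
    Y = np.asarray(Y, dtype=np.float64)
    if np.isinf(snr_db):
        return Y
    rng = np.random.default_rng(seed)
    sigma = np.linalg.norm(Y) / np.sqrt(Y.size) * 10 ** (-snr_db / 20)
    return Y + rng.normal(0.0, sigma, size=Y.shape)


def realized_snr_db(Y_clean: np.ndarray, Y_noisy: np.ndarray) -> float:
    """Actual SNR in dB of a noisy observation against its clean version."""
    noise = np.asarray(Y_noisy) - np.asarray(Y_clean)
    return 10 * np.log10(np.linalg.norm(Y_clean) ** 2 / np.linalg.norm(noise) ** 2)


def save_observations_npz(path, Y: np.ndarray, snr_db: float = np.inf,
                          seed: int | None = None) -> None:
    np.savez(path, Y=np.asarray(Y, dtype=np.float64),
             snr_db=np.array(snr_db),
             seed=np.array(-1 if seed is None else seed))


def load_observations_npz(path) -> tuple[np.ndarray, float, int | None]:
    with np.load(path, allow_pickle=False) as f:
        seed = int(f["seed"])
        return f["Y"], float(f["snr_db"]), (None if seed < 0 else seed)
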