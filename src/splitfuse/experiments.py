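"""Synthetic signals and simulation drivers.

Protocols implemented here:

* success rates — draw independent (signal, masks) pairs, run a solver
  from a chosen initialization on noise-free observations, and report the
  percentage of trials recovered below a normalized-error threshold;
* convergence traces — per-outer-iteration error curves across mask
  counts K and noise levels;
* noisy reconstruction benchmark — normalized error / PSNR / SSIM tables
  on phantom or user-supplied images.

Seed hygiene: every trial derives its signal, mask, noise and init seeds
as distinct deterministic functions of (master_seed, trial) through
``numpy.random.SeedSequence`` spawn keys, so a fixed master seed
reproduces every table entry.  For mask-count sweeps the K masks are
nested prefixes of one larger draw, so growing K strictly adds
information on matched seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import baselines, init_methods, metrics, solver
from .forward import MaskSet, add_awgn, forward_intensity, sample_masks

__all__ = [
    "ExperimentSpec",
    "generate_signal",
    "phantom_image",
    "derive_seed",
    "run_trial",
    "run_success_rate_experiment",
    "run_convergence_trace",
    "run_noisy_reconstruction",
    "CSV_COLUMNS",
    "SUCCESS_THRESHOLD",
]

#: Frozen result-table schema (diff-friendly regression surface).
CSV_COLUMNS = [
    "solver", "init", "signal_kind", "N", "K", "snr_db", "trial",
    "err", "psnr", "ssim", "n_iters", "converged",
]

#: Normalized-error threshold under which a trial counts as recovered.
SUCCESS_THRESHOLD = 1e-5

SIGNAL_KINDS = ("uniform01", "gaussian", "phantom", "image_file")

_ROLE = {"signal": 0, "masks": 1, "noise": 2, "init": 3}


def derive_seed(master_seed: int, trial: int, role: str) -> int:
    """Deterministic per-trial, per-role child seed below 2^31."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(trial, _ROLE[role]))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def phantom_image(shape: tuple[int, int]) -> np.ndarray:
    """Deterministic piecewise-constant test image in [0, 1].

    A flat background with two rectangles and a disc of distinct
    intensities — enough structure for PSNR/SSIM to be meaningful while
    requiring no image files.
    """
    H, W = shape
    img = np.full((H, W), 0.15)
    img[H // 8: H // 2, W // 8: W // 2] = 0.55
    img[H // 2: 7 * H // 8, W // 2: 7 * W // 8] = 0.85
    yy, xx = np.mgrid[0:H, 0:W]
    disc = (yy - 0.35 * H) ** 2 + (xx - 0.65 * W) ** 2 <= (0.18 * min(H, W)) ** 2
    img[disc] = 1.0
    return img


def load_image(path) -> np.ndarray:
    """Read an 8/16-bit grayscale PNG/TIFF into a float image in [0, 1]."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path), dtype=np.float64)
    if arr.ndim == 3:  # collapse color to luminance
        arr = arr.mean(axis=2)
    peak = 65535.0 if arr.max() > 255 else 255.0
    return arr / peak


def save_image(path, img: np.ndarray) -> None:
    import imageio.v3 as iio

    arr = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(path, (arr * 255).round().astype(np.uint8))


def generate_signal(
    kind: str,
    shape: int | tuple[int, ...],
    seed: int | None = None,
    path=None,
) -> np.ndarray:
    """Draw or load a test signal.

    uniform01 — i.i.d. uniform [0, 1] entries; gaussian — i.i.d. standard
    normal; phantom — the deterministic piecewise-constant image;
    image_file — grayscale file at ``path`` scaled to [0, 1].
    """
    if isinstance(shape, (int, np.integer)):
        shape = (int(shape),)
    else:
        shape = tuple(int(s) for s in shape)
    rng = np.random.default_rng(seed)
    if kind == "uniform01":
        return rng.uniform(size=shape)
    if kind == "gaussian":
        return rng.standard_normal(shape)
    if kind == "phantom":
        if len(shape) != 2:
            raise ValueError("phantom requires a 2-D shape")
        return phantom_image(shape)
    if kind == "image_file":
        return load_image(path)
    raise ValueError(f"unknown signal kind {kind!r}; choose from {SIGNAL_KINDS}")


@dataclass
class ExperimentSpec:
    """Declarative description of a simulation sweep."""

    signal_kind: str = "uniform01"
    shape: tuple[int, ...] = (32, 32)
    K_list: Sequence[int] = (2, 3, 4, 5, 6)
    snr_db_list: Sequence[float] = (np.inf,)
    n_trials: int = 100
    solver_name: str = "proposed"
    init_name: str = "random"
    master_seed: int = 0
    solver_config: solver.SolverConfig = field(default_factory=solver.SolverConfig)
    image_path: str | None = None

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if any(k < 1 for k in self.K_list):
            raise ValueError("all K must be >= 1")


def make_init(
    init_name: str,
    Y: np.ndarray,
    masks: MaskSet,
    seed: int,
    ground_truth: np.ndarray | None = None,
) -> np.ndarray:
    """Build the initial estimate named by ``init_name``.

    "random" is the positive random init; "wf"/"twf"/"taf" the spectral
    inits; "truth" starts at the ground truth (diagnostic only).
    """
    if init_name == "random":
        return init_methods.random_positive_init(Y, masks, seed=seed)
    if init_name in ("wf", "twf", "taf"):
        return init_methods.spectral_init(init_name, Y, masks, seed=seed)
    if init_name == "truth":
        if ground_truth is None:
            raise ValueError("truth init requires a ground truth")
        return np.asarray(ground_truth, dtype=np.float64).copy()
    raise ValueError(f"unknown init {init_name!r}")


def run_trial(
    solver_name: str,
    init_name: str,
    x: np.ndarray,
    masks: MaskSet,
    snr_db: float = np.inf,
    noise_seed: int | None = None,
    init_seed: int | None = None,
    solver_config: solver.SolverConfig | None = None,
) -> solver.RecoveryResult:
    """One reconstruction: simulate observations, initialize, solve.

    The amplitude-flow baselines natively consume non-squared magnitudes,
    so their noise is re-applied to the magnitudes at the same nominal SNR;
    the spectral/random initializers always see the squared magnitudes.
    """
    Y_clean = forward_intensity(x, masks)
    Y = add_awgn(Y_clean, snr_db, seed=noise_seed)
    init = make_init(init_name, Y, masks, init_seed, ground_truth=x)
    if solver_name == "proposed":
        cfg = solver_config or solver.SolverConfig()
        return solver.run(Y, masks, init, cfg, ground_truth=x)
    if solver_name in baselines.BASELINE_METHODS:
        cfg = baselines.BaselineConfig(method=solver_name)
        if solver_name in baselines.MAGNITUDE_METHODS:
            obs = add_awgn(np.sqrt(Y_clean), snr_db, seed=noise_seed)
        else:
            obs = Y
        return baselines.run_baseline(cfg, obs, masks, init, ground_truth=x)
    raise ValueError(f"unknown solver {solver_name!r}")


def _trial_row(spec: ExperimentSpec, K, snr_db, t, res, x) -> dict:
    err = metrics.normalized_error(res.x_hat, x)
    psnr = ssim = np.nan
    if x.ndim == 2:
        psnr, ssim = metrics.image_quality(res.x_hat, x)
    return {
        "solver": spec.solver_name, "init": spec.init_name,
        "signal_kind": spec.signal_kind, "N": int(np.prod(spec.shape)),
        "K": K, "snr_db": snr_db, "trial": t, "err": err,
        "psnr": psnr, "ssim": ssim, "n_iters": res.n_iters,
        "converged": res.converged,
    }


def run_success_rate_experiment(
    spec: ExperimentSpec,
    threshold: float = SUCCESS_THRESHOLD,
) -> pd.DataFrame:
    """Noise-free success-rate protocol.

    For each K: ``n_trials`` independent (signal, masks, init) draws with
    per-trial derived seeds, noise-free observations, success when the
    final normalized error is below ``threshold``.  Returns one row per
    (K,) cell with the rate, a binomial standard error, and the per-trial
    table attached as ``df.attrs["trials"]``.  A trial that raises counts
    as a failure.
    """
    rows, cells = [], []
    for K in spec.K_list:
        errors = []
        for t in range(spec.n_trials):
            x = generate_signal(
                spec.signal_kind, spec.shape,
                seed=derive_seed(spec.master_seed, t, "signal"),
                path=spec.image_path,
            )
            masks = sample_masks(
                spec.shape, K, seed=derive_seed(spec.master_seed, t, "masks")
            )
            try:
                res = run_trial(
                    spec.solver_name, spec.init_name, x, masks,
                    init_seed=derive_seed(spec.master_seed, t, "init"),
                    solver_config=spec.solver_config,
                )
                err = metrics.normalized_error(res.x_hat, x)
            except (solver.NumericalError, FloatingPointError):
                res, err = None, np.inf
            errors.append(err)
            if res is not None:
                rows.append(_trial_row(spec, K, np.inf, t, res, x))
        rate = metrics.success_rate(errors, threshold)
        p = rate / 100.0
        cells.append({
            "solver": spec.solver_name, "init": spec.init_name,
            "signal_kind": spec.signal_kind, "N": int(np.prod(spec.shape)),
            "K": K, "n_trials": spec.n_trials, "success_rate": rate,
            "binomial_se": 100.0 * np.sqrt(p * (1 - p) / spec.n_trials),
        })
    table = pd.DataFrame(cells)
    table.attrs["trials"] = pd.DataFrame(rows, columns=CSV_COLUMNS)
    return table


def _nested_masks(shape, K_max: int, seed: int) -> MaskSet:
    return sample_masks(shape, K_max, seed=seed)


def _mask_prefix(masks: MaskSet, K: int) -> MaskSet:
    return MaskSet(masks.masks[:K], seed=masks.seed, alphabet=masks.alphabet)


def run_convergence_trace(spec: ExperimentSpec) -> pd.DataFrame:
    """Per-iteration error records across (K, SNR) on matched seeds.

    One ground-truth signal and one master mask draw per spec; each K uses
    the first K masks of that draw and each SNR reuses the same noise seed,
    so error differences across cells reflect K and SNR alone.  Returns a
    long table (K, snr_db, iteration, err).
    """
    x = generate_signal(
        spec.signal_kind, spec.shape,
        seed=derive_seed(spec.master_seed, 0, "signal"),
        path=spec.image_path,
    )
    all_masks = _nested_masks(
        spec.shape, max(spec.K_list), derive_seed(spec.master_seed, 0, "masks")
    )
    records = []
    for K in spec.K_list:
        masks = _mask_prefix(all_masks, K)
        for snr_db in spec.snr_db_list:
            res = run_trial(
                spec.solver_name, spec.init_name, x, masks,
                snr_db=snr_db,
                noise_seed=derive_seed(spec.master_seed, 0, "noise"),
                init_seed=derive_seed(spec.master_seed, 0, "init"),
                solver_config=spec.solver_config,
            )
            for i, err in enumerate(res.err_trace, start=1):
                records.append(
                    {"K": K, "snr_db": snr_db, "iteration": i, "err": err}
                )
    return pd.DataFrame(records)


def run_noisy_reconstruction(spec: ExperimentSpec) -> pd.DataFrame:
    """Image-reconstruction benchmark: err / PSNR / SSIM per (K, SNR).

    Runs the configured solver on a phantom or supplied image for every
    (K, snr_db) cell with nested masks and matched seeds, and returns the
    frozen CSV schema.
    """
    x = generate_signal(
        spec.signal_kind, spec.shape,
        seed=derive_seed(spec.master_seed, 0, "signal"),
        path=spec.image_path,
    )
    if x.ndim != 2:
        raise ValueError("noisy reconstruction benchmark expects an image")
    all_masks = _nested_masks(
        spec.shape, max(spec.K_list), derive_seed(spec.master_seed, 0, "masks")
    )
    rows = []
    for K in spec.K_list:
        masks = _mask_prefix(all_masks, K)
        for snr_db in spec.snr_db_list:
            res = run_trial(
                spec.solver_name, spec.init_name, x, masks,
                snr_db=snr_db,
                noise_seed=derive_seed(spec.master_seed, 0, "noise"),
                init_seed=derive_seed(spec.master_seed, 0, "init"),
                solver_config=spec.solver_config,
            )
            rows.append(_trial_row(spec, K, snr_db, 0, res, x))
    return pd.DataFrame(rows, columns=CSV_COLUMNS)
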