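"""Reference gradient-flow and ADMM baselines for CDP phase retrieval.

Re-implementations of the published comparison methods, matrix-free over
the same FFT forward model:

* WF     — Wirtinger flow: gradient descent on the squared-intensity loss
           with the ramped step size of its authors.
* TWF    — truncated Wirtinger flow: Poisson-likelihood gradient with the
           authors' adaptive truncation events.
* TAF    — truncated amplitude flow: amplitude-based loss, gradient over
           the rows whose correlation passes the truncation test.
* MRTAF  — TAF with heavy-ball momentum and a median-based reweighting of
           the residuals (a robustified TAF variant).
* PhaseSplit — ADMM on the same split-variable bilinear formulation as the
           proposed solver (consensus constraint a = b with a scaled dual),
           but without the fusing step.

The amplitude-flow family (TAF, MRTAF) consumes non-squared magnitudes;
everything else consumes squared magnitudes.  Defaults follow the cited
works where stated; parameters the sources leave open are exposed here
with documented values.  The fidelity bar of this module is qualitative:
success/failure patterns and error plateaus, not bit-exactness to the
original MATLAB implementations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import BilinearOperator, MaskSet, _fftn, _ifftn_unnorm
from .metrics import normalized_error
from .solver import RecoveryResult, _cg_normal

__all__ = ["BaselineConfig", "run_baseline", "BASELINE_METHODS"]

BASELINE_METHODS = ("wf", "twf", "taf", "mrtaf", "phasesplit")

#: Methods whose forward model uses non-squared magnitudes.
MAGNITUDE_METHODS = ("taf", "mrtaf")


@dataclass
class BaselineConfig:
    """Per-method parameters, defaulting to the cited works' constants.

    Gradient methods: ``step_mu`` is the (maximum) step size; WF ramps it
    as ``min(1 - exp(-t/tau0), step_mu)``.  TWF truncation uses
    (alpha_lb, alpha_ub, alpha_h); TAF keeps rows with
    ``|z_i| >= psi_i / (1 + taf_gamma)``.  MRTAF adds momentum and drops
    rows whose amplitude residual exceeds ``mrtaf_median_mult`` times the
    median residual.  PhaseSplit: ``admm_rho`` is the relative consensus
    penalty and ``admm_cg_max`` the inner CG cap.
    """

    method: str = "wf"
    max_iters: int = 2500
    tol: float = 1e-15
    # Wirtinger-flow family
    step_mu: float = 0.2
    wf_tau0: float = 330.0
    twf_alpha_lb: float = 0.3
    twf_alpha_ub: float = 5.0
    twf_alpha_h: float = 5.0
    # amplitude-flow family
    taf_gamma: float = 0.7
    taf_step: float = 0.6
    mrtaf_momentum: float = 0.3
    mrtaf_median_mult: float = 6.0
    # PhaseSplit ADMM
    admm_rho: float = 0.1
    admm_cg_max: int = 50
    admm_cg_tol: float = 1e-12

    def __post_init__(self) -> None:
        if self.method not in BASELINE_METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; choose from {BASELINE_METHODS}"
            )
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.method == "phasesplit" and not self.admm_rho > 0:
            raise ValueError("admm_rho must be positive")


def _masked_spectra(masks: MaskSet, x: np.ndarray) -> np.ndarray:
    return _fftn(masks.masks * x[None])


def _backproject(masks: MaskSet, S: np.ndarray) -> np.ndarray:
    """Re{ sum_j W_j^* F^H S_j } — adjoint of x -> F(W x) onto real vectors."""
    t = _ifftn_unnorm(S)
    return (masks.masks.conj() * t).real.sum(axis=0)


def _trace(errs: list[float] | None) -> np.ndarray | None:
    return None if errs is None else np.asarray(errs)


def _rel_change(new: np.ndarray, old: np.ndarray) -> float:
    denom = np.linalg.norm(new)
    return float(np.linalg.norm(new - old) / denom) if denom > 0 else np.inf


def _run_wf_family(
    config: BaselineConfig,
    Y: np.ndarray,
    masks: MaskSet,
    init: np.ndarray,
    ground_truth: np.ndarray | None,
) -> RecoveryResult:
    """WF and TWF share the squared-magnitude gradient structure."""
    K, N = masks.K, masks.N
    M = N * K
    Yk = np.ascontiguousarray(Y.T).reshape((K,) + masks.shape)
    x = np.asarray(init, dtype=np.float64).copy()
    norm0_sq = float(x.ravel() @ x.ravel())
    errs = [] if ground_truth is not None else None
    converged = False
    n = 0
    for n in range(1, config.max_iters + 1):
        z = _masked_spectra(masks, x)
        absz2 = z.real**2 + z.imag**2
        if config.method == "wf":
            # grad = (1/M) sum (|z|^2 - y) H_ij x ; ramped step / ||x0||^2
            r = absz2 - Yk
            grad = _backproject(masks, r * z) / M
            mu = min(1.0 - np.exp(-n / config.wf_tau0), config.step_mu)
            step = mu / norm0_sq
        else:  # twf: Poisson-likelihood gradient with truncation
            absz = np.sqrt(absz2)
            nx = np.linalg.norm(x)
            resid = Yk - absz2
            # E1: moderate normalized correlation sqrt(N)|z_i|/(||a_i|| ||x||)
            # = |z_i|/||x|| for CDP rows; E2: residual not dominated by a
            # single heavy-tailed row.
            rel = absz / nx
            e1 = (rel >= config.twf_alpha_lb) & (rel <= config.twf_alpha_ub)
            e2 = np.abs(resid) <= (
                config.twf_alpha_h / M * np.sum(np.abs(resid)) * rel
            )
            w = (e1 & e2).astype(np.float64)
            safe = np.maximum(absz2, np.finfo(float).tiny)
            grad = -_backproject(masks, (w * 2.0 * resid / safe) * z) / M
            step = config.step_mu / max(norm0_sq, np.finfo(float).tiny)
        x_new = x - step * grad
        delta = _rel_change(x_new, x)
        x = x_new
        if errs is not None:
            errs.append(normalized_error(x, ground_truth))
        if delta < config.tol:
            converged = True
            break
    return RecoveryResult(x, n, converged, _trace(errs))


def _run_amplitude_family(
    config: BaselineConfig,
    psi: np.ndarray,
    masks: MaskSet,
    init: np.ndarray,
    ground_truth: np.ndarray | None,
) -> RecoveryResult:
    """TAF and MRTAF: amplitude loss (1/2M) sum (|z_i| - psi_i)^2."""
    K, N = masks.K, masks.N
    M = N * K
    psik = np.ascontiguousarray(psi.T).reshape((K,) + masks.shape)
    x = np.asarray(init, dtype=np.float64).copy()
    velocity = np.zeros_like(x)
    errs = [] if ground_truth is not None else None
    converged = False
    n = 0
    for n in range(1, config.max_iters + 1):
        z = _masked_spectra(masks, x)
        absz = np.abs(z)
        safe = np.maximum(absz, np.finfo(float).tiny)
        keep = absz >= psik / (1.0 + config.taf_gamma)
        if config.method == "mrtaf":
            res = np.abs(absz - psik)
            med = np.median(res)
            if med > 0:
                keep &= res <= config.mrtaf_median_mult * med
        grad = _backproject(masks, keep * (z - psik * z / safe)) / M
        if config.method == "mrtaf":
            velocity = config.mrtaf_momentum * velocity + grad
            update = velocity
        else:
            update = grad
        x_new = x - config.taf_step * update
        delta = _rel_change(x_new, x)
        x = x_new
        if errs is not None:
            errs.append(normalized_error(x, ground_truth))
        if delta < config.tol:
            converged = True
            break
    return RecoveryResult(x, n, converged, _trace(errs))


def _run_phasesplit(
    config: BaselineConfig,
    Y: np.ndarray,
    masks: MaskSet,
    init: np.ndarray,
    ground_truth: np.ndarray | None,
) -> RecoveryResult:
    """ADMM on the split bilinear objective with consensus a = b.

    b-update: regularized least squares anchored at a (CG on the augmented
    normal equations); a-update: symmetric solve anchored at b; scaled dual
    ascent on the consensus gap.  The penalty is ``admm_rho`` times the
    mean diagonal scale K N ||anchor||^2 of H^T H, keeping the method
    scale-invariant.
    """
    N = masks.N
    a = np.asarray(init, dtype=np.float64).copy()
    b = a.copy()
    u = np.zeros_like(a)
    errs = [] if ground_truth is not None else None
    converged = False
    n = 0

    def _solve(anchor, target, warm):
        """argmin ||H_anchor v - y||^2 + rho_abs ||v - target||^2 via CG."""
        op = BilinearOperator(anchor, masks)
        rho_abs = config.admm_rho * masks.K * N * float(
            anchor.ravel() @ anchor.ravel()
        )
        rhs = op._adjoint(op.to_internal(Y)) + rho_abs * target

        class _Aug:
            def _normal(self, v):
                return op._normal(v) + rho_abs * v

        return _cg_normal(_Aug(), rhs, warm, config.admm_cg_tol,
                          config.admm_cg_max)

    for n in range(1, config.max_iters + 1):
        a_old = a
        b = _solve(a, a - u, b)
        a = _solve(b, b + u, a)
        u = u + b - a
        delta = _rel_change(a, a_old)
        if errs is not None:
            errs.append(normalized_error(a, ground_truth))
        if delta < config.tol:
            converged = True
            break
    return RecoveryResult(a, n, converged, _trace(errs))


def run_baseline(
    config: BaselineConfig,
    observations: np.ndarray,
    masks: MaskSet,
    init: np.ndarray,
    ground_truth: np.ndarray | None = None,
) -> RecoveryResult:
    """Run one baseline solver.

    ``observations`` are squared magnitudes for wf/twf/phasesplit and
    non-squared magnitudes for taf/mrtaf (each family's native forward
    model).  Returns the same :class:`~splitfuse.solver.RecoveryResult`
    contract as the proposed solver.
    """
    observations = np.asarray(observations, dtype=np.float64)
    if observations.shape != (masks.N, masks.K):
        raise ValueError(
            f"observations have shape {observations.shape}, expected "
            f"{(masks.N, masks.K)}"
        )
    if config.method in ("wf", "twf"):
        return _run_wf_family(config, observations, masks, init, ground_truth)
    if config.method in MAGNITUDE_METHODS:
        return _run_amplitude_family(
            config, observations, masks, init, ground_truth
        )
    if config.method == "phasesplit":
        return _run_phasesplit(config, observations, masks, init, ground_truth)
    raise ValueError(f"unknown method {config.method!r}")
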