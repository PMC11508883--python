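"""Split-variable alternating minimization with a fusing (recombination) step.

The phase-retrieval problem is lifted to the rank-1 factorization
``X = b a^T`` so each squared-magnitude measurement becomes bilinear,
``a^T H_ij b``, and each half-step a linear least-squares problem::

    b_n = argmin_b || H_{a_{n-1}} b - y ||^2        (CG on normal equations)
    a_n = b_n = (a_{n-1} + b_n) / 2                 (fusing)

Pure alternation between the two half-steps stalls: the split variables
settle on opposing sides of the true signal.  Averaging them after each
half-step cancels the opposing error components and restores convergence;
only one half-step per outer iteration is needed.

The global sign ambiguity of real phase retrieval is never resolved here —
that is the metrics module's job.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import BilinearOperator, MaskSet

__all__ = [
    "SolverConfig",
    "RecoveryResult",
    "NumericalError",
    "solve_half_step",
    "recombine",
    "run",
]


class NumericalError(RuntimeError):
    """Raised when an inner solve produces non-finite values."""


@dataclass
class SolverConfig:
    """Tunables of the outer loop and the inner CG solve.

    tol : relative outer stopping tolerance on ||a_n - a_{n-1}|| / ||a_n||.
    max_outer : cap q on outer iterations.
    cg_max : cap p on CG iterations per half-step.
    cg_tol : relative residual tolerance for CG.
    warm_start : start CG from the previous half-step's solution.
    fuse : disable to run pure alternation of the two half-steps
        (diagnostic mode; the full algorithm keeps this True).
    """

    tol: float = 1e-15
    max_outer: int = 2500
    cg_max: int = 50
    cg_tol: float = 1e-12
    warm_start: bool = True
    fuse: bool = True

    def __post_init__(self) -> None:
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.max_outer < 1 or self.cg_max < 1:
            raise ValueError("iteration caps must be >= 1")


@dataclass
class RecoveryResult:
    """Outcome of a solver run.

    err_trace holds the sign-invariant normalized error per outer iteration
    and is only populated when a ground truth was supplied.
    """

    x_hat: np.ndarray
    n_iters: int
    converged: bool
    err_trace: np.ndarray | None = None
    step_delta: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def final_error(self) -> float | None:
        if self.err_trace is None or len(self.err_trace) == 0:
            return None
        return float(self.err_trace[-1])


def _cg_normal(
    op: BilinearOperator,
    rhs: np.ndarray,
    x0: np.ndarray,
    tol: float,
    maxiter: int,
) -> np.ndarray:
    """Conjugate gradient on ``H^T H x = rhs``, matrix-free.

    Plain Hestenes–Stiefel CG; each iteration costs one normal-operator
    application, i.e. O(K N log N).  Stops on relative residual ``tol``.
    """
    x = x0.copy()
    r = rhs - op._normal(x)
    p = r.copy()
    rs = float(r.ravel() @ r.ravel())
    stop = (tol * np.linalg.norm(rhs)) ** 2
    for _ in range(maxiter):
        if rs <= stop:
            break
        Ap = op._normal(p)
        pAp = float(p.ravel() @ Ap.ravel())
        if not np.isfinite(pAp) or pAp <= 0:
            # H^T H is PSD; a non-positive curvature signals breakdown
            # (numerically singular operator, e.g. a zero anchor).
            if pAp == 0:
                break
            raise NumericalError("CG breakdown: non-finite or negative curvature")
        alpha = rs / pAp
        x += alpha * p
        r -= alpha * Ap
        rs_new = float(r.ravel() @ r.ravel())
        p = r + (rs_new / rs) * p
        rs = rs_new
    if not np.all(np.isfinite(x)):
        raise NumericalError("CG produced non-finite iterate")
    return x


def solve_half_step(
    anchor: np.ndarray,
    Y: np.ndarray,
    masks: MaskSet,
    config: SolverConfig | None = None,
    warm: np.ndarray | None = None,
) -> np.ndarray:
    """Least-squares minimizer of ``||H_anchor b - y||^2``.

    Solves the normal equations ``H^T H b = H^T y`` by matrix-free CG,
    initialized at ``warm`` when given, else at the anchor itself.
    """
    config = config or SolverConfig()
    anchor = np.asarray(anchor, dtype=np.float64)
    if not np.linalg.norm(anchor) > 0:
        raise NumericalError("zero anchor makes the half-step operator degenerate")
    op = BilinearOperator(anchor, masks)
    rhs = op._adjoint(op.to_internal(Y))
    x0 = anchor if warm is None else np.asarray(warm, dtype=np.float64)
    return _cg_normal(op, rhs, x0, config.cg_tol, config.cg_max)


def recombine(a_prev: np.ndarray, b_new: np.ndarray) -> np.ndarray:
    """Fusing step: the elementwise average ``(a_prev + b_new) / 2``.

    At a half-step optimum the split variables sit on opposing sides of the
    solution, so averaging cancels the leading error components.  The caller
    assigns the result to both variables.
    """
    a_prev = np.asarray(a_prev, dtype=np.float64)
    b_new = np.asarray(b_new, dtype=np.float64)
    if a_prev.shape != b_new.shape:
        raise ValueError(
            f"shape mismatch: {a_prev.shape} vs {b_new.shape}"
        )
    return 0.5 * (a_prev + b_new)


def run(
    Y: np.ndarray,
    masks: MaskSet,
    init: np.ndarray,
    config: SolverConfig | None = None,
    ground_truth: np.ndarray | None = None,
) -> RecoveryResult:
    """Run the full solver from an initial estimate.

    Each outer iteration solves the b half-step anchored at the current
    fused estimate, then fuses.  Stops when the relative change
    ``||a_n - a_{n-1}|| / ||a_n||`` drops below ``config.tol`` or after
    ``config.max_outer`` iterations (``converged=False`` then — not an
    error).  With ``config.fuse=False`` the two half-steps alternate with
    no averaging, which is the stalling variant kept for diagnostics.
    """
    from .metrics import normalized_error

    config = config or SolverConfig()
    a = np.asarray(init, dtype=np.float64).copy()
    if not np.linalg.norm(init) > 0:
        raise ValueError("init must be nonzero")
    b = a.copy()
    errs: list[float] = [] if ground_truth is not None else None
    deltas: list[float] = []
    converged = False
    n = 0
    for n in range(1, config.max_outer + 1):
        warm = b if config.warm_start else None
        b = solve_half_step(a, Y, masks, config, warm=warm)
        if config.fuse:
            a_new = recombine(a, b)
            b = a_new
        else:
            # pure alternation: the a half-step anchored at the fresh b
            a_new = solve_half_step(
                b, Y, masks, config, warm=a if config.warm_start else None
            )
        delta = float(np.linalg.norm(a_new - a))
        scale = float(np.linalg.norm(a_new))
        a = a_new
        deltas.append(delta)
        if errs is not None:
            errs.append(normalized_error(a, ground_truth))
        if scale > 0 and delta / scale < config.tol:
            converged = True
            break
    return RecoveryResult(
        x_hat=a,
        n_iters=n,
        converged=converged,
        err_trace=None if errs is None else np.asarray(errs),
        step_delta=np.asarray(deltas),
    )
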