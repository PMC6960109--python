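"""Stage-1 compressive-sensing recovery.

The missing-value problem is posed as basis pursuit denoise (BPDN) over the
2-D DCT coefficients of the subjects × genes matrix:

    min ||Z||_1  subject to  ||A(Z) - y||_2 <= sigma,

where ``A`` is the masked synthesis operator (inverse 2-D DCT followed by
extraction of the observed entries) and ``y`` is the vector of observed
values.  ``sigma = 0`` (pure basis pursuit, the default) interpolates the
observed entries exactly; a positive ``sigma`` allows a noise-sized misfit.

The solver follows the SPGL1 strategy: BPDN is reduced to a sequence of
Lasso subproblems ``min ||A(Z) - y||_2 s.t. ||Z||_1 <= tau`` solved by a
spectral (Barzilai–Borwein) projected gradient method with a non-monotone
line search, while the ℓ1 budget ``tau`` is driven to the BPDN solution by
Newton root-finding on the Pareto curve ``phi(tau) = ||residual(tau)||_2``
(``phi'(tau) = -||A*(r)||_inf / ||r||_2``).  Only ``apply``/``adjoint``
matrix-vector products are used; the operator is never materialized.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix
from .transforms import (
    DCTBasisPair,
    ObservationMask,
    SensingOperator,
    build_sensing_operator,
    forward_2d,
    inverse_2d,
)

__all__ = ["SolverConfig", "Stage1Result", "bpdn_solve", "recover_stage1"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SolverConfig:
    """Configuration for the BPDN solver.

    sigma: residual target in ℓ2 units of the data vector (0 = basis pursuit).
    max_iters: cap on outer Pareto (Newton) iterations.
    opt_tol: relative optimality tolerance; on convergence
        ``||A(Z) - y|| <= sigma + opt_tol * max(1, ||y||)``.
    dec_tol: relative duality-gap tolerance for each Lasso subproblem.
    spg_iters: cap on projected-gradient iterations per subproblem.
    """

    sigma: float = 0.0
    max_iters: int = 300
    opt_tol: float = 1e-4
    dec_tol: float = 1e-4
    spg_iters: int = 400

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.opt_tol <= 0 or self.dec_tol <= 0:
            raise ValueError("tolerances must be > 0")


@dataclass(frozen=True)
class Stage1Result:
    """Outcome of the compressive-sensing recovery stage."""

    X_tilde: np.ndarray
    Z: np.ndarray
    residual_norm: float
    iterations: int
    converged: bool


def _project_l1_ball(z: np.ndarray, tau: float) -> np.ndarray:
    """Euclidean projection onto the ℓ1 ball of radius tau (Duchi et al.)."""
    if tau <= 0:
        return np.zeros_like(z)
    a = np.abs(z)
    if a.sum() <= tau:
        return z
    u = np.sort(a)[::-1]
    cssv = np.cumsum(u) - tau
    k = np.arange(1, u.size + 1)
    rho = np.nonzero(u * k > cssv)[0][-1]
    theta = cssv[rho] / (rho + 1.0)
    return np.sign(z) * np.maximum(a - theta, 0.0)


def _spg_lasso(apply_v, adjoint_v, y, z, tau, rgap_tol, max_iter):
    """Approximately solve min 0.5 ||A z - y||^2 s.t. ||z||_1 <= tau by
    spectral projected gradient with a non-monotone Armijo line search.

    Returns (z, r, atr, n_iters) with r = y - A z and atr = A* r.
    """
    gamma = 1e-4
    history = 10
    step_min, step_max = 1e-12, 1e12

    z = _project_l1_ball(z, tau)
    r = y - apply_v(z)
    f = 0.5 * float(r @ r)
    atr = adjoint_v(r)  # = -grad f
    f_hist = [f]
    gnorm = np.max(np.abs(atr)) if atr.size else 0.0
    step = 1.0 / gnorm if gnorm > 0 else 1.0

    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # Duality gap of the Lasso subproblem at (z, r):
        # gap = r.(r - y) + tau * ||A* r||_inf  >= 0 at feasible z.
        gap = float(r @ (r - y)) + tau * np.max(np.abs(atr))
        if abs(gap) / max(1.0, f) <= rgap_tol:
            break

        f_ref = max(f_hist[-history:])
        alpha = float(np.clip(step, step_min, step_max))
        while True:
            z_new = _project_l1_ball(z + alpha * atr, tau)
            d = z_new - z
            r_new = y - apply_v(z_new)
            f_new = 0.5 * float(r_new @ r_new)
            # Armijo on the projected-arc; grad f = -atr.
            if f_new <= f_ref + gamma * float(-atr @ d) or alpha < step_min:
                break
            alpha /= 2.0
        atr_new = adjoint_v(r_new)
        s = z_new - z
        g_diff = atr - atr_new  # = grad_new - grad_old
        sts = float(s @ s)
        sty = float(s @ g_diff)
        step = sts / sty if sty > 0 else step_max
        z, r, f, atr = z_new, r_new, f_new, atr_new
        f_hist.append(f)
        if sts <= 1e-30 * max(1.0, float(z @ z)):
            break
    return z, r, atr, n_iter


def bpdn_solve(
    op: SensingOperator,
    y: np.ndarray,
    cfg: SolverConfig | None = None,
    return_info: bool = False,
):
    """Solve min ||Z||_1 s.t. ||op.apply(Z) - y||_2 <= cfg.sigma.

    Returns the coefficient matrix Z (and, with ``return_info=True``, a dict
    with residual_norm / iterations / converged).  On non-convergence the
    best iterate is returned with a warning, never silently.
    """
    cfg = cfg or SolverConfig()
    y = np.asarray(y, dtype=float).ravel()
    m, n = op.shape
    if y.size != op.n_measurements:
        raise ValueError(
            f"data vector length {y.size} != observed entries {op.n_measurements}"
        )

    def apply_v(z):
        return op.apply(z.reshape(m, n))

    def adjoint_v(v):
        return op.adjoint(v).ravel()

    info = {"residual_norm": 0.0, "iterations": 0, "converged": True}
    ynorm = float(np.linalg.norm(y))
    if ynorm == 0.0 or cfg.sigma >= ynorm:
        # Z = 0 is feasible and has minimal ℓ1 norm.
        info["residual_norm"] = ynorm
        Z = np.zeros((m, n))
        return (Z, info) if return_info else Z

    if (
        op.n_measurements == m * n
        and getattr(op, "mask", None) is not None
        and getattr(op, "basis", None) is not None
    ):
        # Fully observed: the synthesis operator is orthonormal, the equality
        # system determines Z uniquely, and the solution is the analysis
        # transform of the (row-major) data.
        X = np.zeros(m * n)
        X[np.flatnonzero(op.mask.entries.ravel())] = y
        Z = forward_2d(X.reshape(m, n), op.basis)
        info["residual_norm"] = float(np.linalg.norm(apply_v(Z.ravel()) - y))
        return (Z, info) if return_info else Z

    feas_tol = cfg.sigma + cfg.opt_tol * max(1.0, ynorm)
    z = np.zeros(m * n)
    tau = 0.0
    r = y.copy()
    rnorm = ynorm
    total_spg = 0
    converged = False
    for outer in range(1, cfg.max_iters + 1):
        z, r, atr, nit = _spg_lasso(
            apply_v, adjoint_v, y, z, tau, cfg.dec_tol, cfg.spg_iters
        )
        total_spg += nit
        rnorm = float(np.linalg.norm(r))
        if rnorm <= feas_tol:
            converged = True
            break
        gnorm = float(np.max(np.abs(atr)))
        if gnorm <= 1e-14 * rnorm:
            # Residual cannot be reduced further (y outside the range at this
            # accuracy); treat as converged to the least-misfit solution.
            converged = rnorm <= cfg.sigma + np.sqrt(cfg.opt_tol) * max(1.0, ynorm)
            break
        # Newton step on phi(tau) = ||r(tau)||: phi' = -gnorm / rnorm.
        delta = rnorm * (rnorm - cfg.sigma) / gnorm
        tau = tau + max(delta, 1e-3 * max(tau, 1.0) * cfg.opt_tol)
        logger.debug(
            "bpdn outer %d: tau=%.6g rnorm=%.3e spg_iters=%d", outer, tau, rnorm, nit
        )
    info = {
        "residual_norm": rnorm,
        "iterations": total_spg,
        "converged": converged,
    }
    if not converged:
        warnings.warn(
            f"bpdn_solve did not reach the residual target "
            f"(||r|| = {rnorm:.3e} > {feas_tol:.3e}); returning best iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    Z = z.reshape(m, n)
    return (Z, info) if return_info else Z


def recover_stage1(
    Y: ExpressionMatrix | np.ndarray,
    mask: ObservationMask,
    cfg: SolverConfig | None = None,
) -> Stage1Result:
    """Recover a complete matrix from the observed entries of ``Y`` by sparse
    recovery in the 2-D DCT domain (Stage 1)."""
    values = Y.values if isinstance(Y, ExpressionMatrix) else np.asarray(Y, float)
    if values.shape != mask.shape:
        raise ValueError("matrix and mask shapes differ")
    basis = DCTBasisPair.for_shape(values.shape)
    op = build_sensing_operator(mask, basis)
    y = values.ravel(order="C")[np.flatnonzero(mask.entries.ravel(order="C"))]
    Z, info = bpdn_solve(op, y, cfg, return_info=True)
    X_tilde = inverse_2d(Z, basis)
    return Stage1Result(
        X_tilde=X_tilde,
        Z=Z,
        residual_norm=info["residual_norm"],
        iterations=info["iterations"],
        converged=info["converged"],
    )
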