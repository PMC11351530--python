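"""Symmetric positive-definite (SPD) matrix primitives for EEG covariance
descriptors.

A motor-imagery trial is summarized by its spatial covariance matrix, a point
on the SPD manifold.  This module provides the covariance estimator and the
matrix/manifold operations the tangent-space pipeline needs: matrix square
root, logarithm and exponential (all via eigendecomposition of the
symmetrized input), the affine-invariant Fréchet (Riemannian) mean, and the
affine-invariant geodesic distance.

All functions accept and return plain ``numpy`` arrays; an SPD "set" is a
stacked array of shape ``(N, e, e)``.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "check_spd",
    "estimate_trial_covariance",
    "matrix_sqrt",
    "matrix_invsqrt",
    "matrix_log",
    "matrix_exp",
    "riemannian_mean",
    "riemannian_distance",
]

#: relative symmetry tolerance for SPD validation
SYM_TOL = 1e-10

#: relative diagonal jitter applied to degenerate covariance estimates
JITTER_REL = 1e-10


def _as_square(A: np.ndarray, name: str = "matrix") -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"{name} must be square, got shape {A.shape}")
    if not np.all(np.isfinite(A)):
        raise ValueError(f"{name} contains non-finite entries")
    return A


def check_spd(C: np.ndarray, tol: float = SYM_TOL) -> np.ndarray:
    """Validate that ``C`` is symmetric positive definite.

    Symmetry is checked relative to the largest absolute entry; positive
    definiteness via the smallest eigenvalue of the symmetrized matrix.
    Returns the validated (symmetrized) matrix.
    """
    C = _as_square(C, "SPD matrix")
    scale = max(np.abs(C).max(), 1.0)
    if np.abs(C - C.T).max() > tol * scale:
        raise ValueError("matrix is not symmetric within tolerance")
    Cs = (C + C.T) / 2.0
    w = np.linalg.eigvalsh(Cs)
    if w[0] <= 0.0:
        raise ValueError(
            f"matrix is not positive definite (min eigenvalue {w[0]:.3e})"
        )
    return Cs


def estimate_trial_covariance(
    trial: np.ndarray, shrinkage: float = 0.0
) -> np.ndarray:
    """Spatial covariance of one multichannel trial.

    Parameters
    ----------
    trial : ndarray, shape (e, T)
        One EEG trial, ``e`` channels by ``T`` samples (µV).
    shrinkage : float in [0, 1]
        Convex blend toward the scaled identity ``(tr(C)/e)·I``.  The default
        0 is the plain sample covariance.

    Returns
    -------
    ndarray, shape (e, e)
        ``X_c X_cᵀ / (T − 1)`` with ``X_c`` the row-mean-centered trial.
        If the result is numerically singular (e.g. a constant channel), a
        diagonal jitter of ``1e-10·tr(C)/e`` is added (escalating tenfold if
        needed) so the output is strictly positive definite.
    """
    X = np.asarray(trial, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"trial must be 2-D (channels × samples), got {X.ndim}-D")
    e, T = X.shape
    if e < 2:
        raise ValueError("trial needs at least 2 channels")
    if T < 2:
        raise ValueError("trial needs at least 2 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("trial contains non-finite entries")
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")

    Xc = X - X.mean(axis=1, keepdims=True)
    C = (Xc @ Xc.T) / (T - 1)
    if shrinkage > 0.0:
        mu = np.trace(C) / e
        C = (1.0 - shrinkage) * C + shrinkage * mu * np.eye(e)
    C = (C + C.T) / 2.0

    # degenerate trials (rank-deficient, constant channels) get a tiny ridge
    jitter = JITTER_REL * max(np.trace(C), 1.0) / e
    for _ in range(16):
        if np.linalg.eigvalsh(C)[0] > 0.0:
            break
        C = C + jitter * np.eye(e)
        jitter *= 10.0
    return C


def _eig_fun(C: np.ndarray, fun, require_spd: bool = True) -> np.ndarray:
    """Apply a scalar function to the eigenvalues of a symmetric matrix."""
    Cs = (C + C.T) / 2.0
    w, V = np.linalg.eigh(Cs)
    if require_spd and w[0] <= 0.0:
        raise ValueError(
            f"matrix is not positive definite (min eigenvalue {w[0]:.3e})"
        )
    return (V * fun(w)) @ V.T


def matrix_sqrt(C: np.ndarray) -> np.ndarray:
    """Principal square root of an SPD matrix (S with S·S = C)."""
    return _eig_fun(_as_square(C), np.sqrt)


def matrix_invsqrt(C: np.ndarray) -> np.ndarray:
    """Inverse principal square root of an SPD matrix."""
    return _eig_fun(_as_square(C), lambda w: 1.0 / np.sqrt(w))


def matrix_log(C: np.ndarray) -> np.ndarray:
    """Matrix logarithm of an SPD matrix (symmetric result)."""
    return _eig_fun(_as_square(C), np.log)


def matrix_exp(S: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix (SPD result)."""
    S = _as_square(S, "symmetric matrix")
    scale = max(np.abs(S).max(), 1.0)
    if np.abs(S - S.T).max() > 1e-8 * scale:
        raise ValueError("matrix_exp requires a symmetric matrix")
    return _eig_fun(S, np.exp, require_spd=False)


def _as_stack(covs) -> np.ndarray:
    covs = np.asarray(covs, dtype=float)
    if covs.ndim == 2:
        covs = covs[None]
    if covs.ndim != 3 or covs.shape[1] != covs.shape[2]:
        raise ValueError(f"expected a stack of square matrices, got {covs.shape}")
    return covs


def riemannian_mean(
    covs,
    tol: float = 1e-8,
    max_iter: int = 100,
    return_info: bool = False,
):
    """Affine-invariant Fréchet mean of a set of SPD matrices.

    Fixed-point iteration ``M ← M^{1/2} exp(mean_i log(M^{-1/2} C_i M^{-1/2}))
    M^{1/2}`` initialized at the arithmetic mean, stopped when the Frobenius
    norm of the mean tangent vector drops below ``tol``.

    Parameters
    ----------
    covs : ndarray, shape (N, e, e)
        Non-empty stack of SPD matrices.
    tol, max_iter :
        Convergence controls.  Non-convergence raises a warning; the last
        iterate is still returned (``info["converged"]`` records the flag).
    return_info : bool
        If True, also return ``{"converged", "n_iter", "residual"}``.
    """
    covs = _as_stack(covs)
    N = covs.shape[0]
    if N == 0:
        raise ValueError("riemannian_mean of an empty set")

    M = covs.mean(axis=0)
    converged = False
    resid = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        M_half = matrix_sqrt(M)
        M_ihalf = matrix_invsqrt(M)
        logs = np.zeros_like(M)
        for C in covs:
            logs += matrix_log(M_ihalf @ C @ M_ihalf)
        logs /= N
        resid = float(np.linalg.norm(logs, "fro"))
        if resid < tol:
            converged = True
            break
        M = M_half @ matrix_exp(logs) @ M_half
        M = (M + M.T) / 2.0
    if not converged:
        warnings.warn(
            f"Fréchet mean did not converge in {max_iter} iterations "
            f"(residual {resid:.3e})",
            RuntimeWarning,
        )
    if return_info:
        return M, {"converged": converged, "n_iter": it, "residual": resid}
    return M


def riemannian_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Affine-invariant geodesic distance ``‖log(A^{-1/2} B A^{-1/2})‖_F``."""
    A = _as_square(A, "A")
    B = _as_square(B, "B")
    if A.shape != B.shape:
        raise ValueError(f"dimension mismatch: {A.shape} vs {B.shape}")
    A_ihalf = matrix_invsqrt(A)
    return float(np.linalg.norm(matrix_log(A_ihalf @ B @ A_ihalf), "fro"))
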