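"""Covariance descriptors: multiple tangent-space projections and Cholesky
features.

Two alternative vector descriptors of a trial covariance matrix ``C``:

* **M-TSP** — project ``C`` into the tangent space at each class-wise
  Riemannian reference mean ``Cref_m`` via
  ``Z_m = Cref_m^{1/2} log(Cref_m^{-1/2} C Cref_m^{-1/2}) Cref_m^{1/2}``,
  vectorize the upper triangle of each ``Z_m`` and concatenate, giving a
  feature vector of length ``M·e(e+1)/2``.
* **Cholesky** — factor ``C = L Lᵀ`` and take the lower-triangular entries of
  ``L`` (length ``e(e+1)/2``).

Vectorization is row-major over the triangle, diagonal included, with no
rescaling of off-diagonal entries (an optional √2 off-diagonal weighting is
available but off by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spd import (
    check_spd,
    matrix_invsqrt,
    matrix_log,
    matrix_sqrt,
    riemannian_mean,
)

__all__ = [
    "TangentReferenceBank",
    "fit_reference_bank",
    "tangent_project",
    "upper_vectorize",
    "mtsp_transform",
    "cholesky_features",
    "extract_features",
    "feature_frame",
]


@dataclass
class TangentReferenceBank:
    """Per-class Riemannian reference means with cached matrix-root factors.

    ``refs[m]`` is the Fréchet mean of the class ``class_order[m]`` training
    covariances; ``sqrts``/``invsqrts`` cache ``refs[m]^{±1/2}`` so repeated
    projections avoid re-decomposing.
    """

    refs: np.ndarray  # (M, e, e)
    class_order: np.ndarray  # (M,)
    sqrts: np.ndarray = field(repr=False, default=None)
    invsqrts: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        self.refs = np.asarray(self.refs, dtype=float)
        if self.refs.ndim != 3 or self.refs.shape[1] != self.refs.shape[2]:
            raise ValueError("refs must be a (M, e, e) stack")
        self.class_order = np.asarray(self.class_order)
        if len(self.class_order) != len(self.refs):
            raise ValueError("class_order length must match refs")
        if len(np.unique(self.class_order)) != len(self.class_order):
            raise ValueError("class_order has duplicate labels")
        if self.sqrts is None:
            self.sqrts = np.stack([matrix_sqrt(R) for R in self.refs])
        if self.invsqrts is None:
            self.invsqrts = np.stack([matrix_invsqrt(R) for R in self.refs])

    @property
    def n_classes(self) -> int:
        return len(self.refs)

    @property
    def n_channels(self) -> int:
        return self.refs.shape[1]


def fit_reference_bank(
    covs, labels, tol: float = 1e-8, max_iter: int = 100
) -> TangentReferenceBank:
    """Fit one Riemannian mean per class (ascending label order)."""
    covs = np.asarray(covs, dtype=float)
    labels = np.asarray(labels)
    if covs.ndim != 3:
        raise ValueError("covs must be a (N, e, e) stack")
    if len(labels) != len(covs):
        raise ValueError("labels length must match number of matrices")
    classes = np.unique(labels)
    if len(classes) < 1:
        raise ValueError("need at least one class")
    refs = []
    for cls in classes:
        members = covs[labels == cls]
        if len(members) == 0:  # pragma: no cover - unique() precludes this
            raise ValueError(f"class {cls} has no members")
        refs.append(riemannian_mean(members, tol=tol, max_iter=max_iter))
    return TangentReferenceBank(refs=np.stack(refs), class_order=classes)


def tangent_project(
    C: np.ndarray,
    Cref: np.ndarray | None = None,
    *,
    sqrt: np.ndarray | None = None,
    invsqrt: np.ndarray | None = None,
) -> np.ndarray:
    """Project ``C`` into the tangent space at ``Cref``.

    Returns ``Cref^{1/2} · log(Cref^{-1/2} C Cref^{-1/2}) · Cref^{1/2}``,
    a symmetric matrix.  Precomputed ``Cref^{±1/2}`` factors may be passed
    instead of (or in addition to) ``Cref``.
    """
    C = np.asarray(C, dtype=float)
    if sqrt is None or invsqrt is None:
        if Cref is None:
            raise ValueError("either Cref or its sqrt/invsqrt factors required")
        sqrt = matrix_sqrt(Cref)
        invsqrt = matrix_invsqrt(Cref)
    if C.shape != sqrt.shape:
        raise ValueError(f"dimension mismatch: {C.shape} vs {sqrt.shape}")
    Z = sqrt @ matrix_log(invsqrt @ C @ invsqrt) @ sqrt
    return (Z + Z.T) / 2.0


def upper_vectorize(Z: np.ndarray, weight_offdiag: bool = False) -> np.ndarray:
    """Row-major upper-triangle vectorization (diagonal included).

    ``weight_offdiag=True`` applies the √2 off-diagonal weighting that makes
    the Euclidean norm of the vector equal the Frobenius norm of ``Z``; the
    default takes the triangle entries as-is.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[0] != Z.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {Z.shape}")
    e = Z.shape[0]
    iu = np.triu_indices(e)
    v = Z[iu].copy()
    if weight_offdiag:
        v[iu[0] != iu[1]] *= np.sqrt(2.0)
    return v


def mtsp_transform(
    covs, bank: TangentReferenceBank, weight_offdiag: bool = False
) -> np.ndarray:
    """Multiple tangent-space projection feature vectors.

    For each covariance, concatenates (in ``bank.class_order``)
    ``upper_vectorize(tangent_project(C, Cref_m))`` over the M references,
    yielding vectors of length ``M·e(e+1)/2``.  Accepts a single ``(e, e)``
    matrix (returns a vector) or an ``(N, e, e)`` stack (returns a matrix).
    """
    covs = np.asarray(covs, dtype=float)
    single = covs.ndim == 2
    if single:
        covs = covs[None]
    e = bank.n_channels
    if covs.shape[1:] != (e, e):
        raise ValueError(f"dimension mismatch: {covs.shape[1:]} vs ({e}, {e})")
    blocks = []
    for m in range(bank.n_classes):
        blk = np.stack(
            [
                upper_vectorize(
                    tangent_project(
                        C, sqrt=bank.sqrts[m], invsqrt=bank.invsqrts[m]
                    ),
                    weight_offdiag=weight_offdiag,
                )
                for C in covs
            ]
        )
        blocks.append(blk)
    Z = np.hstack(blocks)
    return Z[0] if single else Z


def cholesky_features(covs) -> np.ndarray:
    """Lower-triangular Cholesky factor entries as a feature vector.

    Factors ``C = L Lᵀ`` (L lower-triangular, positive diagonal) and returns
    the row-major lower-triangle traversal of ``L``, length ``e(e+1)/2``.
    Accepts a single matrix or an ``(N, e, e)`` stack.
    """
    covs = np.asarray(covs, dtype=float)
    single = covs.ndim == 2
    if single:
        covs = covs[None]
    feats = []
    for C in covs:
        Cs = check_spd(C)
        L = np.linalg.cholesky(Cs)
        feats.append(L[np.tril_indices(L.shape[0])])
    F = np.stack(feats)
    return F[0] if single else F


def extract_features(
    covs,
    method: str,
    bank: TangentReferenceBank | None = None,
    weight_offdiag: bool = False,
) -> np.ndarray:
    """Dispatch to ``mtsp`` or ``cholesky`` feature extraction."""
    if method == "mtsp":
        if bank is None:
            raise ValueError("mtsp extraction requires a fitted reference bank")
        return mtsp_transform(covs, bank, weight_offdiag=weight_offdiag)
    if method == "cholesky":
        return cholesky_features(covs)
    raise ValueError(f"unknown feature method {method!r}")


def _triangle_names(prefix: str, e: int, upper: bool) -> list[str]:
    idx = np.triu_indices(e) if upper else np.tril_indices(e)
    return [f"{prefix}_{i + 1}_{j + 1}" for i, j in zip(*idx)]


def feature_frame(
    X: np.ndarray, method: str, e: int, n_classes: int = 2
) -> pd.DataFrame:
    """Feature matrix as a DataFrame with coordinate-named columns.

    Columns are ``ts{m}_{i}_{j}`` (m-th tangent block, 1-based matrix
    coordinates) for M-TSP or ``chol_{i}_{j}`` for Cholesky features.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d = e * (e + 1) // 2
    if method == "mtsp":
        names = []
        for m in range(1, n_classes + 1):
            names += _triangle_names(f"ts{m}", e, upper=True)
    elif method == "cholesky":
        names = _triangle_names("chol", e, upper=False)
    else:
        raise ValueError(f"unknown feature method {method!r}")
    if X.shape[1] != len(names):
        raise ValueError(
            f"feature width {X.shape[1]} inconsistent with e={e} ({len(names)})"
        )
    assert len(names) % d == 0
    return pd.DataFrame(X, columns=names)
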