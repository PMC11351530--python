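"""Gate-generated functional weight classifier (GG-FWC).

A binary classifier whose output is a linear model with input-dependent
weights:

    o(x) = Σ_{d=0..D} Σ_{r=0..R} w_{dr} · k_r(x) · x_d,    x_0 = 1, k_0 ≡ 1

where k_r (r ≥ 1) are unnormalized Gaussian RBF gates centered on k-means
centroids with widths set from per-cluster dispersion scaled by δ.  The
change of variables z_s(x) = k_r(x)·x_d (s = r·(D+1)+d) turns this into a
plain linear model over (R+1)(D+1) expanded features, so training is a
linear maximal-margin (hinge-loss SVM) fit on the expansion.  The r = 0
block is exactly (1, x₁, …, x_D): the model is a fusion of a linear
classifier and a localized nonlinear one.

Inputs are z-scored with training statistics before gate construction and
margin training; the constant z_0 column carries the bias, so the weight
vector alone defines the model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans
from sklearn.svm import LinearSVC

__all__ = ["GateSet", "GGFWC", "fit_gates", "kernel_activations", "expand_features"]


@dataclass
class GateSet:
    """R RBF gates: k-means centroids, per-cluster dispersions and scale δ.

    The effective squared kernel width of gate r is ``2·delta·dispersions[r]``.
    """

    centroids: np.ndarray  # (R, D)
    dispersions: np.ndarray  # (R,)
    delta: float

    def __post_init__(self):
        self.centroids = np.atleast_2d(np.asarray(self.centroids, dtype=float))
        self.dispersions = np.asarray(self.dispersions, dtype=float)
        if self.centroids.shape[0] != self.dispersions.shape[0]:
            raise ValueError("one dispersion per centroid required")
        if self.centroids.shape[0] < 1:
            raise ValueError("need at least one gate")
        if np.any(self.dispersions <= 0.0):
            raise ValueError("dispersions must be strictly positive")
        if self.delta <= 0.0:
            raise ValueError("delta must be strictly positive")

    @property
    def n_gates(self) -> int:
        return self.centroids.shape[0]

    @property
    def n_features(self) -> int:
        return self.centroids.shape[1]


def fit_gates(X: np.ndarray, R: int, delta: float, seed: int = 0) -> GateSet:
    """Build R RBF gates from data by k-means.

    Centroids come from k-means (k-means++ init, 10 restarts, seeded);
    dispersion of gate r is the mean squared Euclidean distance of the
    cluster-r members to their centroid.  Singleton or otherwise degenerate
    clusters (zero within-cluster scatter) fall back to the global dispersion
    — the mean squared distance of all samples to the grand mean — so no gate
    has zero width.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N = X.shape[0]
    if not 1 <= R <= N:
        raise ValueError(f"need 1 <= R <= N, got R={R}, N={N}")
    if delta <= 0.0:
        raise ValueError("delta must be strictly positive")
    km = KMeans(n_clusters=R, init="k-means++", n_init=10, random_state=seed)
    assign = km.fit_predict(X)
    centroids = km.cluster_centers_

    global_disp = float(np.mean(np.sum((X - X.mean(axis=0)) ** 2, axis=1)))
    if global_disp <= 0.0:
        global_disp = 1.0
    disp = np.empty(R)
    for r in range(R):
        members = X[assign == r]
        if len(members) >= 2:
            disp[r] = np.mean(np.sum((members - centroids[r]) ** 2, axis=1))
        else:
            disp[r] = 0.0
        # numerically zero scatter (relative to the data) is degenerate too
        if disp[r] <= 1e-12 * global_disp:
            disp[r] = global_disp
    return GateSet(centroids=centroids, dispersions=disp, delta=float(delta))


def kernel_activations(X: np.ndarray, gates: GateSet) -> np.ndarray:
    """Gate outputs ``k_r(x) = exp(−‖x − c_r‖² / (2·δ·σ_r²))`` in (0, 1]."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    X2 = np.atleast_2d(X)
    if X2.shape[1] != gates.n_features:
        raise ValueError(
            f"dimension mismatch: {X2.shape[1]} vs {gates.n_features}"
        )
    d2 = ((X2[:, None, :] - gates.centroids[None, :, :]) ** 2).sum(axis=2)
    K = np.exp(-d2 / (2.0 * gates.delta * gates.dispersions[None, :]))
    return K[0] if single else K


def expand_features(X: np.ndarray, gates: GateSet) -> np.ndarray:
    """Expanded variable set z_s(x) = k_r(x)·x_d, s = r·(D+1)+d.

    Ordering is r-major then d, with k_0 ≡ 1 and x_0 = 1, so the output has
    (R+1)(D+1) components and its r = 0 block is exactly ``(1, x_1, …, x_D)``.
    """
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    X2 = np.atleast_2d(X)
    K = np.atleast_2d(kernel_activations(X2, gates))
    ones = np.ones((X2.shape[0], 1))
    Ka = np.hstack([ones, K])  # (N, R+1)
    Xa = np.hstack([ones, X2])  # (N, D+1)
    Z = (Ka[:, :, None] * Xa[:, None, :]).reshape(X2.shape[0], -1)
    return Z[0] if single else Z


class GGFWC:
    """Gate-generated functional weight classifier (binary).

    Parameters
    ----------
    R : int
        Number of RBF gates.
    delta : float
        Scale factor applied to the per-cluster dispersions (kernel widths).
    margin_C : float
        Regularization parameter of the maximal-margin (hinge-loss linear
        SVM) training of the expanded linear model.
    seed : int
        Seeds k-means and the margin solver; fits are bit-reproducible.
    """

    def __init__(
        self,
        R: int = 10,
        delta: float = 10.0,
        margin_C: float = 1.0,
        seed: int = 0,
        max_iter: int = 20000,
    ):
        self.R = int(R)
        self.delta = float(delta)
        self.margin_C = float(margin_C)
        self.seed = int(seed)
        self.max_iter = int(max_iter)
        self.gates_: GateSet | None = None
        self.weights_: np.ndarray | None = None
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None
        self.classes_: np.ndarray | None = None

    # -- fitting -----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GGFWC":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        if len(y) != X.shape[0]:
            raise ValueError("X and y length mismatch")
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(
                f"GGFWC is a binary classifier; got {len(classes)} class(es)"
            )
        if X.shape[0] < max(self.R, 2):
            raise ValueError("need at least max(R, 2) training samples")
        self.classes_ = classes  # classes_[0] -> -1, classes_[1] -> +1
        y_pm = np.where(y == classes[1], 1.0, -1.0)

        self.mean_ = X.mean(axis=0)
        self.std_ = np.maximum(X.std(axis=0), 1e-12)
        Xs = (X - self.mean_) / self.std_

        self.gates_ = fit_gates(Xs, self.R, self.delta, seed=self.seed)
        Z = expand_features(Xs, self.gates_)
        svm = LinearSVC(
            loss="hinge",
            C=self.margin_C,
            fit_intercept=False,
            max_iter=self.max_iter,
            tol=1e-6,
            random_state=self.seed,
        )
        svm.fit(Z, y_pm)
        self.weights_ = svm.coef_.ravel().copy()
        return self

    # -- inference ---------------------------------------------------------

    def _check_fitted(self):
        if self.weights_ is None:
            raise RuntimeError("GGFWC model is not fitted")

    def decision_function(self, X: np.ndarray) -> np.ndarray | float:
        """o(x) = w · z(x) on standardized inputs (Eq.-(4) form)."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        Xs = (np.atleast_2d(X) - self.mean_) / self.std_
        Z = expand_features(Xs, self.gates_)
        o = Z @ self.weights_
        return float(o[0]) if single else o

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class prediction; a decision value of exactly 0 goes positive."""
        o = np.atleast_1d(self.decision_function(X))
        idx = (o >= 0.0).astype(int)
        out = self.classes_[idx]
        return out[0] if np.asarray(X).ndim == 1 else out

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(np.atleast_1d(self.predict(X)) == np.asarray(y)))

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "hyperparameters": {
                "R": self.R,
                "delta": self.delta,
                "margin_C": self.margin_C,
                "seed": self.seed,
                "max_iter": self.max_iter,
            },
            "gates": {
                "centroids": self.gates_.centroids.tolist(),
                "dispersions": self.gates_.dispersions.tolist(),
                "delta": self.gates_.delta,
            },
            "weights": self.weights_.tolist(),
            "scaler": {"mean": self.mean_.tolist(), "std": self.std_.tolist()},
            "class_map": {
                str(self.classes_[0]): -1,
                str(self.classes_[1]): 1,
            },
            "classes": np.asarray(self.classes_).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GGFWC":
        hp = d["hyperparameters"]
        model = cls(
            R=hp["R"],
            delta=hp["delta"],
            margin_C=hp["margin_C"],
            seed=hp["seed"],
            max_iter=hp.get("max_iter", 20000),
        )
        model.gates_ = GateSet(
            centroids=np.array(d["gates"]["centroids"], dtype=float),
            dispersions=np.array(d["gates"]["dispersions"], dtype=float),
            delta=float(d["gates"]["delta"]),
        )
        model.weights_ = np.array(d["weights"], dtype=float)
        model.mean_ = np.array(d["scaler"]["mean"], dtype=float)
        model.std_ = np.array(d["scaler"]["std"], dtype=float)
        model.classes_ = np.array(d["classes"])
        return model

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "GGFWC":
        return cls.from_dict(json.loads(Path(path).read_text()))
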