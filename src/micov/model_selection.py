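"""Hyperparameter search for the GG-FWC: (R, δ, C) by Bayesian optimization.

The three classifier hyperparameters are tuned jointly over the design
space used throughout this package: the gate count R as an integer in
[2, 30], the dispersion scale δ continuous on [1, 400] (sampled and modelled
on a log scale), and the margin parameter C on the fixed grid
{1e-4, 1e-3, 1e-2, 0.1, 1, 10, 100, 1000}.  The objective is mean stratified
k-fold cross-validated accuracy on the training data.

The optimizer is sequential model-based: after a random initial design, a
Gaussian-process surrogate (Matérn 5/2 + white noise) is fit to the observed
scores and the next point maximizes expected improvement over a random
candidate pool drawn from the space.  Everything is driven by a single seed,
so a longer run reproduces a shorter run as its prefix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.model_selection import StratifiedKFold

from .ggfwc import GGFWC

__all__ = ["HyperparameterSpace", "TuningResult", "cross_val_score", "tune"]

C_GRID = (0.0001, 0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)


@dataclass
class HyperparameterSpace:
    """Search space for (R, δ, C) with an evaluation budget."""

    R_range: tuple[int, int] = (2, 30)
    delta_range: tuple[float, float] = (1.0, 400.0)
    C_grid: tuple[float, ...] = C_GRID
    budget: int = 300

    def __post_init__(self):
        if self.R_range[0] > self.R_range[1] or self.R_range[0] < 1:
            raise ValueError("invalid R_range")
        if self.delta_range[0] > self.delta_range[1] or self.delta_range[0] <= 0:
            raise ValueError("invalid delta_range")
        if len(self.C_grid) == 0:
            raise ValueError("empty C grid")
        if self.budget < 1:
            raise ValueError("budget must be >= 1")

    def contains(self, params: dict) -> bool:
        return (
            self.R_range[0] <= params["R"] <= self.R_range[1]
            and int(params["R"]) == params["R"]
            and self.delta_range[0] <= params["delta"] <= self.delta_range[1]
            and any(np.isclose(params["C"], c) for c in self.C_grid)
        )

    def sample(self, rng: np.random.Generator) -> dict:
        lo, hi = np.log(self.delta_range[0]), np.log(self.delta_range[1])
        return {
            "R": int(rng.integers(self.R_range[0], self.R_range[1] + 1)),
            "delta": float(np.exp(rng.uniform(lo, hi))),
            "C": float(self.C_grid[rng.integers(len(self.C_grid))]),
        }

    def encode(self, params: dict) -> np.ndarray:
        """Map params to the unit cube for the GP surrogate."""
        r0, r1 = self.R_range
        lo, hi = np.log(self.delta_range[0]), np.log(self.delta_range[1])
        ci = int(np.argmin([abs(np.log10(params["C"]) - np.log10(c)) for c in self.C_grid]))
        return np.array(
            [
                (params["R"] - r0) / max(r1 - r0, 1),
                (np.log(params["delta"]) - lo) / max(hi - lo, 1e-12),
                ci / max(len(self.C_grid) - 1, 1),
            ]
        )


@dataclass
class TuningResult:
    """Best parameters, best CV score and the full evaluation trace."""

    best_params: dict
    best_score: float
    trace: list = field(default_factory=list)  # [(params, score), ...]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "eval_index": i,
                "R": p["R"],
                "delta": p["delta"],
                "C": p["C"],
                "cv_accuracy": s,
            }
            for i, (p, s) in enumerate(self.trace)
        ]
        return pd.DataFrame(rows)

    def save_trace(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def cross_val_score(
    X: np.ndarray,
    y: np.ndarray,
    params: dict,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Mean stratified k-fold held-out accuracy of a GG-FWC fit.

    Deterministic given ``seed``, which fixes both the fold shuffling and
    the per-fold classifier seeds.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if len(y) < folds:
        raise ValueError("fewer samples than folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        model = GGFWC(
            R=int(params["R"]),
            delta=float(params["delta"]),
            margin_C=float(params["C"]),
            seed=seed,
        )
        model.fit(X[tr], y[tr])
        accs.append(model.score(X[te], y[te]))
    return float(np.mean(accs))


def _expected_improvement(
    gp: GaussianProcessRegressor, cand: np.ndarray, best: float, xi: float = 0.01
) -> np.ndarray:
    mu, sd = gp.predict(cand, return_std=True)
    sd = np.maximum(sd, 1e-12)
    imp = mu - best - xi
    z = imp / sd
    return imp * norm.cdf(z) + sd * norm.pdf(z)


def tune(
    X: np.ndarray,
    y: np.ndarray,
    space: HyperparameterSpace | None = None,
    folds: int = 5,
    seed: int = 0,
    objective=None,
    n_initial: int = 10,
    n_candidates: int = 512,
) -> TuningResult:
    """Bayesian (R, δ, C) search maximizing cross-validated accuracy.

    Parameters
    ----------
    objective : callable(params) -> float, optional
        Replaces the default ``cross_val_score`` objective (useful for
        testing the optimizer against a known response surface).
    n_initial : int
        Size of the random initial design (capped at the budget).
    """
    if space is None:
        space = HyperparameterSpace()
    if objective is None:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        if X.shape[0] == 0:
            raise ValueError("empty data")

        def objective(params):
            return cross_val_score(X, y, params, folds=folds, seed=seed)

    rng = np.random.default_rng(seed)
    trace: list[tuple[dict, float]] = []
    encoded: list[np.ndarray] = []
    scores: list[float] = []

    kernel = ConstantKernel(1.0) * Matern(
        length_scale=[0.3, 0.3, 0.3],
        length_scale_bounds=(1e-2, 1e2),
        nu=2.5,
    ) + WhiteKernel(noise_level=1e-4, noise_level_bounds=(1e-8, 1e-1))

    n_init = min(n_initial, space.budget)
    for _ in range(n_init):
        p = space.sample(rng)
        s = float(objective(p))
        trace.append((p, s))
        encoded.append(space.encode(p))
        scores.append(s)

    while len(trace) < space.budget:
        gp = GaussianProcessRegressor(
            kernel=kernel,
            normalize_y=True,
            alpha=1e-8,
            n_restarts_optimizer=1,
            random_state=int(rng.integers(2**31 - 1)),
        )
        with warnings.catch_warnings():
            # hyperparameters at a length-scale bound are fine for acquisition
            warnings.simplefilter("ignore")
            gp.fit(np.array(encoded), np.array(scores))
        cands = [space.sample(rng) for _ in range(n_candidates)]
        enc = np.array([space.encode(c) for c in cands])
        ei = _expected_improvement(gp, enc, max(scores))
        p = cands[int(np.argmax(ei))]
        s = float(objective(p))
        trace.append((p, s))
        encoded.append(space.encode(p))
        scores.append(s)

    best_idx = int(np.argmax(scores))
    return TuningResult(
        best_params=trace[best_idx][0],
        best_score=float(scores[best_idx]),
        trace=trace,
    )
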