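"""Seeded generator of class-conditional multichannel EEG-like trials.

The generator emulates the shape and statistical structure that the
covariance pipeline assumes: each of the two motor-imagery classes has a
fixed spatial covariance "center" on the SPD manifold, the two centers sit
at a controlled geodesic distance (``class_sep``), each trial draws its own
covariance from a Wishart distribution around its class center
(``wishart_dof`` controls the trial-to-trial dispersion, larger = tighter),
and the trial time series is zero-mean Gaussian with that covariance.

Two presets mirror the reference cohorts: a 3-channel set with 360 training
and 240 test trials per subject (``ds1_like``) and a 22-channel set with one
120-trial training and one 120-trial test session per subject
(``ds2_like``).  All randomness flows from the single ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import wishart

from .io_eval import DS2_GENDER, TrialSet
from .spd import matrix_exp, matrix_invsqrt, matrix_log, matrix_sqrt

__all__ = [
    "SyntheticSpec",
    "ds1_like",
    "ds2_like",
    "sample_class_centers",
    "simulate_trials",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic subject's recording.

    e : channels; T : samples per trial; n_train/n_test : trial counts;
    class_sep : geodesic distance between the two class covariance centers;
    wishart_dof : Wishart degrees of freedom (≥ e) of the per-trial
    covariance draw; fs : nominal sampling rate (Hz), metadata only.
    """

    e: int = 22
    T: int = 500
    n_train: int = 120
    n_test: int = 120
    class_sep: float = 1.0
    wishart_dof: int = 50
    seed: int = 0
    fs: float = 250.0

    def __post_init__(self):
        if self.e < 2:
            raise ValueError("need at least 2 channels")
        if self.T <= self.e:
            raise ValueError("need more samples than channels (T > e)")
        if self.class_sep < 0:
            raise ValueError("class_sep must be nonnegative")
        if self.wishart_dof < self.e:
            raise ValueError("wishart_dof must be >= e")


def ds1_like(seed: int = 0, **overrides) -> SyntheticSpec:
    """3-channel preset: 360 training / 240 test trials per subject."""
    base = SyntheticSpec(
        e=3, T=1000, n_train=360, n_test=240, class_sep=1.0,
        wishart_dof=50, seed=seed, fs=250.0,
    )
    return replace(base, **overrides) if overrides else base


def ds2_like(seed: int = 0, **overrides) -> SyntheticSpec:
    """22-channel preset: one 120-trial train and one 120-trial test session."""
    base = SyntheticSpec(
        e=22, T=500, n_train=120, n_test=120, class_sep=1.0,
        wishart_dof=50, seed=seed, fs=250.0,
    )
    return replace(base, **overrides) if overrides else base


def _random_spd(e: int, rng: np.random.Generator, spread: float = 0.5) -> np.ndarray:
    """Random SPD base: exp of a random symmetric matrix (eigenvalues O(1))."""
    A = rng.standard_normal((e, e))
    S = spread * (A + A.T) / np.sqrt(2 * e)
    return matrix_exp(S)


def sample_class_centers(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Two SPD class centers at geodesic distance exactly ``class_sep``.

    The first center is a random SPD base B; the second is B displaced by an
    exponential-map step of norm ``class_sep`` along a random *focal* tangent
    direction ``u uᵀ`` (u a random unit spatial direction), so
    ``riemannian_distance(C1, C2) == class_sep`` up to floating point.  The
    rank-one direction mimics the spatially focal power modulation
    (event-related desynchronization) that distinguishes motor-imagery
    classes, rather than a diffuse change of the whole covariance.
    """
    rng = np.random.default_rng(spec.seed)
    B = _random_spd(spec.e, rng)
    u = rng.standard_normal(spec.e)
    u /= np.linalg.norm(u)
    V = np.outer(u, u) * spec.class_sep  # unit Frobenius norm before scaling
    B_half = matrix_sqrt(B)
    C2 = B_half @ matrix_exp(V) @ B_half
    return B, (C2 + C2.T) / 2.0


def _gaussian_trial(
    Sigma: np.ndarray, T: int, rng: np.random.Generator
) -> np.ndarray:
    L = np.linalg.cholesky(Sigma)
    return L @ rng.standard_normal((Sigma.shape[0], T))


def simulate_trials(
    spec: SyntheticSpec,
    subject_id: str = "S01",
    gender: str = "unknown",
) -> TrialSet:
    """Simulate one subject's labeled train+test trials.

    Per trial, a covariance ``Σ_i ~ Wishart(dof, center/dof)`` (so its mean
    is the class center) is drawn and a zero-mean Gaussian time series with
    covariance ``Σ_i`` is emitted.  Classes are balanced within the train and
    test partitions; trial order within each partition is shuffled.
    """
    rng = np.random.default_rng(spec.seed)
    C1, C2 = sample_class_centers(spec)
    centers = {1: C1, 2: C2}

    trials, labels, roles = [], [], []
    for role, n in (("train", spec.n_train), ("test", spec.n_test)):
        lab = np.repeat([1, 2], [n - n // 2, n // 2])
        rng.shuffle(lab)
        for l in lab:
            Sigma = wishart.rvs(
                df=spec.wishart_dof,
                scale=centers[l] / spec.wishart_dof,
                random_state=rng,
            )
            trials.append(_gaussian_trial(Sigma, spec.T, rng))
            labels.append(int(l))
            roles.append(role)
    return TrialSet(
        trials=np.stack(trials),
        labels=np.array(labels),
        subject_id=subject_id,
        session_role=np.array(roles),
        gender=gender,
        fs=spec.fs,
        classes=(1, 2),
    )


def simulate_cohort(
    base: SyntheticSpec, n_subjects: int = 9, seed: int = 0
) -> list[TrialSet]:
    """Simulate a cohort of subjects with the 4-female/5-male gender pattern.

    Each subject gets an independent sub-seed derived from ``seed`` and its
    own class centers; the gender assignment follows the nine-subject
    reference cohort pattern (subjects 1, 2, 4, 6 female; the rest male),
    cycling for cohorts larger than nine.
    """
    rng = np.random.default_rng(seed)
    sets = []
    for s in range(1, n_subjects + 1):
        sub_seed = int(rng.integers(2**31 - 1))
        spec = replace(base, seed=sub_seed)
        gender = DS2_GENDER.get((s - 1) % 9 + 1, "unknown")
        sets.append(
            simulate_trials(spec, subject_id=f"S{s:02d}", gender=gender)
        )
    return sets
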