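"""Trial containers, the plain-text trial archive, and evaluation summaries.

A :class:`TrialSet` holds the labeled EEG trials of one subject (train and
test sessions together, distinguished by ``session_role``).  Archives are a
directory of delimiter-separated text matrices (one channels × samples file
per trial) plus a JSON manifest carrying labels, subject, session roles,
gender, channel names and sampling rate — readable anywhere, no binary
formats.

Evaluation follows the standard motor-imagery protocol: per-subject test
accuracy, the across-subject mean, and optional gender-group means with the
male − female difference in percentage points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .spd import estimate_trial_covariance

__all__ = [
    "TrialSet",
    "EvaluationReport",
    "write_trialset",
    "read_trialset",
    "evaluate",
    "make_report",
    "gender_summary",
    "DS2_GENDER",
]

#: gender assignment of the nine-subject 22-channel reference cohort
DS2_GENDER = {
    1: "female", 2: "female", 4: "female", 6: "female",
    3: "male", 5: "male", 7: "male", 8: "male", 9: "male",
}

_GENDERS = ("female", "male", "unknown")
_ROLES = ("train", "test")


@dataclass
class TrialSet:
    """Labeled multichannel EEG trials of one subject.

    trials : (N, e, T) array in µV; labels : (N,) class labels;
    session_role : (N,) array of "train"/"test".
    """

    trials: np.ndarray
    labels: np.ndarray
    subject_id: str = "S01"
    session_role: np.ndarray = None
    gender: str = "unknown"
    channel_names: list[str] = field(default_factory=list)
    fs: float = 250.0
    classes: tuple = (1, 2)

    def __post_init__(self):
        self.trials = np.asarray(self.trials, dtype=float)
        if self.trials.ndim != 3:
            raise ValueError("trials must be a (N, e, T) array")
        self.labels = np.asarray(self.labels)
        n = len(self.trials)
        if len(self.labels) != n:
            raise ValueError("labels length must match trial count")
        if self.session_role is None:
            raise ValueError("session_role is required for every trial")
        self.session_role = np.asarray(self.session_role)
        if len(self.session_role) != n:
            raise ValueError("session_role length must match trial count")
        if not set(np.unique(self.session_role)) <= set(_ROLES):
            raise ValueError(f"session_role values must be in {_ROLES}")
        if self.gender not in _GENDERS:
            raise ValueError(f"gender must be one of {_GENDERS}")
        if not set(np.unique(self.labels)) <= set(self.classes):
            raise ValueError("labels outside the declared class set")
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1}" for i in range(self.n_channels)]

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_channels(self) -> int:
        return self.trials.shape[1]

    def subset(self, role: str) -> "TrialSet":
        """Trials of one session role ("train" or "test")."""
        m = self.session_role == role
        return TrialSet(
            trials=self.trials[m],
            labels=self.labels[m],
            subject_id=self.subject_id,
            session_role=self.session_role[m],
            gender=self.gender,
            channel_names=list(self.channel_names),
            fs=self.fs,
            classes=self.classes,
        )

    def covariances(self, shrinkage: float = 0.0) -> np.ndarray:
        """Per-trial spatial covariance matrices, shape (N, e, e)."""
        return np.stack(
            [estimate_trial_covariance(t, shrinkage=shrinkage) for t in self.trials]
        )


def write_trialset(ts: TrialSet, path) -> None:
    """Write a trial archive: trial_<k>.txt matrices + manifest.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    fnames = []
    for k, trial in enumerate(ts.trials):
        fname = f"trial_{k:04d}.txt"
        np.savetxt(path / fname, trial, fmt="%.17e", delimiter="\t")
        fnames.append(fname)
    manifest = {
        "format": "micov-trial-archive-v1",
        "subject_id": ts.subject_id,
        "gender": ts.gender,
        "fs": ts.fs,
        "channel_names": list(ts.channel_names),
        "classes": list(int(c) for c in ts.classes),
        "n_trials": ts.n_trials,
        "trial_files": fnames,
        "labels": [int(l) for l in ts.labels],
        "session_role": [str(r) for r in ts.session_role],
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_trialset(path) -> TrialSet:
    """Read a trial archive written by :func:`write_trialset`."""
    path = Path(path)
    mpath = path / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"no manifest.json under {path}")
    manifest = json.loads(mpath.read_text())
    files = manifest["trial_files"]
    if len(files) != manifest["n_trials"]:
        raise ValueError("manifest trial count does not match file list")
    missing = [f for f in files if not (path / f).exists()]
    if missing:
        raise ValueError(f"manifest lists missing trial files: {missing}")
    trials = []
    shape = None
    for f in files:
        M = np.loadtxt(path / f, delimiter="\t", ndmin=2)
        if shape is None:
            shape = M.shape
        elif M.shape != shape:
            raise ValueError(
                f"ragged trial shapes: {f} is {M.shape}, expected {shape}"
            )
        trials.append(M)
    labels = np.array(manifest["labels"])
    classes = tuple(manifest["classes"])
    if not set(np.unique(labels)) <= set(classes):
        raise ValueError("labels outside the declared class set")
    return TrialSet(
        trials=np.stack(trials) if trials else np.empty((0, 0, 0)),
        labels=labels,
        subject_id=manifest["subject_id"],
        session_role=np.array(manifest["session_role"]),
        gender=manifest["gender"],
        channel_names=list(manifest["channel_names"]),
        fs=manifest["fs"],
        classes=classes,
    )


def evaluate(model, features: np.ndarray, labels) -> float:
    """Fraction of correct predictions on a feature matrix."""
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("empty test set")
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[0] != len(labels):
        raise ValueError("features/labels length mismatch")
    pred = np.atleast_1d(model.predict(features))
    return float(np.mean(pred == labels))


@dataclass
class EvaluationReport:
    """Per-subject accuracies plus their arithmetic mean."""

    per_subject: dict
    mean_accuracy: float
    group_means: dict | None = None


def make_report(per_subject: dict) -> EvaluationReport:
    if not per_subject:
        raise ValueError("empty per-subject accuracy map")
    return EvaluationReport(
        per_subject=dict(per_subject),
        mean_accuracy=float(np.mean(list(per_subject.values()))),
    )


def gender_summary(report: EvaluationReport, grouping: dict) -> dict:
    """Mean accuracy per gender group and the male − female gap.

    ``grouping`` maps every subject in the report to "female" or "male".
    Returns group means (fractions) and their difference in percentage
    points (positive = male advantage).
    """
    groups: dict[str, list[float]] = {"female": [], "male": []}
    for subj, acc in report.per_subject.items():
        if subj not in grouping:
            raise ValueError(f"subject {subj!r} has no gender assignment")
        g = grouping[subj]
        if g not in groups:
            raise ValueError(f"unknown gender group {g!r}")
        groups[g].append(acc)
    means = {g: float(np.mean(v)) if v else float("nan") for g, v in groups.items()}
    diff = (means["male"] - means["female"]) * 100.0
    summary = {
        "female_mean": means["female"],
        "male_mean": means["male"],
        "male_minus_female_points": diff,
        "n_female": len(groups["female"]),
        "n_male": len(groups["male"]),
    }
    report.group_means = {"female": means["female"], "male": means["male"]}
    return summary
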