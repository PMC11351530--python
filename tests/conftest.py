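import numpy as np
import pytest


def random_spd(rng: np.random.Generator, e: int, spread: float = 1.0) -> np.ndarray:
    """Random SPD matrix: exp of a random symmetric matrix."""
    A = rng.standard_normal((e, e))
    S = spread * (A + A.T) / (2 * np.sqrt(e))
    w, V = np.linalg.eigh(S)
    return (V * np.exp(w)) @ V.T


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def spd_factory():
    return random_spd


@pytest.fixture
def xor_data():
    """Four tight clusters at (±1, ±1) with XOR labels.

    No linear rule classifies more than 3 of the 4 cluster centers correctly,
    so any linear classifier is capped at 0.75 training accuracy on balanced
    cluster data, while a localized-gate model can reach 1.0.
    """
    rng = np.random.default_rng(7)
    centers = np.array([[1, 1], [-1, -1], [1, -1], [-1, 1]], dtype=float)
    labels = np.array([1, 1, 2, 2])
    reps = 25
    X = np.vstack([c + 0.05 * rng.standard_normal((reps, 2)) for c in centers])
    y = np.repeat(labels, reps)
    return X, y
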