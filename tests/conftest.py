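import numpy as np
import pytest

import stridedtw as st


def brute_force_delta(D: np.ndarray) -> np.ndarray:
    """Exhaustive-enumeration oracle for the subsequence-DTW distance
    function.

    Delta(n) is the minimum, over every admissible warping path ending
    at cell (M-1, n), of the summed distances along the path.  Paths
    are enumerated explicitly, walking backward from the end cell via
    the allowed predecessors (below-left, below, left); a path
    terminates on its first row-0 cell, except in column 0 where it
    must continue down to (0, 0) — the running-sum initialisation of
    the first column.  Independent of the dynamic-programming
    recurrence it checks.
    """
    D = np.asarray(D, dtype=float)
    M, N = D.shape
    best = np.full(N, np.inf)

    def walk(m: int, n: int, acc: float, end: int) -> None:
        acc += D[m, n]
        if m == 0:
            best[end] = min(best[end], acc)
            return
        if n == 0:
            walk(m - 1, 0, acc, end)
            return
        walk(m - 1, n - 1, acc, end)
        walk(m - 1, n, acc, end)
        walk(m, n - 1, acc, end)

    for end in range(N):
        walk(M - 1, end, 0.0, end)
    return best


@pytest.fixture(scope="session")
def brute_delta():
    return brute_force_delta


@pytest.fixture(scope="session")
def canonical_template_norm():
    """The canonical stride template, normalized, all six axes."""
    return st.normalize_template(st.canonical_template())


@pytest.fixture(scope="session")
def clean_walk():
    """A noise-free, amplitude-unjittered 20-stride walk (seed 42)."""
    spec = st.WalkSpec(n_strides=20, noise_sd=0.0, amplitude_jitter=0.0, seed=42)
    signal, labels = st.generate_walk(spec)
    return signal, labels


@pytest.fixture(scope="session")
def mild_walk():
    """A 10-stride walk with the default mild jitter and noise (seed 42)."""
    spec = st.WalkSpec(n_strides=10, seed=42)
    signal, labels = st.generate_walk(spec)
    return signal, labels


@pytest.fixture()
def zero_signal():
    return st.MultiAxisSignal(np.zeros((400, 6)), fs=102.4, normalized=True)
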