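"""Multi-dimensional subsequence dynamic time warping (msDTW).

The algorithm warps a fixed-length stride template T (length M) onto a
continuous movement sequence S (length N) and reports every
subsequence of S that can be aligned to T at low cost:

1. a per-axis distance matrix D(m, n) = (t_m - s_n)^2;
2. multi-axis combination by element-wise summation of the per-axis
   distance matrices;
3. an accumulated cost matrix C built bottom-to-top by dynamic
   programming, whose top row is the distance function
   Delta(n) = C(M-1, n) — the minimal cost of warping the whole
   template onto a subsequence of S ending at sample n;
4. local minima of Delta below a threshold tau are stride-end
   candidates; backtracking through C recovers the warping path and
   hence the stride start;
5. plausibility constraints (stride duration inside (250, 2000) ms,
   pairwise overlap below 100 ms) prune the candidate set.

Row 0 of D and C corresponds to the template's stride start, row M-1
to its stride end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .signal_core import MultiAxisSignal, parse_axes
from .template import StrideTemplate

try:  # optional JIT acceleration of the DP kernel
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional extra
    _HAVE_NUMBA = False


@dataclass(frozen=True)
class SegmentationConfig:
    """Parameters of the stride segmentation stage.

    tau is the cap on accumulated warping cost (dimensionless, on the
    normalized signal scale) below which a local minimum of the
    distance function counts as a stride-end candidate.  Accumulated
    costs grow with the sampling rate, so a tau value is only
    meaningful at a fixed fs; never compare tau across recordings with
    different sampling rates.
    """

    tau: float
    axes: tuple[str, ...] = ("GY", "GZ")
    min_stride_ms: float = 250.0
    max_stride_ms: float = 2000.0
    max_overlap_ms: float = 100.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "axes", parse_axes(self.axes))
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not (0 < self.min_stride_ms < self.max_stride_ms):
            raise ValueError("require 0 < min_stride_ms < max_stride_ms")
        if self.max_overlap_ms < 0:
            raise ValueError("max_overlap_ms must be non-negative")


@dataclass(frozen=True)
class WarpingPath:
    """An alignment path through the cost matrix.

    ``points`` runs from the stride end (row M-1) down to the stride
    start (row 0); successive (m, n) pairs decrease by one of
    (1, 0), (0, 1) or (1, 1).  ``cost`` is the accumulated cost at the
    path's starting cell, i.e. Delta at the endpoint column.
    """

    points: tuple[tuple[int, int], ...]
    cost: float

    def __len__(self) -> int:
        return len(self.points)

    @property
    def end_column(self) -> int:
        return self.points[0][1]

    @property
    def start_column(self) -> int:
        return self.points[-1][1]


@dataclass(frozen=True)
class StrideSegment:
    """A detected stride: inclusive [start, end] sample interval plus
    its warping cost."""

    start: int
    end: int
    cost: float
    path: WarpingPath | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start must not exceed end")

    def duration_ms(self, fs: float) -> float:
        return (self.end - self.start) * 1000.0 / fs

    def overlap_samples(self, other: "StrideSegment") -> int:
        """Number of shared samples between two inclusive intervals."""
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


def distance_matrix(
    template_axis: np.ndarray, sequence_axis: np.ndarray
) -> np.ndarray:
    """Squared-difference distance matrix D(m, n) = (t_m - s_n)^2.

    Rows index the template (row 0 = stride start), columns the
    sequence.  Both traces must already be on the same (normalized)
    scale.
    """
    t = np.asarray(template_axis, dtype=float)
    s = np.asarray(sequence_axis, dtype=float)
    if t.ndim != 1 or s.ndim != 1:
        raise ValueError("traces must be 1-D")
    if t.size == 0 or s.size == 0:
        raise ValueError("traces must be non-empty")
    return (t[:, None] - s[None, :]) ** 2


def combine_distances(matrices: Sequence[np.ndarray]) -> np.ndarray:
    """Sum per-axis distance matrices element-wise."""
    if len(matrices) == 0:
        raise ValueError("need at least one distance matrix")
    shapes = {np.asarray(m).shape for m in matrices}
    if len(shapes) != 1:
        raise ValueError(f"distance matrices have mismatched shapes: {shapes}")
    out = np.zeros(shapes.pop(), dtype=float)
    for m in matrices:
        out += np.asarray(m, dtype=float)
    return out


def _accumulate_py(D: np.ndarray) -> np.ndarray:
    M, N = D.shape
    C = np.empty_like(D)
    C[0, :] = D[0, :]
    C[:, 0] = np.cumsum(D[:, 0])
    for m in range(1, M):
        for n in range(1, N):
            C[m, n] = D[m, n] + min(C[m - 1, n - 1], C[m - 1, n], C[m, n - 1])
    return C


if _HAVE_NUMBA:
    _accumulate_jit = _njit(cache=True)(_accumulate_py)
else:  # pragma: no cover
    _accumulate_jit = _accumulate_py


def accumulate_costs(D: np.ndarray) -> np.ndarray:
    """Build the accumulated cost matrix C from a distance matrix D.

    Bottom row (row 0, stride start) is copied from D; the first column
    is the running sum of D's first column; every other cell adds
    D(m, n) to the cheapest of its left, below and below-left
    neighbours, filled bottom to top.
    """
    D = np.ascontiguousarray(D, dtype=float)
    if D.ndim != 2 or D.size == 0:
        raise ValueError("D must be a non-empty 2-D matrix")
    if D.shape[0] == 1 or D.shape[1] == 1:
        C = np.empty_like(D)
        C[0, :] = D[0, :]
        C[:, 0] = np.cumsum(D[:, 0])
        return C
    return _accumulate_jit(D)


def distance_function(C: np.ndarray) -> np.ndarray:
    """The distance function Delta: the top row C(M-1, :)."""
    C = np.asarray(C, dtype=float)
    return C[-1, :].copy()


def find_endpoints(delta: np.ndarray, tau: float) -> list[int]:
    """Stride-end candidate columns: local minima of Delta below tau.

    A local minimum is a column strictly smaller than both neighbours;
    plateaus (runs of equal values) count once, at their leftmost
    column, when both flanking values are larger; array boundaries
    qualify when their single neighbour is larger.  Candidates are
    returned in ascending Delta order (ties by column index).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    delta = np.asarray(delta, dtype=float)
    n = delta.size
    if n == 0:
        return []
    if n == 1:
        return [0] if delta[0] < tau else []

    minima: list[int] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and delta[j + 1] == delta[i]:
            j += 1
        left_larger = i == 0 or delta[i - 1] > delta[i]
        right_larger = j == n - 1 or delta[j + 1] > delta[j]
        if left_larger and right_larger and delta[i] < tau:
            minima.append(i)
        i = j + 1
    minima.sort(key=lambda c: (delta[c], c))
    return minima


def backtrack(C: np.ndarray, endpoint: int) -> WarpingPath:
    """Trace the minimal-cost warping path from (M-1, endpoint) to row 0.

    At each step the path moves to the cheapest admissible neighbour —
    below-left, below, or left — with ties broken in that order
    (diagonal first, then vertical, then horizontal), and terminates at
    the first cell reached in row 0.
    """
    C = np.asarray(C, dtype=float)
    M, N = C.shape
    if not (0 <= endpoint < N):
        raise ValueError(f"endpoint {endpoint} outside [0, {N})")
    m, n = M - 1, endpoint
    points = [(m, n)]
    while m > 0:
        if n == 0:
            m -= 1
        else:
            # candidates in tie-break preference order
            steps = (
                (m - 1, n - 1),
                (m - 1, n),
                (m, n - 1),
            )
            costs = [C[i, j] for i, j in steps]
            m, n = steps[int(np.argmin(costs))]
        points.append((m, n))
    return WarpingPath(points=tuple(points), cost=float(C[M - 1, endpoint]))


def apply_constraints(
    candidates: Sequence[tuple[WarpingPath, float]],
    fs: float,
    config: SegmentationConfig,
) -> list[StrideSegment]:
    """Filter warping-path candidates into the final stride list.

    Candidates are visited in ascending cost order.  A candidate is
    kept iff its duration lies strictly inside
    (min_stride_ms, max_stride_ms) and its overlap with every
    already-kept segment is below max_overlap_ms.  Overlap is measured
    on inclusive sample intervals as shared-sample count * 1000 / fs,
    so two consecutive strides sharing a single border sample are
    always admissible at gait sampling rates.  The kept segments are
    returned sorted by start index.
    """
    ordered = sorted(candidates, key=lambda pc: pc[1])
    kept: list[StrideSegment] = []
    for path, cost in ordered:
        seg = StrideSegment(
            start=path.start_column, end=path.end_column, cost=cost, path=path
        )
        duration = seg.duration_ms(fs)
        if not (config.min_stride_ms < duration < config.max_stride_ms):
            continue
        if any(
            seg.overlap_samples(other) * 1000.0 / fs >= config.max_overlap_ms
            for other in kept
        ):
            continue
        kept.append(seg)
    kept.sort(key=lambda s: (s.start, s.end))
    return kept


def compute_distance_function(
    sequence: MultiAxisSignal,
    template: StrideTemplate,
    axes: str | Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Run stages 1-3 of msDTW and return (C, Delta).

    Useful when sweeping tau: the cost matrix does not depend on tau,
    so it can be computed once and reused for every threshold.
    """
    if not sequence.normalized:
        raise ValueError("sequence must be normalized before msDTW")
    if not template.normalized:
        raise ValueError("template must be normalized before msDTW")
    sel = parse_axes(axes)
    missing = [a for a in sel if a not in template.axes]
    if missing:
        raise ValueError(f"axis {missing[0]!r} missing from template")
    D = combine_distances(
        [distance_matrix(template.axis(a), sequence.axis(a)) for a in sel]
    )
    C = accumulate_costs(D)
    return C, distance_function(C)


def segment_strides(
    sequence: MultiAxisSignal,
    template: StrideTemplate,
    config: SegmentationConfig,
) -> list[StrideSegment]:
    """Full msDTW stride segmentation of a movement sequence.

    Orchestrates: per-axis distance matrices -> multi-axis summation ->
    accumulated cost matrix -> distance function -> sub-tau local
    minima -> backtracking -> duration/overlap constraints.
    """
    C, delta = compute_distance_function(sequence, template, config.axes)
    endpoints = find_endpoints(delta, config.tau)
    candidates = [(backtrack(C, e), float(delta[e])) for e in endpoints]
    return apply_constraints(candidates, sequence.fs, config)
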