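"""Evaluation of stride segmentation against manually labeled strides.

Detected stride segments are matched to gold-standard labels when both
borders fall within ±100 ms of the labeled borders (about 10 % of a
stride time); baseline peaks are matched when they lie between a
label's borders.  Precision, recall and F-measure summarise the
counts.  The module also provides the tuning harness: a threshold
sweep over a tau grid and leave-one-subject-out cross-validation
(LOSO CV), where each subject is held out once while tau is chosen on
the remaining subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .msdtw import (
    SegmentationConfig,
    StrideSegment,
    apply_constraints,
    backtrack,
    compute_distance_function,
    find_endpoints,
)
from .signal_core import MultiAxisSignal, parse_axes
from .template import LabeledStride, StrideTemplate

#: Default threshold grid for tuning tau.
DEFAULT_TAU_GRID: tuple[float, ...] = tuple(float(t) for t in range(5, 131, 5))

DEFAULT_TOLERANCE_MS = 100.0


@dataclass(frozen=True)
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class MetricResult:
    precision: float
    recall: float
    f_measure: float


@dataclass(frozen=True)
class SweepRow:
    """One threshold of a sweep: pooled counts over all datasets plus
    both metric variants (pooled counts vs. mean of per-dataset
    metrics — these differ in general and are reported side by side)."""

    tau: float
    counts: EvalCounts
    metrics: MetricResult
    mean_metrics: MetricResult
    n_candidates: int


@dataclass(frozen=True)
class SweepResult:
    axes: tuple[str, ...]
    rows: tuple[SweepRow, ...]

    def best_tau(self) -> float:
        """The tau maximising pooled F-measure (ties -> smallest tau)."""
        best = max(self.rows, key=lambda r: (r.metrics.f_measure, -r.tau))
        return best.tau


@dataclass(frozen=True)
class FoldResult:
    subject: str
    tau: float
    counts: EvalCounts
    metrics: MetricResult


@dataclass(frozen=True)
class LosoResult:
    folds: tuple[FoldResult, ...]
    mean_metrics: MetricResult
    pooled_metrics: MetricResult
    mean_tau: float


def _bounds(label) -> tuple[int, int]:
    if isinstance(label, LabeledStride):
        return label.start, label.end
    start, end = label
    return int(start), int(end)


def compute_metrics(counts: EvalCounts) -> MetricResult:
    """Precision, recall and F-measure from TP/FP/FN counts.

    precision = tp / (tp + fp); recall = tp / (tp + fn);
    F = 2 p r / (p + r).  Degenerate cases are total by convention:
    an empty detection set against an empty label set scores 1.0 on
    all three; otherwise a zero denominator yields 0.
    """
    if counts.tp == 0 and counts.fp == 0 and counts.fn == 0:
        return MetricResult(1.0, 1.0, 1.0)
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    if precision == recall:  # harmonic mean of equals, exactly
        f = precision
    elif precision + recall:
        f = 2 * precision * recall / (precision + recall)
    else:
        f = 0.0
    return MetricResult(precision, recall, f)


def match_strides(
    detected: Sequence[StrideSegment],
    labeled: Sequence,
    fs: float,
    tol_ms: float = DEFAULT_TOLERANCE_MS,
) -> EvalCounts:
    """Match detected segments to labeled strides within a border tolerance.

    Greedy one-to-one matching in start order: a detection matches the
    first unmatched label whose start AND end are each within
    ``tol_ms`` of the detection's borders.  Matches are true positives,
    unmatched detections false positives, unmatched labels false
    negatives.
    """
    tol_samples = tol_ms * fs / 1000.0
    labels = sorted((_bounds(l) for l in labeled), key=lambda b: b)
    dets = sorted(detected, key=lambda s: (s.start, s.end))
    matched = [False] * len(labels)
    tp = 0
    for det in dets:
        for i, (ls, le) in enumerate(labels):
            if matched[i]:
                continue
            if abs(det.start - ls) <= tol_samples and abs(det.end - le) <= tol_samples:
                matched[i] = True
                tp += 1
                break
    return EvalCounts(tp=tp, fp=len(dets) - tp, fn=matched.count(False))


def match_peaks(peaks: Sequence[int], labeled: Sequence) -> EvalCounts:
    """Match baseline peaks to labeled strides.

    A label absorbs at most one peak lying inside its inclusive
    [start, end] interval (the first such unused peak).  Surplus peaks
    inside a label and peaks inside no label are false positives;
    labels absorbing no peak are false negatives.
    """
    labels = sorted((_bounds(l) for l in labeled), key=lambda b: b)
    peaks = sorted(int(p) for p in peaks)
    used = [False] * len(peaks)
    tp = 0
    for ls, le in labels:
        for i, p in enumerate(peaks):
            if used[i] or not (ls <= p <= le):
                continue
            used[i] = True
            tp += 1
            break
    return EvalCounts(tp=tp, fp=used.count(False), fn=len(labels) - tp)


def _segments_per_tau(
    sequence: MultiAxisSignal,
    template: StrideTemplate,
    axes: Sequence[str],
    taus: Sequence[float],
    seg_kwargs: Mapping | None = None,
) -> list[tuple[list[StrideSegment], int]]:
    """Segment one sequence at every tau, computing the cost matrix once.

    The accumulated cost matrix and the candidate minima do not depend
    on tau, so they are computed a single time; each tau then filters
    the candidate set and re-applies the constraints.  Returns, per
    tau, the kept segments and the number of candidate endpoints.
    """
    seg_kwargs = dict(seg_kwargs or {})
    taus = [float(t) for t in taus]
    C, delta = compute_distance_function(sequence, template, axes)
    all_endpoints = find_endpoints(delta, max(taus))
    paths = {e: backtrack(C, e) for e in all_endpoints}
    out = []
    for tau in taus:
        config = SegmentationConfig(tau=tau, axes=tuple(axes), **seg_kwargs)
        cands = [(paths[e], float(delta[e])) for e in all_endpoints if delta[e] < tau]
        out.append((apply_constraints(cands, sequence.fs, config), len(cands)))
    return out


def threshold_sweep(
    datasets: Sequence[tuple[MultiAxisSignal, Sequence]],
    template: StrideTemplate,
    axes: str | Sequence[str] = ("GY", "GZ"),
    taus: Sequence[float] = DEFAULT_TAU_GRID,
    tol_ms: float = DEFAULT_TOLERANCE_MS,
    seg_kwargs: Mapping | None = None,
) -> SweepResult:
    """Evaluate segmentation over a grid of thresholds.

    For each tau, counts are pooled over all (sequence, labels)
    datasets; metrics are reported both from the pooled counts and as
    the mean of per-dataset metrics.  Taus must be strictly
    increasing.  Deterministic.
    """
    sel = parse_axes(axes)
    taus = [float(t) for t in taus]
    if any(b <= a for a, b in zip(taus, taus[1:])):
        raise ValueError("taus must be strictly increasing")
    per_ds = [
        (
            _segments_per_tau(seq, template, sel, taus, seg_kwargs),
            labels,
            seq.fs,
        )
        for seq, labels in datasets
    ]
    rows = []
    for k, tau in enumerate(taus):
        pooled = EvalCounts()
        per_metrics = []
        n_cand = 0
        for seg_list, labels, fs in per_ds:
            segments, n = seg_list[k]
            counts = match_strides(segments, labels, fs, tol_ms)
            pooled = pooled + counts
            per_metrics.append(compute_metrics(counts))
            n_cand += n
        mean_metrics = MetricResult(
            float(np.mean([m.precision for m in per_metrics])),
            float(np.mean([m.recall for m in per_metrics])),
            float(np.mean([m.f_measure for m in per_metrics])),
        )
        rows.append(
            SweepRow(tau, pooled, compute_metrics(pooled), mean_metrics, n_cand)
        )
    return SweepResult(axes=sel, rows=tuple(rows))


def loso_cv(
    subject_datasets: Mapping[str, tuple[MultiAxisSignal, Sequence]],
    template: StrideTemplate,
    axes: str | Sequence[str] = ("GY", "GZ"),
    taus: Sequence[float] = DEFAULT_TAU_GRID,
    tol_ms: float = DEFAULT_TOLERANCE_MS,
    seg_kwargs: Mapping | None = None,
) -> LosoResult:
    """Leave-one-subject-out cross-validation of the threshold tau.

    For every fold, the tau maximising the pooled F-measure over the
    training subjects (ties resolved toward the smallest tau) is
    applied to the held-out subject.  Reports per-fold metrics, their
    across-fold mean, pooled-counts metrics, and the mean chosen tau.
    """
    subjects = list(subject_datasets)
    if len(subjects) < 2:
        raise ValueError("LOSO cross-validation needs at least 2 subjects")
    sel = parse_axes(axes)
    taus = [float(t) for t in taus]

    counts_by_subject: dict[str, list[EvalCounts]] = {}
    for subject in subjects:
        seq, labels = subject_datasets[subject]
        per_tau = _segments_per_tau(seq, template, sel, taus, seg_kwargs)
        counts_by_subject[subject] = [
            match_strides(segments, labels, seq.fs, tol_ms)
            for segments, _ in per_tau
        ]

    folds = []
    pooled = EvalCounts()
    for held_out in subjects:
        train = [s for s in subjects if s != held_out]
        best_tau, best_f = None, -1.0
        for k, tau in enumerate(taus):
            agg = EvalCounts()
            for s in train:
                agg = agg + counts_by_subject[s][k]
            f = compute_metrics(agg).f_measure
            if f > best_f:  # strict: ties keep the smallest tau
                best_tau, best_f, best_k = tau, f, k
        counts = counts_by_subject[held_out][best_k]
        folds.append(
            FoldResult(held_out, best_tau, counts, compute_metrics(counts))
        )
        pooled = pooled + counts

    mean_metrics = MetricResult(
        float(np.mean([f.metrics.precision for f in folds])),
        float(np.mean([f.metrics.recall for f in folds])),
        float(np.mean([f.metrics.f_measure for f in folds])),
    )
    return LosoResult(
        folds=tuple(folds),
        mean_metrics=mean_metrics,
        pooled_metrics=compute_metrics(pooled),
        mean_tau=float(np.mean([f.tau for f in folds])),
    )
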