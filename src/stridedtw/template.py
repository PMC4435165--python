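"""Stride template construction.

A stride template is the sample-wise mean of many manually labeled
strides, each first linearly resampled to a common length (200 samples
by default), built per sensor axis.  The template is the reference
pattern that the subsequence-DTW stage warps onto a continuous
movement sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .signal_core import (
    AXES,
    MultiAxisSignal,
    NormalizationError,
    SensorRanges,
    parse_axes,
    resample_linear,
)

DEFAULT_TEMPLATE_LEN = 200


@dataclass(frozen=True)
class LabeledStride:
    """A manually labeled stride: inclusive [start, end] sample indices
    into a source recording.

    Stride borders follow the sagittal-plane gyroscope convention: the
    start is the negative GZ peak before the swing phase and the end is
    the negative peak closing the stance phase, so consecutive strides
    may share a border sample.
    """

    start: int
    end: int
    source: MultiAxisSignal

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end < len(self.source)):
            raise ValueError(
                f"invalid stride borders [{self.start}, {self.end}] for a "
                f"recording of {len(self.source)} samples"
            )

    @property
    def n_samples(self) -> int:
        return self.end - self.start + 1

    def trace(self, axis: str) -> np.ndarray:
        return self.source.axis(axis)[self.start : self.end + 1]


@dataclass
class StrideTemplate:
    """A fixed-length per-axis stride template.

    ``data`` holds one column per axis in ``axes``; rows run from stride
    start (row 0) to stride end (row M-1).
    """

    data: np.ndarray
    axes: tuple[str, ...]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.axes = parse_axes(self.axes)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.axes):
            raise ValueError(
                f"template data must have shape (M, {len(self.axes)}), "
                f"got {self.data.shape}"
            )
        if self.data.shape[0] < 2:
            raise ValueError("template must have at least 2 samples")

    def __len__(self) -> int:
        return self.data.shape[0]

    def axis(self, name: str) -> np.ndarray:
        if name not in self.axes:
            raise ValueError(f"axis {name!r} not in template axes {self.axes}")
        return self.data[:, self.axes.index(name)]

    def select(self, axes: str | Sequence[str]) -> "StrideTemplate":
        """Restrict the template to a subset of its axes."""
        sel = parse_axes(axes)
        missing = [a for a in sel if a not in self.axes]
        if missing:
            raise ValueError(f"axis {missing[0]!r} not in template axes {self.axes}")
        idx = [self.axes.index(a) for a in sel]
        return StrideTemplate(self.data[:, idx], axes=sel, normalized=self.normalized)


def build_template(
    strides: Sequence[LabeledStride],
    axes: str | Sequence[str] = AXES,
    target_len: int = DEFAULT_TEMPLATE_LEN,
) -> StrideTemplate:
    """Average labeled strides into a template.

    Each stride's trace on each requested axis is linearly resampled to
    ``target_len`` samples, then all strides are averaged sample by
    sample with equal weight.  The result is unnormalized; apply
    :func:`normalize_template` before msDTW.
    """
    if len(strides) == 0:
        raise ValueError("cannot build a template from an empty stride list")
    sel = parse_axes(axes)
    stacked = np.empty((len(strides), target_len, len(sel)))
    for i, stride in enumerate(strides):
        for j, axis in enumerate(sel):
            stacked[i, :, j] = resample_linear(stride.trace(axis), target_len)
    # summing in sorted order makes the mean exactly permutation-invariant
    stacked.sort(axis=0)
    return StrideTemplate(stacked.mean(axis=0), axes=sel, normalized=False)


def normalize_template(
    template: StrideTemplate, ranges: SensorRanges | None = None
) -> StrideTemplate:
    """Divide each template axis by its sensor range constant.

    Pure division, no clipping; see :func:`~stridedtw.signal_core.normalize_signal`.
    """
    if template.normalized:
        raise NormalizationError("template is already normalized")
    ranges = ranges or SensorRanges()
    divisors = np.array([ranges.for_axis(a) for a in template.axes])
    return StrideTemplate(template.data / divisors, axes=template.axes, normalized=True)
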