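"""Core data model for multi-axis inertial signals.

A foot-worn inertial measurement unit records six channels: tri-axial
acceleration (AX anterior-posterior, AY inferior-superior, AZ
lateral-medial, in g) and tri-axial angular velocity (GX coronal,
GY transverse, GZ sagittal plane, in °/s).  This module provides the
in-memory container for such recordings plus the three elementary
signal operations every later stage builds on: sensor-range
normalization, per-axis sign harmonization (so left- and right-foot
sensors share one orientation convention), and linear resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Canonical axis order used everywhere in the package.
AXES: tuple[str, ...] = ("AX", "AY", "AZ", "GX", "GY", "GZ")

ACCEL_AXES: tuple[str, ...] = ("AX", "AY", "AZ")
GYRO_AXES: tuple[str, ...] = ("GX", "GY", "GZ")

#: Default sampling rate of the shoe-mounted sensor unit, Hz.
DEFAULT_FS: float = 102.4


class NormalizationError(ValueError):
    """Raised when a signal or template is normalized twice."""


def parse_axes(spec: str | Sequence[str]) -> tuple[str, ...]:
    """Parse an axis selection.

    Accepts a sequence of axis names, a comma-separated list
    (``"GY,GZ"``) or the concatenated form used in the gait literature
    (``"AXAYAZGYGZ"``).  Returns an ordered, duplicate-free tuple.

    Raises
    ------
    ValueError
        On unknown tokens, duplicates, or an empty selection.
    """
    if isinstance(spec, str):
        text = spec.strip().upper()
        if "," in text:
            tokens = [t.strip() for t in text.split(",") if t.strip()]
        else:
            if len(text) % 2 != 0:
                raise ValueError(f"cannot parse axis selection {spec!r}")
            tokens = [text[i : i + 2] for i in range(0, len(text), 2)]
    else:
        tokens = [str(t).upper() for t in spec]
    if not tokens:
        raise ValueError("axis selection is empty")
    for t in tokens:
        if t not in AXES:
            raise ValueError(f"unknown axis {t!r}; expected one of {AXES}")
    if len(set(tokens)) != len(tokens):
        raise ValueError(f"duplicate axis in selection {tokens}")
    return tuple(tokens)


@dataclass(frozen=True)
class SensorRanges:
    """Nominal full-scale ranges of the sensor unit.

    The recording hardware measures ±6 g and ±500 °/s; dividing each
    channel by its positive range puts accelerometer and gyroscope data
    on a common dimensionless [-1, 1] scale so their distances can be
    summed.
    """

    accel_range: float = 6.0  # g
    gyro_range: float = 500.0  # °/s

    def __post_init__(self) -> None:
        if self.accel_range <= 0 or self.gyro_range <= 0:
            raise ValueError("sensor ranges must be strictly positive")

    def for_axis(self, axis: str) -> float:
        if axis in ACCEL_AXES:
            return self.accel_range
        if axis in GYRO_AXES:
            return self.gyro_range
        raise ValueError(f"unknown axis {axis!r}")


@dataclass
class MultiAxisSignal:
    """A time-ordered 6-axis inertial recording.

    Parameters
    ----------
    data : ndarray, shape (N, 6)
        Samples in canonical axis order ``AXES``.  Accelerometer columns
        in g, gyroscope columns in °/s (or dimensionless once
        ``normalized`` is set).
    fs : float
        Sampling rate in Hz.
    normalized : bool
        True once every channel has been divided by its sensor range.
    """

    data: np.ndarray
    fs: float = DEFAULT_FS
    normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(AXES):
            raise ValueError(
                f"data must have shape (N, {len(AXES)}), got {self.data.shape}"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def axis(self, name: str) -> np.ndarray:
        """Return one axis trace as a 1-D view."""
        return self.data[:, AXES.index(name)]

    def select(self, axes: str | Sequence[str]) -> np.ndarray:
        """Return an (N, k) array of the selected axes, in request order."""
        sel = parse_axes(axes)
        idx = [AXES.index(a) for a in sel]
        return self.data[:, idx]

    def copy(self) -> "MultiAxisSignal":
        return MultiAxisSignal(self.data.copy(), fs=self.fs, normalized=self.normalized)

    @classmethod
    def from_dataframe(cls, df, fs: float, normalized: bool = False) -> "MultiAxisSignal":
        missing = [a for a in AXES if a not in df.columns]
        if missing:
            raise ValueError(f"missing axis column(s): {', '.join(missing)}")
        return cls(df[list(AXES)].to_numpy(dtype=float), fs=fs, normalized=normalized)

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.data, columns=list(AXES))
        df.insert(0, "time_s", np.arange(self.n_samples) / self.fs)
        return df


def normalize_signal(
    signal: MultiAxisSignal, ranges: SensorRanges | None = None
) -> MultiAxisSignal:
    """Scale each channel by its positive sensor range.

    Accelerometer channels are divided by ``accel_range`` (6 g) and
    gyroscope channels by ``gyro_range`` (500 °/s).  This is a pure
    division: samples exceeding the nominal range keep magnitudes above
    one, which preserves information from saturated samples.

    Raises
    ------
    NormalizationError
        If the signal is already normalized.
    """
    if signal.normalized:
        raise NormalizationError("signal is already normalized")
    ranges = ranges or SensorRanges()
    divisors = np.array([ranges.for_axis(a) for a in AXES])
    return MultiAxisSignal(signal.data / divisors, fs=signal.fs, normalized=True)


def invert_axes(
    signal: MultiAxisSignal, sign_map: Mapping[str, int]
) -> MultiAxisSignal:
    """Flip the sign of selected axes.

    Left- and right-foot sensors are mirror images of each other; a
    per-axis sign map (values in {+1, -1}; omitted axes default to +1)
    brings both feet to one orientation convention.  Applying the same
    map twice is the identity.
    """
    signs = np.ones(len(AXES))
    for axis, sign in sign_map.items():
        if axis not in AXES:
            raise ValueError(f"unknown axis {axis!r}")
        if sign not in (1, -1):
            raise ValueError(f"sign for {axis} must be +1 or -1, got {sign}")
        signs[AXES.index(axis)] = sign
    return MultiAxisSignal(
        signal.data * signs, fs=signal.fs, normalized=signal.normalized
    )


def resample_linear(trace: np.ndarray, target_len: int) -> np.ndarray:
    """Linearly resample a 1-D trace to ``target_len`` samples.

    The input index span [0, L-1] is mapped uniformly onto
    [0, target_len-1] (endpoint inclusive), so the first and last values
    are preserved exactly.  Matches MATLAB ``interp1``-style piecewise
    linear interpolation on a uniform grid.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1:
        raise ValueError("trace must be 1-D")
    if trace.size < 2:
        raise ValueError("trace must contain at least 2 samples")
    if target_len < 2:
        raise ValueError("target_len must be at least 2")
    src = np.arange(trace.size, dtype=float)
    dst = np.linspace(0.0, trace.size - 1.0, target_len)
    return np.interp(dst, src, trace)
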