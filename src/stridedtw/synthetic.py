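"""Synthetic 6-axis gait signals with exact ground-truth stride labels.

The generator emulates the morphology of straight-walking strides seen
in shoe-mounted inertial recordings: the sagittal gyroscope trace (GZ)
shows a dominant positive swing-phase peak flanked by two negative
border troughs (which define the stride start and end), the transverse
and coronal gyroscope axes carry smaller correlated oscillations, and
the accelerometer axes carry smooth push-off/landing transients.  All
waveforms are sums of Gaussian and sinusoidal lobes with hand-set
positions — analytic, linearly scalable and owing nothing to any real
recording.

Besides stride runs, the generator produces non-gait confounder
blocks:

* ``stairs`` — periodic single-lobe GZ bursts exceeding the swing-peak
  amplitude gate of peak-detection baselines, but lacking the negative
  border troughs, so they are dissimilar in shape to a stride;
* ``turning`` — sustained high-amplitude transverse-plane (GY)
  rotation with subdued GZ, as in a direction change;
* ``rest`` — standing still (all axes zero before noise).

Everything is driven by a single seeded random stream with a fixed
draw order, so a given spec reproduces bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .signal_core import AXES, DEFAULT_FS, MultiAxisSignal, SensorRanges
from .template import DEFAULT_TEMPLATE_LEN, LabeledStride, StrideTemplate
from .signal_core import resample_linear

MIN_STRIDE_MS = 250.0
MAX_STRIDE_MS = 2000.0


def _gauss(phase: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-(((phase - center) / width) ** 2))


def _n_samples(duration_ms: float, fs: float) -> int:
    return int(round(duration_ms * fs / 1000.0))


def canonical_stride(
    duration_ms: float, fs: float = DEFAULT_FS, amplitude: float = 1.0
) -> np.ndarray:
    """One synthetic stride as an (n, 6) array in raw units (g, °/s).

    The waveform is a fixed shape evaluated on ``round(duration_ms *
    fs / 1000)`` uniformly spaced phase points, so strides of different
    durations are pure time-scalings of one another.  ``amplitude``
    scales every channel linearly.  GZ starts and ends in its negative
    border troughs, peaking mid-swing at 450 °/s (for amplitude 1).
    """
    if not (MIN_STRIDE_MS < duration_ms < MAX_STRIDE_MS):
        raise ValueError(
            f"stride duration {duration_ms} ms outside ({MIN_STRIDE_MS}, "
            f"{MAX_STRIDE_MS}) ms"
        )
    n = _n_samples(duration_ms, fs)
    phase = np.linspace(0.0, 1.0, n)
    out = np.zeros((n, len(AXES)))

    gz = (
        450.0 * _gauss(phase, 0.55, 0.10)
        - 200.0 * _gauss(phase, 0.0, 0.06)
        - 200.0 * _gauss(phase, 1.0, 0.06)
        - 60.0 * _gauss(phase, 0.25, 0.15)
    )
    gx = 80.0 * np.sin(2 * np.pi * phase) * _gauss(phase, 0.5, 0.35)
    gy = 45.0 * np.sin(2 * np.pi * phase) * _gauss(phase, 0.55, 0.3)
    ax = (
        1.0 * _gauss(phase, 0.6, 0.08)
        - 0.8 * _gauss(phase, 0.05, 0.08)
        - 0.8 * _gauss(phase, 0.95, 0.08)
    )
    ay = 1.2 * _gauss(phase, 0.5, 0.12) - 0.5 * _gauss(phase, 0.1, 0.1)
    az = 0.5 * np.sin(2 * np.pi * phase) * _gauss(phase, 0.5, 0.3)

    for name, trace in zip(AXES, (ax, ay, az, gx, gy, gz)):
        out[:, AXES.index(name)] = amplitude * trace
    return out


def canonical_template(
    fs: float = DEFAULT_FS,
    duration_ms: float = 1000.0,
    target_len: int = DEFAULT_TEMPLATE_LEN,
) -> StrideTemplate:
    """The canonical stride shape resampled to a template.

    Equivalent to averaging a single noise-free canonical stride;
    returned unnormalized, like a template built from raw strides.
    """
    stride = canonical_stride(duration_ms, fs, amplitude=1.0)
    data = np.column_stack(
        [resample_linear(stride[:, j], target_len) for j in range(stride.shape[1])]
    )
    return StrideTemplate(data, axes=AXES, normalized=False)


def stairs_block(
    duration_ms: float,
    fs: float = DEFAULT_FS,
    peak_amplitude: float = 200.0,
    period_ms: float = 900.0,
) -> np.ndarray:
    """Stair-climbing-like periodic motion as an (n, 6) raw-unit array.

    GZ carries one positive single-lobe burst per period — no negative
    border troughs — so the block is periodic and fast enough to fool
    an amplitude-gated peak detector whenever ``peak_amplitude``
    exceeds its gate, while remaining dissimilar in shape to a stride
    template.
    """
    n = _n_samples(duration_ms, fs)
    t_ms = np.arange(n) * 1000.0 / fs
    phase = (t_ms % period_ms) / period_ms
    gz = peak_amplitude * _gauss(phase, 0.5, 0.12)
    out = np.zeros((n, len(AXES)))
    out[:, AXES.index("GZ")] = gz
    out[:, AXES.index("GY")] = 0.25 * peak_amplitude * _gauss(phase, 0.45, 0.2)
    out[:, AXES.index("AY")] = 0.4 * _gauss(phase, 0.55, 0.15)
    out[:, AXES.index("AX")] = 0.25 * np.sin(2 * np.pi * phase)
    return out


def turning_block(
    duration_ms: float, fs: float = DEFAULT_FS, gy_amplitude: float = 250.0
) -> np.ndarray:
    """Turning-like motion: sustained high transverse-plane rotation."""
    n = _n_samples(duration_ms, fs)
    phase = np.linspace(0.0, 1.0, n) if n > 1 else np.zeros(n)
    out = np.zeros((n, len(AXES)))
    out[:, AXES.index("GY")] = gy_amplitude * _gauss(phase, 0.5, 0.3)
    out[:, AXES.index("GZ")] = 60.0 * np.sin(3 * np.pi * phase) * _gauss(phase, 0.5, 0.35)
    out[:, AXES.index("AZ")] = 0.3 * np.sin(2 * np.pi * phase)
    return out


def rest_block(duration_ms: float, fs: float = DEFAULT_FS) -> np.ndarray:
    """Standing still."""
    return np.zeros((_n_samples(duration_ms, fs), len(AXES)))


_CONFOUNDER_BUILDERS = {
    "stairs": stairs_block,
    "turning": turning_block,
    "rest": rest_block,
}


@dataclass(frozen=True)
class ConfounderBlock:
    """A non-gait block: kind in {'stairs', 'turning', 'rest'}."""

    kind: str
    duration_ms: float
    amplitude: float | None = None  # stairs GZ / turning GY peak, °/s

    def __post_init__(self) -> None:
        if self.kind not in _CONFOUNDER_BUILDERS:
            raise ValueError(
                f"unknown confounder kind {self.kind!r}; "
                f"expected one of {sorted(_CONFOUNDER_BUILDERS)}"
            )
        if self.duration_ms < 0:
            raise ValueError("confounder duration must be non-negative")

    def render(self, fs: float) -> np.ndarray:
        builder = _CONFOUNDER_BUILDERS[self.kind]
        if self.kind == "stairs" and self.amplitude is not None:
            return builder(self.duration_ms, fs, peak_amplitude=self.amplitude)
        if self.kind == "turning" and self.amplitude is not None:
            return builder(self.duration_ms, fs, gy_amplitude=self.amplitude)
        return builder(self.duration_ms, fs)


@dataclass(frozen=True)
class WalkSpec:
    """Recipe for a synthetic walk.

    Stride durations are drawn from a normal distribution
    (mean 1000 ms, SD 100 ms by default) truncated to mean ± 3 SD so
    every true stride satisfies the (250, 2000) ms plausibility window;
    per-stride amplitudes are jittered multiplicatively.  ``noise_sd``
    is white-noise SD expressed in normalized units (fractions of the
    sensor range) and is applied to every channel.  Confounder blocks
    are rendered before the stride run, each padded by a short rest.
    """

    n_strides: int = 10
    fs: float = DEFAULT_FS
    stride_time_mean_ms: float = 1000.0
    stride_time_sd_ms: float = 100.0
    amplitude_jitter: float = 0.05
    noise_sd: float = 0.01
    confounders: tuple[ConfounderBlock, ...] = ()
    lead_ms: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strides < 0:
            raise ValueError("n_strides must be non-negative")
        if self.noise_sd < 0 or self.amplitude_jitter < 0:
            raise ValueError("noise_sd and amplitude_jitter must be non-negative")
        lo = self.stride_time_mean_ms - 3 * self.stride_time_sd_ms
        hi = self.stride_time_mean_ms + 3 * self.stride_time_sd_ms
        if lo <= MIN_STRIDE_MS or hi >= MAX_STRIDE_MS:
            raise ValueError(
                "stride_time mean ± 3 SD must stay inside the "
                f"({MIN_STRIDE_MS}, {MAX_STRIDE_MS}) ms stride window"
            )


def generate_walk(spec: WalkSpec) -> tuple[MultiAxisSignal, list[LabeledStride]]:
    """Render a walk: confounders, then a run of jittered strides.

    Draw order per stride is fixed (duration, then amplitude), all
    from one ``numpy.random.default_rng(seed)`` stream, followed by a
    single noise draw for the assembled signal; identical specs
    therefore produce bit-identical output.  Returns the raw-unit
    signal and exact stride border labels (confounders are unlabeled).
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs
    blocks: list[np.ndarray] = [rest_block(spec.lead_ms, fs)]
    for conf in spec.confounders:
        blocks.append(conf.render(fs))
        blocks.append(rest_block(spec.lead_ms, fs))

    lo = spec.stride_time_mean_ms - 3 * spec.stride_time_sd_ms
    hi = spec.stride_time_mean_ms + 3 * spec.stride_time_sd_ms
    stride_bounds: list[tuple[int, int]] = []
    offset = sum(b.shape[0] for b in blocks)
    for _ in range(spec.n_strides):
        duration = float(np.clip(rng.normal(spec.stride_time_mean_ms, spec.stride_time_sd_ms), lo, hi))
        amplitude = float(max(0.1, rng.normal(1.0, spec.amplitude_jitter)))
        stride = canonical_stride(duration, fs, amplitude)
        blocks.append(stride)
        stride_bounds.append((offset, offset + stride.shape[0] - 1))
        offset += stride.shape[0]
    blocks.append(rest_block(spec.lead_ms, fs))

    data = np.vstack(blocks) if blocks else np.zeros((0, len(AXES)))
    if spec.noise_sd > 0 and data.shape[0]:
        ranges = SensorRanges()
        scale = np.array([ranges.for_axis(a) for a in AXES])
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape) * scale

    signal = MultiAxisSignal(data, fs=fs, normalized=False)
    labels = [LabeledStride(s, e, signal) for s, e in stride_bounds]
    return signal, labels
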