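"""Peak-detection baseline for stride recognition.

The classical comparison method: each stride is marked by the dominant
positive swing-phase peak in the sagittal-plane gyroscope trace (GZ).
A peak counts as a stride when its angular velocity exceeds an
amplitude gate (150 °/s for shoe-mounted sensors) and it is separated
from other accepted peaks by a refractory window (250 ms); among
maxima closer together than the window, only the highest survives.
Unlike msDTW this yields one point per stride, not stride borders, and
any sufficiently fast periodic movement (stair climbing, for instance)
can fire it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PeakDetectionConfig:
    min_amplitude: float = 150.0  # °/s, on the raw gyroscope scale
    min_separation_ms: float = 250.0

    def __post_init__(self) -> None:
        if self.min_amplitude <= 0 or self.min_separation_ms <= 0:
            raise ValueError("peak detection parameters must be positive")


def detect_swing_peaks(
    gz: np.ndarray, fs: float, config: PeakDetectionConfig | None = None
) -> list[int]:
    """Detect swing-phase peaks in a raw GZ trace (°/s).

    Simple 3-point local maxima above ``min_amplitude`` are collected,
    then thinned greedily by descending amplitude: the globally highest
    remaining maximum is kept and every other maximum within
    ``min_separation_ms`` of it is discarded, repeating until none
    remain.  Amplitude ties are broken toward the earlier index.
    Returns strictly increasing sample indices.
    """
    config = config or PeakDetectionConfig()
    gz = np.asarray(gz, dtype=float)
    if gz.size < 3:
        return []
    interior = np.arange(1, gz.size - 1)
    is_max = (gz[interior] > gz[interior - 1]) & (gz[interior] > gz[interior + 1])
    candidates = interior[is_max & (gz[interior] > config.min_amplitude)]
    if candidates.size == 0:
        return []

    min_sep = config.min_separation_ms * fs / 1000.0
    # greedy suppression, highest amplitude first (earlier index on ties)
    order = sorted(candidates, key=lambda i: (-gz[i], i))
    kept: list[int] = []
    for idx in order:
        if all(abs(idx - k) >= min_sep for k in kept):
            kept.append(int(idx))
    kept.sort()
    return kept
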