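"""File formats: sensor CSV, label files, templates, segments, peaks.

All formats are delimited text.  Sample indices in files are 0-based
and inclusive, matching the in-memory convention; seconds columns are
derived from the sampling rate.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .msdtw import StrideSegment
from .signal_core import AXES, DEFAULT_FS, MultiAxisSignal, parse_axes
from .template import StrideTemplate

logger = logging.getLogger(__name__)

#: Written floats survive a round trip bit-exactly at this precision.
_FLOAT_FMT = "%.17g"

SENSOR_COLUMNS = ("time_s",) + AXES


class SensorFileError(ValueError):
    """Malformed sensor file."""


def write_sensor_csv(signal: MultiAxisSignal, path: str | Path) -> None:
    signal.to_dataframe().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_sensor_csv(
    path: str | Path, fs: float | None = None, uniformity_tol: float = 0.01
) -> MultiAxisSignal:
    """Read a sensor CSV (columns ``time_s,AX,AY,AZ,GX,GY,GZ``).

    The sampling rate is inferred from the time column unless ``fs``
    is given; a missing/short time column falls back to the default
    102.4 Hz with a logged warning.  Raises :class:`SensorFileError`
    with a distinct message for a missing column, non-monotone time,
    or sampling non-uniform beyond ``uniformity_tol`` (fraction of the
    median interval).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in AXES if c not in df.columns]
    if missing:
        raise SensorFileError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    if len(df) == 0:
        return MultiAxisSignal(np.zeros((0, len(AXES))), fs=fs or DEFAULT_FS)

    if "time_s" in df.columns and len(df) >= 2:
        dt = np.diff(df["time_s"].to_numpy(dtype=float))
        if np.any(dt <= 0):
            raise SensorFileError(f"{path}: time_s column is not strictly increasing")
        med = float(np.median(dt))
        if np.max(np.abs(dt - med)) > uniformity_tol * med:
            raise SensorFileError(
                f"{path}: non-uniform sampling (interval deviates more than "
                f"{uniformity_tol:.0%} from the median {med:.6g} s)"
            )
        inferred = 1.0 / med
        if fs is None:
            fs = inferred
    elif fs is None:
        fs = DEFAULT_FS
        logger.warning(
            "%s: no usable time_s column; assuming default fs = %g Hz", path, fs
        )
    return MultiAxisSignal.from_dataframe(df, fs=fs)


def write_labels(labels: Sequence, path: str | Path) -> None:
    """Write stride labels as ``start_sample,end_sample`` rows."""
    rows = []
    for lab in labels:
        if hasattr(lab, "start"):
            rows.append((int(lab.start), int(lab.end)))
        else:
            rows.append((int(lab[0]), int(lab[1])))
    rows.sort()
    pd.DataFrame(rows, columns=["start_sample", "end_sample"]).to_csv(
        path, index=False
    )


def read_labels(path: str | Path) -> list[tuple[int, int]]:
    df = pd.read_csv(path)
    for col in ("start_sample", "end_sample"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing label column {col!r}")
    rows = [(int(s), int(e)) for s, e in zip(df["start_sample"], df["end_sample"])]
    for s, e in rows:
        if s >= e:
            raise ValueError(f"{path}: label start {s} must precede end {e}")
    if rows != sorted(rows):
        raise ValueError(f"{path}: labels must be sorted by start_sample")
    return rows


def write_template(
    template: StrideTemplate,
    path: str | Path,
    extra_meta: Mapping[str, object] | None = None,
) -> None:
    """Write a template CSV (one row per sample, one column per axis)
    plus a ``<path>.meta`` side-car with its parameters."""
    path = Path(path)
    pd.DataFrame(template.data, columns=list(template.axes)).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )
    meta: dict[str, object] = {
        "length": len(template),
        "axes": ",".join(template.axes),
        "normalized": template.normalized,
    }
    meta.update(extra_meta or {})
    lines = [f"{k}={json.dumps(v) if not isinstance(v, str) else v}" for k, v in meta.items()]
    Path(str(path) + ".meta").write_text("\n".join(lines) + "\n")


def read_template(path: str | Path) -> StrideTemplate:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    axes = parse_axes(list(df.columns))
    normalized = False
    meta_path = Path(str(path) + ".meta")
    if meta_path.exists():
        meta = read_config(meta_path)
        normalized = str(meta.get("normalized", "false")).lower() == "true"
    return StrideTemplate(df.to_numpy(dtype=float), axes=axes, normalized=normalized)


def write_segments(
    segments: Sequence[StrideSegment], fs: float, path: str | Path
) -> None:
    """Segment table: start_sample, end_sample, start_s, end_s, cost;
    ordered by start_sample."""
    rows = sorted(segments, key=lambda s: (s.start, s.end))
    df = pd.DataFrame(
        {
            "start_sample": [s.start for s in rows],
            "end_sample": [s.end for s in rows],
            "start_s": [s.start / fs for s in rows],
            "end_s": [s.end / fs for s in rows],
            "cost": [s.cost for s in rows],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_segments(path: str | Path) -> list[StrideSegment]:
    df = pd.read_csv(path)
    return [
        StrideSegment(int(r.start_sample), int(r.end_sample), float(r.cost))
        for r in df.itertuples()
    ]


def write_peaks(peaks: Sequence[int], fs: float, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_index": [int(p) for p in peaks], "time_s": [p / fs for p in peaks]}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_peaks(path: str | Path) -> list[int]:
    df = pd.read_csv(path)
    return [int(p) for p in df["sample_index"]]


def write_config(values: Mapping[str, object], path: str | Path) -> None:
    """Flat ``key=value`` configuration text."""
    lines = [f"{k}={v}" for k, v in values.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}: malformed config line {line!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out
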