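"""Cohort-style result tables.

Three tabular report shapes mirror how stride-segmentation studies
publish their results, so that a cohort dataset — once available — can
be evaluated without new plumbing:

* an axis-combination grid — subject groups in rows, axis
  combinations in columns, mean cross-validated F-measure in cells;
* a detailed results table — per group and protocol: mean chosen
  threshold, precision, recall and F-measure of the msDTW method;
* a peak-baseline table — per group and protocol: precision, recall
  and F-measure of the peak-detection baseline.

All builders return plain :class:`pandas.DataFrame` objects;
:func:`write_report` persists them as tab-separated text.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .evaluation import EvalCounts, LosoResult, compute_metrics


def axis_combination_report(
    results: Mapping[str, Mapping[str, LosoResult]]
) -> pd.DataFrame:
    """Grid of mean cross-validated F-measures.

    ``results`` maps group name -> axis-combination token (for example
    ``"GYGZ"``) -> LOSO result; cells hold the across-fold mean
    F-measure.
    """
    groups = list(results)
    combos: list[str] = []
    for per_group in results.values():
        for token in per_group:
            if token not in combos:
                combos.append(token)
    table = pd.DataFrame(index=groups, columns=combos, dtype=float)
    for group, per_group in results.items():
        for token, res in per_group.items():
            table.loc[group, token] = res.mean_metrics.f_measure
    table.index.name = "group"
    return table


def detailed_report(
    results: Mapping[tuple[str, str, str], LosoResult]
) -> pd.DataFrame:
    """Detailed msDTW results table.

    ``results`` maps (group, protocol, axes token) -> LOSO result.
    Rows carry the mean chosen threshold and the across-fold mean
    precision, recall and F-measure.
    """
    rows = []
    for (group, protocol, axes), res in results.items():
        rows.append(
            {
                "group": group,
                "protocol": protocol,
                "axes": axes,
                "threshold": res.mean_tau,
                "precision": res.mean_metrics.precision,
                "recall": res.mean_metrics.recall,
                "f_measure": res.mean_metrics.f_measure,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group",
            "protocol",
            "axes",
            "threshold",
            "precision",
            "recall",
            "f_measure",
        ],
    )


def peak_baseline_report(
    counts: Mapping[tuple[str, str], EvalCounts]
) -> pd.DataFrame:
    """Peak-detection baseline table: (group, protocol) -> pooled counts."""
    rows = []
    for (group, protocol), c in counts.items():
        m = compute_metrics(c)
        rows.append(
            {
                "group": group,
                "protocol": protocol,
                "tp": c.tp,
                "fp": c.fp,
                "fn": c.fn,
                "precision": m.precision,
                "recall": m.recall,
                "f_measure": m.f_measure,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["group", "protocol", "tp", "fp", "fn", "precision", "recall", "f_measure"],
    )


def write_report(table: pd.DataFrame, path: str | Path) -> None:
    """Persist a report as tab-separated text."""
    table.to_csv(path, sep="\t", index=table.index.name is not None)
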