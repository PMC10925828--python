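"""Reading and writing long-format count tables.

The pipeline's interchange format is a long CSV with one row per
(well, day, line) count:

    experiment,condition,ratio_label,replicate,day,line,count

``condition`` is one of ``monoculture``, ``coculture``,
``transwell_mono``, ``transwell_co``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import GrowthCurve

__all__ = ["REQUIRED_COLUMNS", "curves_to_frame", "frame_to_curves",
           "save_counts", "load_counts"]

REQUIRED_COLUMNS = ("experiment", "condition", "ratio_label", "replicate",
                    "day", "line", "count")


def curves_to_frame(curves: list[GrowthCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for day, count in zip(c.days, c.counts):
            rows.append((c.experiment, c.condition, c.ratio_label,
                         c.replicate, float(day), c.line, float(count)))
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def frame_to_curves(df: pd.DataFrame) -> list[GrowthCurve]:
    """Validate a long table and group it into typed growth curves."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    df = df.copy()
    for col in ("day", "count"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    neg = df.index[df["count"] < 0]
    if len(neg):
        row = df.loc[neg[0]]
        raise ValueError(
            f"negative count at row {neg[0]} "
            f"({row['line']} {row['condition']} {row['ratio_label']} "
            f"{row['replicate']} day {row['day']}: {row['count']})"
        )
    keys = ["experiment", "condition", "ratio_label", "replicate", "line"]
    dup = df.duplicated(subset=keys + ["day"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate (replicate, day, line) row: {tuple(row[k] for k in keys)} "
            f"day {row['day']}"
        )
    curves = []
    for key, grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("day")
        exp, condition, ratio, rep, line = key
        curves.append(GrowthCurve(
            line=str(line), condition=str(condition), ratio_label=str(ratio),
            replicate=str(rep),
            days=grp["day"].to_numpy(dtype=float),
            counts=grp["count"].to_numpy(dtype=float),
            experiment=str(exp),
        ))
    return curves


def save_counts(curves: list[GrowthCurve], path) -> None:
    curves_to_frame(curves).to_csv(path, index=False)


def load_counts(path) -> list[GrowthCurve]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return frame_to_curves(pd.read_csv(path))
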