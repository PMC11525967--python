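"""Developmental time-courses of mRNA concentration on the nuclei-count axis.

The embryonic nuclei count serves as a developmental clock for fixed-sample
smFISH data: measurements from many embryos are ordered by increasing nuclei
count, then both the stage axis and the measured quantity are smoothed with a
centered running average of order 5 (configurable), with per-window SEM bands.
The division of the mother cell of interest (~180 nuclei for MSpaap) is kept
as a stage landmark annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimecourseConfig",
    "order_by_stage",
    "moving_average",
    "window_sem",
    "build_timecourse",
]


@dataclass(frozen=True)
class TimecourseConfig:
    """Smoothing settings: odd centered window and the stage landmark."""

    window_order: int = 5
    division_landmark: int = 180
    value_column: str = "concentration"

    def __post_init__(self) -> None:
        if self.window_order < 1 or self.window_order % 2 == 0:
            raise ValueError("window_order must be odd and ≥ 1")


def order_by_stage(points: pd.DataFrame) -> pd.DataFrame:
    """Stable ascending sort by embryonic nuclei count (ties keep input order)."""
    if "nuclei_count" not in points.columns:
        raise ValueError("points need a 'nuclei_count' column")
    return points.sort_values("nuclei_count", kind="stable").reset_index(drop=True)


def _windows(series: Sequence[float], order: int) -> np.ndarray:
    arr = np.asarray(series, dtype=float)
    if order < 1 or order % 2 == 0:
        raise ValueError("order must be odd and ≥ 1")
    if arr.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if len(arr) < order:
        raise ValueError(
            f"series of length {len(arr)} is shorter than the window order "
            f"{order}; use a smaller order"
        )
    return np.lib.stride_tricks.sliding_window_view(arr, order)


def moving_average(series: Sequence[float], order: int = 5) -> np.ndarray:
    """Centered running average; output length = len(series) − order + 1."""
    return _windows(series, order).mean(axis=1)


def window_sem(series: Sequence[float], order: int = 5) -> np.ndarray:
    """Per-window SEM: sample SD of each window divided by √order."""
    w = _windows(series, order)
    if order == 1:
        return np.zeros(len(w))
    return w.std(axis=1, ddof=1) / np.sqrt(order)


def build_timecourse(
    points: pd.DataFrame,
    config: TimecourseConfig | None = None,
) -> pd.DataFrame:
    """Smoothed time-course per cell and channel.

    ``points`` is the tidy per-embryo table (columns ``cell_name``,
    ``channel``, ``nuclei_count`` and the configured value column).  For each
    (cell, channel) series: order by stage, apply the centered running average
    to both the stage axis and the value, and attach the per-window SEM of the
    value.  Output columns: cell_name, channel, smoothed_stage,
    smoothed_value, sem, division_landmark.
    """
    config = config or TimecourseConfig()
    value_col = config.value_column
    for col in ("cell_name", "channel", "nuclei_count", value_col):
        if col not in points.columns:
            raise ValueError(f"points need a {col!r} column")
    out = []
    for (cell, channel), group in points.groupby(["cell_name", "channel"],
                                                 sort=False):
        g = order_by_stage(group)
        stage = moving_average(g["nuclei_count"].to_numpy(float),
                               config.window_order)
        value = moving_average(g[value_col].to_numpy(float),
                               config.window_order)
        sem = window_sem(g[value_col].to_numpy(float), config.window_order)
        out.append(pd.DataFrame({
            "cell_name": cell,
            "channel": channel,
            "smoothed_stage": stage,
            "smoothed_value": value,
            "sem": sem,
            "division_landmark": config.division_landmark,
        }))
    if not out:
        return pd.DataFrame(columns=[
            "cell_name", "channel", "smoothed_stage", "smoothed_value",
            "sem", "division_landmark",
        ])
    return pd.concat(out, ignore_index=True)
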