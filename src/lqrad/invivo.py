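"""Caliper-based tumor volumes and group growth summaries.

Flank xenograft volume from two-axis caliper readings uses the standard
ellipsoid approximation

    V = length * width^2 / 2        [mm^3, length >= width]

Inputs with width > length are swapped (with a warning) rather than
rejected: the two axes are easily transposed at the cage side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["tumor_volume", "TumorMeasurementLog", "growth_summaries", "GrowthSummary"]

CALIPER_COLUMNS = ("animal_id", "group", "day", "length_mm", "width_mm")


def tumor_volume(length, width):
    """Ellipsoid tumor volume (mm^3) = length * width^2 / 2; inputs in mm > 0."""
    L = np.asarray(length, dtype=float)
    W = np.asarray(width, dtype=float)
    if np.any(L <= 0) or np.any(W <= 0):
        raise ValueError("length and width must be positive")
    out = L * W * W / 2.0
    return float(out) if out.ndim == 0 else out


class TumorMeasurementLog:
    """A caliper time series with computed volumes.

    Wraps a long-format frame with columns ``animal_id, group, day,
    length_mm, width_mm`` plus a derived ``volume_mm3``. Rows where the
    recorded width exceeds the length are swapped with a warning so the
    convention width <= length always holds.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in CALIPER_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        frame = frame.copy()
        frame["day"] = frame["day"].astype(int)
        if np.any(frame["day"].to_numpy() < 0):
            raise ValueError("day must be >= 0")
        L = frame["length_mm"].astype(float).to_numpy()
        W = frame["width_mm"].astype(float).to_numpy()
        swapped = W > L
        if swapped.any():
            warnings.warn(
                f"{int(swapped.sum())} caliper entries had width > length; axes swapped",
                stacklevel=2,
            )
            L[swapped], W[swapped] = W[swapped], L[swapped].copy()
        frame["length_mm"] = L
        frame["width_mm"] = W
        frame["volume_mm3"] = tumor_volume(L, W)
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "TumorMeasurementLog":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class GrowthSummary:
    """Per-group descriptive growth metrics.

    relative_volume: long table (animal_id, group, day, relative_volume),
    volume scaled to each animal's day-0 reading.
    time_to_threshold: one row per animal with the first measured day at or
    above the threshold volume (NaN + censored=True if never reached).
    group_summary: per-group mean time-to-threshold and growth delay in days
    relative to the control group mean.
    """

    relative_volume: pd.DataFrame
    time_to_threshold: pd.DataFrame
    group_summary: pd.DataFrame


def growth_summaries(
    log: TumorMeasurementLog,
    threshold_volume: float,
    control_group: str,
) -> GrowthSummary:
    """Relative growth curves, time-to-threshold, and growth delay per group.

    Every animal must have a day-0 entry (the normalization reference).
    Time-to-threshold is the first *measured* day with volume >= threshold,
    without interpolation; animals never reaching it are censored and
    excluded from the group means. Growth delay = group mean time minus the
    control-group mean (negative values mean faster-than-control growth).
    """
    if threshold_volume <= 0:
        raise ValueError("threshold_volume must be positive")
    df = log.frame
    if control_group not in set(df["group"]):
        raise ValueError(f"control group {control_group!r} not present in log")

    day0 = df[df["day"] == 0].set_index("animal_id")["volume_mm3"]
    missing = sorted(set(df["animal_id"]) - set(day0.index))
    if missing:
        raise ValueError(f"animals without a day-0 entry: {missing}")

    rel = df[["animal_id", "group", "day", "volume_mm3"]].copy()
    rel["relative_volume"] = rel["volume_mm3"] / rel["animal_id"].map(day0).to_numpy()
    rel = rel.drop(columns="volume_mm3").sort_values(["group", "animal_id", "day"]).reset_index(drop=True)

    ttt_rows = []
    for (animal, group), sub in df.groupby(["animal_id", "group"], sort=True):
        hit = sub.loc[sub["volume_mm3"] >= threshold_volume, "day"]
        if hit.empty:
            ttt_rows.append((animal, group, np.nan, True))
        else:
            ttt_rows.append((animal, group, float(hit.min()), False))
    ttt = pd.DataFrame(ttt_rows, columns=["animal_id", "group", "day_reached", "censored"])

    group_mean = ttt[~ttt["censored"]].groupby("group")["day_reached"].mean()
    if control_group not in group_mean.index:
        raise ValueError(f"no animal in control group {control_group!r} reached the threshold")
    control_mean = float(group_mean[control_group])
    summary = pd.DataFrame(
        {
            "group": group_mean.index,
            "mean_day_reached": group_mean.to_numpy(),
            "growth_delay_days": group_mean.to_numpy() - control_mean,
            "n_reached": ttt[~ttt["censored"]].groupby("group").size().reindex(group_mean.index).to_numpy(),
            "n_censored": ttt[ttt["censored"]].groupby("group").size().reindex(group_mean.index, fill_value=0).to_numpy(),
        }
    ).reset_index(drop=True)
    return GrowthSummary(rel, ttt, summary)
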