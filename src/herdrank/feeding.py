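"""Feeder-event feature extraction.

Raw feeder sessions (animal, start time, duration, intake) are reduced to
per-animal-day summaries: total intake, visit count, total and median
session duration, feed rate, and the distribution of feeding time over
six 4-hour slots.  Each absolute metric also gets a pen-relative
counterpart (value / same-day pen median), and daily values are
aggregated per study phase (medians, except time-slot metrics which use
means, and the daily median session duration which aggregates as a
median of medians).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_SLOTS = 6
SLOT_HOURS = 4.0

BASE_METRICS = [
    "intake_g",
    "n_visits",
    "total_duration_s",
    "median_session_s",
    "feed_rate_g_per_s",
]


def slot_columns(kind: str, anchor_hour: int = 2) -> list[str]:
    """Column names for the six 4-h windows, e.g. ``slot_s_10_14``."""
    cols = []
    for k in range(N_SLOTS):
        lo = int((anchor_hour + SLOT_HOURS * k) % 24)
        hi = int((lo + SLOT_HOURS) % 24) or 24
        cols.append(f"slot_{kind}_{lo:02d}_{hi:02d}")
    return cols


def _slot_overlap_seconds(
    start_hour: np.ndarray, duration_s: np.ndarray, anchor_hour: int
) -> np.ndarray:
    """Seconds of each session falling in each 4-h window (pro-rata split).

    Sessions are attributed to windows by clock time; a session crossing
    midnight wraps into the windows of the following clock cycle but is
    still booked to the day it started.
    """
    s = (start_hour - anchor_hour) % 24.0  # hours since the anchor
    e = s + duration_s / 3600.0
    out = np.zeros((len(s), N_SLOTS))
    for k in range(N_SLOTS):
        lo, hi = SLOT_HOURS * k, SLOT_HOURS * (k + 1)
        for shift in (0.0, 24.0):  # handle wrap past the anchor
            ov = np.minimum(e, hi + shift) - np.maximum(s, lo + shift)
            out[:, k] += np.clip(ov, 0.0, None)
    return out * 3600.0


def daily_summaries(events: pd.DataFrame, slot_anchor_hour: int = 2) -> pd.DataFrame:
    """Aggregate raw feeder events into per-animal-day metrics.

    The default anchor of 02:00 makes one window exactly [10:00, 14:00).
    Rows with negative duration or intake are rejected with a warning.
    Day boundaries are at midnight; an event belongs to the day it starts.
    """
    ev = events.copy()
    ev["start_time"] = pd.to_datetime(ev["start_time"])
    bad = (ev["duration_s"] <= 0) | (ev["intake_g"] < 0)
    if bad.any():
        logger.warning("rejecting %d events with nonpositive duration or negative intake",
                       int(bad.sum()))
        ev = ev[~bad]
    if ev.empty:
        raise ValueError("no valid feeding events")
    ev["day"] = ev["start_time"].dt.normalize()
    hour = (
        ev["start_time"].dt.hour
        + ev["start_time"].dt.minute / 60.0
        + ev["start_time"].dt.second / 3600.0
    ).to_numpy()
    slots = _slot_overlap_seconds(hour, ev["duration_s"].to_numpy(), slot_anchor_hour)
    sec_cols = slot_columns("s", slot_anchor_hour)
    for j, col in enumerate(sec_cols):
        ev[col] = slots[:, j]

    grouped = ev.groupby(["animal_id", "day"])
    out = grouped.agg(
        intake_g=("intake_g", "sum"),
        n_visits=("intake_g", "size"),
        total_duration_s=("duration_s", "sum"),
        median_session_s=("duration_s", "median"),
        **{c: (c, "sum") for c in sec_cols},
    ).reset_index()
    out["feed_rate_g_per_s"] = out["intake_g"] / out["total_duration_s"]
    pct_cols = slot_columns("pct", slot_anchor_hour)
    for sc, pc in zip(sec_cols, pct_cols):
        out[pc] = 100.0 * out[sc] / out["total_duration_s"]
    return out


def normalize_by_pen(
    daily: pd.DataFrame,
    pens: pd.DataFrame | pd.Series,
    metrics: list[str] | None = None,
) -> pd.DataFrame:
    """Add ``rel_<metric>`` columns: value / same-day pen median.

    ``pens`` is either a Series animal_id -> pen_id (static groups) or a
    DataFrame with columns ``animal_id, day, pen_id`` for mixing-aware
    membership (``day`` as a normalized timestamp or a study-day int
    matching ``daily['day']``).  A zero pen-day median yields NaN, never
    infinity.
    """
    df = daily.copy()
    if isinstance(pens, pd.Series):
        df["pen_id"] = df["animal_id"].map(pens)
    else:
        df = df.merge(pens, on=["animal_id", "day"], how="left")
    if df["pen_id"].isna().any():
        lost = df.loc[df["pen_id"].isna(), "animal_id"].unique().tolist()
        raise ValueError(f"no pen assignment for animals {lost}")
    if metrics is None:
        metrics = [c for c in df.columns
                   if c in BASE_METRICS or c.startswith(("slot_s_", "slot_pct_"))]
    for m in metrics:
        med = df.groupby(["pen_id", "day"])[m].transform("median")
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = df[m] / med
        df[f"rel_{m}"] = rel.where(med != 0)
    return df


def phase_aggregate(daily: pd.DataFrame, phase_of_day) -> pd.DataFrame:
    """Per-animal per-phase values: medians over days, except time-slot
    metrics (means) and the daily median session duration (median of the
    daily medians).

    ``phase_of_day`` maps a day value from ``daily['day']`` to a phase
    label; animals without data in a phase simply have no row (exclusion
    is logged by the caller when a full roster is expected).
    """
    df = daily.copy()
    df["phase"] = df["day"].map(phase_of_day)
    value_cols = [
        c for c in df.columns
        if c not in ("animal_id", "day", "phase", "pen_id")
        and pd.api.types.is_numeric_dtype(df[c])
    ]
    mean_cols = [c for c in value_cols if "slot_" in c]
    median_cols = [c for c in value_cols if c not in mean_cols]
    agg = {c: "mean" for c in mean_cols}
    agg.update({c: "median" for c in median_cols})
    out = df.groupby(["animal_id", "phase"]).agg(agg).reset_index()
    return out
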