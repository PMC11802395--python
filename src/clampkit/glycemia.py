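"""Meal-test AUC summaries and CGM-derived glycaemic metrics.

CGM metrics use duration weighting with left-sample attribution: each
reading represents the interval until the next reading; intervals longer
than the gap threshold (default 30 min) are treated as sensor gaps and
excluded from all denominators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError, ValidationError

SENSOR_RANGE = (2.2, 22.2)  # mmol/L, typical CGM reporting limits
DEFAULT_GAP_MIN = 30.0
DEFAULT_RANGE = (4.0, 10.0)  # mmol/L consensus target range


def auc_trapezoid(
    time: np.ndarray,
    values: np.ndarray,
    t0: float,
    t1: float,
    incremental: bool = False,
) -> float:
    """Trapezoidal area under a sampled curve between t0 and t1 (units: value*min).

    Endpoints inside a sampling interval are linearly interpolated; the
    curve must span [t0, t1].  The incremental variant subtracts the
    value at t0 before integrating and retains negative area.
    """
    time = np.asarray(time, float)
    values = np.asarray(values, float)
    if np.any(np.diff(time) <= 0):
        raise ValidationError("time must be strictly increasing")
    if t0 < time[0] or t1 > time[-1] or t1 <= t0:
        raise DomainError(f"requested span [{t0}, {t1}] not covered by samples")
    inner = (time > t0) & (time < t1)
    t = np.concatenate([[t0], time[inner], [t1]])
    v = np.concatenate([[np.interp(t0, time, values)], values[inner], [np.interp(t1, time, values)]])
    if incremental:
        v = v - v[0]
    return float(np.trapezoid(v, t))


@dataclass
class CgmTrace:
    """Timestamped interstitial glucose (mmol/L) at roughly 5-min cadence."""

    timestamps: pd.DatetimeIndex
    glucose: np.ndarray
    gap_min: float = DEFAULT_GAP_MIN

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.glucose = np.asarray(self.glucose, float)
        if len(self.timestamps) != len(self.glucose):
            raise ValidationError("timestamps and glucose lengths differ")
        if len(self.timestamps) >= 2 and (self.timestamps[1:] <= self.timestamps[:-1]).any():
            raise ValidationError("timestamps must be strictly increasing")
        lo, hi = SENSOR_RANGE
        if np.any((self.glucose < lo) | (self.glucose > hi)):
            warnings.warn(
                f"glucose values outside the sensor range [{lo}, {hi}] mmol/L", stacklevel=2
            )

    def interval_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """(durations in minutes, kept mask) for left-attributed intervals.

        The last sample carries no interval; intervals longer than
        ``gap_min`` are flagged as gaps and dropped.
        """
        if len(self.timestamps) < 2:
            raise InsufficientDataError("need at least 2 samples to form intervals")
        dt = np.diff(self.timestamps.view("int64")) / 60e9  # ns -> min
        kept = dt <= self.gap_min
        return dt, kept

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.timestamps, "glucose_mmol_l": self.glucose})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, gap_min: float = DEFAULT_GAP_MIN) -> "CgmTrace":
        return cls(
            timestamps=pd.DatetimeIndex(pd.to_datetime(df["timestamp"])),
            glucose=df["glucose_mmol_l"].to_numpy(float),
            gap_min=gap_min,
        )


def _weighted(trace: CgmTrace, min_hours: float):
    dt, kept = trace.interval_weights()
    if not kept.any():
        raise InsufficientDataError("all intervals are gaps")
    total_min = float(dt[kept].sum())
    if total_min < min_hours * 60.0:
        raise InsufficientDataError(
            f"only {total_min / 60:.1f} h of non-gap data; need >= {min_hours} h"
        )
    g = trace.glucose[:-1][kept]
    w = dt[kept]
    return g, w, total_min


def time_in_range(
    trace: CgmTrace,
    lo: float = DEFAULT_RANGE[0],
    hi: float = DEFAULT_RANGE[1],
    min_hours: float = 24.0,
) -> float:
    """Percentage of (non-gap, duration-weighted) time with lo <= glucose <= hi."""
    g, w, total = _weighted(trace, min_hours)
    return float(100.0 * w[(g >= lo) & (g <= hi)].sum() / total)


def cgm_summary(
    trace: CgmTrace,
    lo: float = DEFAULT_RANGE[0],
    hi: float = DEFAULT_RANGE[1],
    min_hours: float = 24.0,
) -> dict[str, float]:
    """Duration-weighted CGM summary: mean, SD, CV, and the TIR partition.

    time_below + tir + time_above sums to 100% exactly.
    """
    g, w, total = _weighted(trace, min_hours)
    mean = float(np.sum(w * g) / total)
    var = float(np.sum(w * (g - mean) ** 2) / total)
    sd = float(np.sqrt(var))
    below = float(100.0 * w[g < lo].sum() / total)
    above = float(100.0 * w[g > hi].sum() / total)
    tir = 100.0 - below - above
    return {
        "mean": mean,
        "sd": sd,
        "cv": sd / mean if mean > 0 else float("nan"),
        "tir": tir,
        "time_above": above,
        "time_below": below,
        "hours": total / 60.0,
    }
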