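"""Anticoagulation-quality endpoints: Rosendaal TTR and INR proportions.

The Rosendaal method assumes the INR changes linearly between two
consecutive measurements and allocates each inter-visit interval's time
to in-range / out-of-range using the exact boundary-crossing points.
The therapeutic interval is closed: an interpolated INR exactly equal
to a range limit counts as in range.  Consecutive measurements further
apart than ``max_gap`` days (default 56) are excluded from both the
numerator and the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import PatientRecord, TargetRange
from .predmetrics import round1

__all__ = [
    "InrSeries",
    "rosendaal_ttr",
    "inr_proportions",
    "windowed_summary",
    "cohort_ttr",
]

DEFAULT_MAX_GAP = 56  # days


@dataclass(frozen=True)
class InrSeries:
    """Ordered (day, INR) measurements for one patient with a target range."""

    days: tuple[float, ...]
    inrs: tuple[float, ...]
    target: TargetRange

    def __post_init__(self) -> None:
        if len(self.days) != len(self.inrs) or len(self.days) < 1:
            raise ValueError("need equal-length, non-empty day and INR vectors")
        d = np.asarray(self.days)
        if np.any(np.diff(d) <= 0):
            raise ValueError("days must strictly increase")

    @classmethod
    def from_record(cls, record: PatientRecord) -> "InrSeries":
        return cls(
            days=tuple(float(v.day) for v in record.visits),
            inrs=tuple(float(v.inr) for v in record.visits),
            target=record.target,
        )


def _segment_time_in_range(
    t0: float, t1: float, y0: float, y1: float, low: float, high: float
) -> float:
    """Time within [low, high] of the line through (t0,y0)-(t1,y1), exactly."""
    dt = t1 - t0
    if dt <= 0:
        return 0.0
    if y0 == y1:
        return dt if low <= y0 <= high else 0.0
    # times at which the line crosses the two bounds
    slope = (y1 - y0) / dt
    ta = t0 + (low - y0) / slope
    tb = t0 + (high - y0) / slope
    enter, leave = (ta, tb) if ta <= tb else (tb, ta)
    return max(0.0, min(t1, leave) - max(t0, enter))


def rosendaal_ttr(
    series: InrSeries,
    max_gap: float = DEFAULT_MAX_GAP,
    clip_to: tuple[float, float] | None = None,
) -> float | None:
    """%TTR by linear interpolation; None when undefined.

    ``clip_to`` restricts the computation to a time window: segments are
    geometrically clipped at the window bounds before time is allocated.
    Returns None for a single measurement or when every segment is
    excluded by the gap rule.
    """
    days = np.asarray(series.days, dtype=float)
    inrs = np.asarray(series.inrs, dtype=float)
    if days.size < 2:
        return None
    low, high = series.target.low, series.target.high
    total = 0.0
    in_range = 0.0
    for i in range(days.size - 1):
        t0, t1 = days[i], days[i + 1]
        if t1 - t0 > max_gap:
            continue
        y0, y1 = inrs[i], inrs[i + 1]
        if clip_to is not None:
            a, b = clip_to
            c0, c1 = max(t0, a), min(t1, b)
            if c1 <= c0:
                continue
            slope = (y1 - y0) / (t1 - t0)
            y0, y1 = y0 + slope * (c0 - t0), y0 + slope * (c1 - t0)
            t0, t1 = c0, c1
        total += t1 - t0
        in_range += _segment_time_in_range(t0, t1, y0, y1, low, high)
    if total <= 0:
        return None
    return 100.0 * in_range / total


@dataclass(frozen=True)
class InrProportions:
    n: int
    counts: dict[str, int]
    in_range_pct: float
    above_pct: float
    below_pct: float

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "counts": dict(self.counts),
            "in_range_pct": self.in_range_pct,
            "above_pct": self.above_pct,
            "below_pct": self.below_pct,
        }


def inr_proportions(
    measurements: Iterable[float], target: TargetRange
) -> InrProportions:
    """Measurement-wise proportions in / above / below the closed range."""
    vals = np.asarray(list(measurements), dtype=float)
    if vals.size == 0:
        raise ValueError("no INR measurements")
    in_range = int(np.sum((vals >= target.low) & (vals <= target.high)))
    above = int(np.sum(vals > target.high))
    below = int(np.sum(vals < target.low))
    n = int(vals.size)
    return InrProportions(
        n=n,
        counts={"in_range": in_range, "above": above, "below": below},
        in_range_pct=round1(100.0 * in_range / n),
        above_pct=round1(100.0 * above / n),
        below_pct=round1(100.0 * below / n),
    )


def cohort_inr_proportions(records: Sequence[PatientRecord]) -> InrProportions:
    """Pooled measurement-wise proportions, each against its own target."""
    in_range = above = below = 0
    for rec in records:
        for v in rec.visits:
            if v.inr > rec.target.high:
                above += 1
            elif v.inr < rec.target.low:
                below += 1
            else:
                in_range += 1
    n = in_range + above + below
    if n == 0:
        raise ValueError("no INR measurements in cohort")
    return InrProportions(
        n=n,
        counts={"in_range": in_range, "above": above, "below": below},
        in_range_pct=round1(100.0 * in_range / n),
        above_pct=round1(100.0 * above / n),
        below_pct=round1(100.0 * below / n),
    )


def cohort_ttr(
    records: Sequence[PatientRecord],
    max_gap: float = DEFAULT_MAX_GAP,
) -> pd.DataFrame:
    """Per-patient %TTR table; summarize with median/IQR as usual."""
    rows = []
    for rec in records:
        ttr = rosendaal_ttr(InrSeries.from_record(rec), max_gap)
        rows.append({"patient_id": rec.patient_id, "ttr_pct": ttr, "n_inr": rec.n_visits})
    return pd.DataFrame(rows)


def windowed_summary(
    records: Sequence[PatientRecord],
    windows: Sequence[int] = (30, 60, 90),
    max_gap: float = DEFAULT_MAX_GAP,
) -> pd.DataFrame:
    """Per-window cohort summary: median/IQR TTR and INR proportions.

    Windows are start-anchored [0, bound]; measurements with day ≤ bound
    count toward the proportions and interpolation segments are clipped
    at the bound.
    """
    rows = []
    for bound in windows:
        ttrs = []
        in_range = above = below = 0
        for rec in records:
            series = InrSeries.from_record(rec)
            ttr = rosendaal_ttr(series, max_gap, clip_to=(0.0, float(bound)))
            if ttr is not None:
                ttrs.append(ttr)
            for v in rec.visits:
                if v.day > bound:
                    continue
                if v.inr > rec.target.high:
                    above += 1
                elif v.inr < rec.target.low:
                    below += 1
                else:
                    in_range += 1
        n = in_range + above + below
        ttrs_arr = np.asarray(ttrs)
        rows.append(
            {
                "window_days": bound,
                "n_patients_with_ttr": len(ttrs),
                "median_ttr_pct": float(np.median(ttrs_arr)) if ttrs else None,
                "iqr_low_ttr_pct": float(np.percentile(ttrs_arr, 25)) if ttrs else None,
                "iqr_high_ttr_pct": float(np.percentile(ttrs_arr, 75)) if ttrs else None,
                "n_inr": n,
                "in_range_pct": round1(100.0 * in_range / n) if n else None,
                "above_pct": round1(100.0 * above / n) if n else None,
                "below_pct": round1(100.0 * below / n) if n else None,
            }
        )
    return pd.DataFrame(rows)
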