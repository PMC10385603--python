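"""Tumour-growth metrics, sacrifice rules and survival statistics.

Calliper volumes use the ellipsoid-style formula V = (L x W x h) x 3.14/6
with the constant 3.14 exactly (study convention).  Growth is summarised by
the doubling time from a log-linear fit, and treatment response by the
maximum volume reduction relative to a reference day.  Survival uses the
Kaplan-Meier product-limit estimator and the log-rank (Mantel-Cox) test;
mice are sacrificed on first rule violation (volume limit, weight loss,
paralysis) and survivors are censored at the 100-day study horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "VOLUME_CONSTANT",
    "STUDY_HORIZON_DAYS",
    "TumourGrowthSeries",
    "SurvivalRecord",
    "tumour_volume",
    "doubling_time",
    "max_volume_reduction",
    "apply_sacrifice_rules",
    "km_estimator",
    "logrank_test",
]

VOLUME_CONSTANT = 3.14 / 6.0  # the study uses 3.14, not pi
STUDY_HORIZON_DAYS = 100.0
DEFAULT_VOLUME_LIMIT_MM3 = 2000.0
DEFAULT_WEIGHT_LOSS_FRACTION = 0.20


def tumour_volume(length_mm: float, width_mm: float, height_mm: float) -> float:
    """Calliper tumour volume in mm^3: (L x W x h) x 3.14/6."""
    if length_mm < 0 or width_mm < 0 or height_mm < 0:
        raise ValueError("dimensions must be nonnegative")
    return length_mm * width_mm * height_mm * VOLUME_CONSTANT


@dataclass
class TumourGrowthSeries:
    """Calliper trajectory of one mouse."""

    mouse_id: str
    group: str
    days: list[float]
    length_mm: list[float]
    width_mm: list[float]
    height_mm: list[float]

    def __post_init__(self) -> None:
        n = len(self.days)
        if not (len(self.length_mm) == len(self.width_mm) == len(self.height_mm) == n):
            raise ValueError("dimension lists must match days in length")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")

    @property
    def volumes_mm3(self) -> list[float]:
        return [tumour_volume(l, w, h)
                for l, w, h in zip(self.length_mm, self.width_mm, self.height_mm)]


@dataclass(frozen=True)
class SurvivalRecord:
    """Time-to-event record for one mouse; event=0 means censored."""

    mouse_id: str
    group: str
    time_days: float
    event: int  # 1 = death or sacrifice, 0 = censored
    cause: str = ""  # paralysis | volume_limit | weight_loss | toxicity | study_end

    def __post_init__(self) -> None:
        if self.time_days <= 0:
            raise ValueError("time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def doubling_time(series: TumourGrowthSeries,
                  window: tuple[float, float] | None = None) -> float:
    """Doubling time in days: ln(2) / slope of ln(volume) vs day.

    Nonpositive volumes inside the window are excluded; a nonpositive slope
    (no growth) yields NaN.  ``window`` is half-open [start, stop).
    """
    days = np.asarray(series.days, float)
    vols = np.asarray(series.volumes_mm3, float)
    if window is not None:
        mask = (days >= window[0]) & (days < window[1])
        days, vols = days[mask], vols[mask]
    keep = vols > 0
    days, vols = days[keep], vols[keep]
    if days.size < 2:
        raise ValueError("need at least two positive volumes in the window")
    slope = np.polyfit(days, np.log(vols), 1)[0]
    # slopes at round-off scale (flat series) count as "no growth"
    if slope <= 1e-12:
        return float("nan")
    return float(math.log(2.0) / slope)


def max_volume_reduction(series: TumourGrowthSeries, reference_day: float) -> float:
    """Maximum percent volume reduction at or after the reference day.

    The reference volume is the measurement at ``reference_day`` (the day of
    the second injection by default in the pipeline); monotone growth gives
    0% (floored at zero).
    """
    days = np.asarray(series.days, float)
    vols = np.asarray(series.volumes_mm3, float)
    ref_idx = np.flatnonzero(np.isclose(days, reference_day))
    if ref_idx.size == 0:
        raise ValueError(f"no measurement at reference day {reference_day}")
    v_ref = vols[ref_idx[0]]
    if v_ref <= 0:
        raise ValueError("reference volume must be positive")
    later = vols[days >= reference_day]
    reduction = 100.0 * (1.0 - np.min(later) / v_ref)
    return float(max(0.0, reduction))


def apply_sacrifice_rules(mouse_id: str, group: str,
                          days: Sequence[float],
                          volumes_mm3: Sequence[float] | None = None,
                          weights_g: Sequence[float] | None = None,
                          paralysis: Sequence[bool] | None = None,
                          volume_limit_mm3: float = DEFAULT_VOLUME_LIMIT_MM3,
                          weight_loss_fraction: float = DEFAULT_WEIGHT_LOSS_FRACTION,
                          horizon_days: float = STUDY_HORIZON_DAYS) -> SurvivalRecord:
    """First day any humane-endpoint rule fires; censored at the horizon.

    Rules, checked in day order (first rule wins within a day): paralysis,
    weight loss >= 20% of initial body weight, tumour volume >= 2000 mm^3.
    """
    days = list(days)
    w0 = weights_g[0] if weights_g else None
    for i, day in enumerate(days):
        if day > horizon_days:
            break
        if paralysis is not None and paralysis[i]:
            return SurvivalRecord(mouse_id, group, day, 1, "paralysis")
        if weights_g is not None and w0 and weights_g[i] <= (1 - weight_loss_fraction) * w0:
            return SurvivalRecord(mouse_id, group, day, 1, "weight_loss")
        if volumes_mm3 is not None and volumes_mm3[i] >= volume_limit_mm3:
            return SurvivalRecord(mouse_id, group, day, 1, "volume_limit")
    return SurvivalRecord(mouse_id, group, horizon_days, 0, "study_end")


def km_estimator(records: Iterable[SurvivalRecord]
                 ) -> tuple[pd.DataFrame, float]:
    """Kaplan-Meier product-limit estimate and median survival.

    Returns a step-function table (time, survival) and the median, defined
    as the smallest event time with S(t) <= 0.5; NaN when the curve never
    reaches 0.5.
    """
    recs = list(records)
    if not recs:
        raise ValueError("need at least one survival record")
    times = np.array([r.time_days for r in recs], float)
    events = np.array([r.event for r in recs], int)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    table = pd.DataFrame({"time": sf.index.values,
                          "survival": sf.iloc[:, 0].values})
    below = table[table["survival"] <= 0.5 + 1e-12]
    median = float(below["time"].iloc[0]) if not below.empty else float("nan")
    return table, median


def logrank_test(group_a: Iterable[SurvivalRecord],
                 group_b: Iterable[SurvivalRecord]) -> tuple[float, float]:
    """Log-rank (Mantel-Cox) chi-square with 1 df and two-sided p-value.

    Returns (NaN, NaN) when the statistic is undefined (zero variance,
    e.g. no events).
    """
    a, b = list(group_a), list(group_b)
    if not a or not b:
        raise ValueError("both groups need records")
    if sum(r.event for r in a) + sum(r.event for r in b) == 0:
        return float("nan"), float("nan")
    res = _ll_logrank(
        [r.time_days for r in a], [r.time_days for r in b],
        event_observed_A=[r.event for r in a],
        event_observed_B=[r.event for r in b],
    )
    chi2 = float(res.test_statistic)
    p = float(res.p_value)
    if math.isnan(chi2):
        return float("nan"), float("nan")
    return chi2, p
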