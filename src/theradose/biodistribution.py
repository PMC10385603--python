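"""Ex vivo biodistribution: organ counts to %ID/g and group statistics.

Each sacrificed mouse contributes one gamma-counter measurement per organ.
Counts are converted to activity, decay-corrected back to injection time,
and normalised by the tail-corrected injected activity and the organ mass,
yielding the percentage of injected dose per gram (%ID/g).  Group summaries
are reported as mean +/- sample SD at each timepoint, and groups are
compared with an unpaired (Welch) t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .nuclide import RadionuclideData, decay_correct

__all__ = [
    "CPM_PER_MBQ",
    "BiodistributionRecord",
    "OrganTimeSeries",
    "corrected_injected_activity",
    "activity_mbq_from_cpm",
    "percent_id_per_gram",
    "group_stats",
    "summarize",
    "organ_time_series",
    "tumour_to_organ_ratio",
    "welch_t_test",
    "records_to_frame",
    "records_from_frame",
]

# 1 MBq = 1e6 decays/s = 6e7 decays/min; a counter with efficiency e
# registers e * 6e7 counts per minute per MBq in the well.
CPM_PER_MBQ = 6.0e7


@dataclass(frozen=True)
class BiodistributionRecord:
    """One organ measurement from one sacrificed mouse."""

    mouse_id: str
    group: str  # "healthy" | "tumour_bearing"
    organ: str
    timepoint_h: float
    organ_mass_g: float
    organ_cpm: float
    counter_efficiency: float
    injected_activity_mbq: float
    tail_remainder_mbq: float
    sacrifice_time_h: float

    def __post_init__(self) -> None:
        if self.organ_mass_g <= 0:
            raise ValueError("organ_mass_g must be positive")
        if not 0 < self.counter_efficiency <= 1:
            raise ValueError("counter_efficiency must be in (0, 1]")
        if self.tail_remainder_mbq > self.injected_activity_mbq:
            raise ValueError("tail remainder exceeds injected activity")
        if self.organ_cpm < 0 or self.tail_remainder_mbq < 0:
            raise ValueError("counts and activities must be nonnegative")


@dataclass
class OrganTimeSeries:
    """Summary %ID/g kinetics of one organ in one group."""

    organ: str
    group: str
    timepoints_h: list[float]
    mean_pid_g: list[float]
    sd_pid_g: list[float]
    n: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(self.timepoints_h), len(self.mean_pid_g), len(self.sd_pid_g)}
        if self.n:
            lengths.add(len(self.n))
        if len(lengths) != 1:
            raise ValueError("all series lists must have equal length")
        if self.n and any(k < 1 for k in self.n):
            raise ValueError("n must be >= 1 per timepoint")
        if any(s < 0 for s in self.sd_pid_g if not math.isnan(s)):
            raise ValueError("sd must be nonnegative")


def corrected_injected_activity(injected_mbq: float, tail_remainder_mbq: float) -> float:
    """Injected activity corrected for what stayed at the tail injection site."""
    if tail_remainder_mbq < 0 or injected_mbq < 0:
        raise ValueError("activities must be nonnegative")
    if tail_remainder_mbq > injected_mbq:
        raise ValueError("tail remainder exceeds injected activity")
    return injected_mbq - tail_remainder_mbq


def activity_mbq_from_cpm(cpm: float, counter_efficiency: float) -> float:
    """Convert gamma-counter counts/min to MBq in the sample."""
    if not 0 < counter_efficiency <= 1:
        raise ValueError("counter_efficiency must be in (0, 1]")
    return cpm / counter_efficiency / CPM_PER_MBQ


def percent_id_per_gram(record: BiodistributionRecord, nuclide: RadionuclideData) -> float:
    """%ID/g for one organ record, decay corrected at injection time."""
    injected = corrected_injected_activity(
        record.injected_activity_mbq, record.tail_remainder_mbq
    )
    if injected <= 0:
        raise ValueError("corrected injected activity must be positive")
    measured = activity_mbq_from_cpm(record.organ_cpm, record.counter_efficiency)
    at_injection = decay_correct(measured, record.sacrifice_time_h, nuclide)
    return 100.0 * at_injection / injected / record.organ_mass_g


def group_stats(
    records: Iterable[BiodistributionRecord],
    organ: str,
    timepoint_h: float,
    nuclide: RadionuclideData,
    group: str | None = None,
) -> tuple[float, float, int]:
    """Mean, sample SD (n-1) and n of %ID/g for one organ at one timepoint.

    SD is reported as NaN for a single record.
    """
    values = [
        percent_id_per_gram(r, nuclide)
        for r in records
        if r.organ == organ
        and math.isclose(r.timepoint_h, timepoint_h, rel_tol=1e-9, abs_tol=1e-9)
        and (group is None or r.group == group)
    ]
    if not values:
        raise ValueError(f"no records for organ={organ!r} at t={timepoint_h} h")
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else float("nan")
    return float(arr.mean()), sd, int(arr.size)


def summarize(records: Sequence[BiodistributionRecord],
              nuclide: RadionuclideData) -> pd.DataFrame:
    """Organ x timepoint mean/SD/n table of %ID/g, one row per cell."""
    rows = []
    for r in records:
        rows.append(
            (r.group, r.organ, r.timepoint_h, percent_id_per_gram(r, nuclide))
        )
    df = pd.DataFrame(rows, columns=["group", "organ", "timepoint_h", "pid_g"])
    out = (
        df.groupby(["group", "organ", "timepoint_h"])["pid_g"]
        .agg(mean_pid_g="mean", sd_pid_g=lambda x: x.std(ddof=1), n="count")
        .reset_index()
        .sort_values(["group", "organ", "timepoint_h"])
        .reset_index(drop=True)
    )
    return out


def organ_time_series(records: Sequence[BiodistributionRecord],
                      nuclide: RadionuclideData,
                      organ: str, group: str) -> OrganTimeSeries:
    """Collapse per-mouse records into one organ's summary time series."""
    df = summarize([r for r in records if r.organ == organ and r.group == group],
                   nuclide)
    if df.empty:
        raise ValueError(f"no records for organ={organ!r}, group={group!r}")
    return OrganTimeSeries(
        organ=organ,
        group=group,
        timepoints_h=df["timepoint_h"].tolist(),
        mean_pid_g=df["mean_pid_g"].tolist(),
        sd_pid_g=df["sd_pid_g"].fillna(0.0).tolist(),
        n=df["n"].tolist(),
    )


def tumour_to_organ_ratio(tumour_mean: float, organ_mean: float) -> float:
    """Ratio of tumour to reference-organ uptake (or absorbed dose)."""
    if organ_mean <= 0:
        raise ValueError("organ mean must be positive")
    return tumour_mean / organ_mean


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float],
                 pooled: bool = False) -> tuple[float, float, float]:
    """Unpaired two-sample t-test; Welch by default, pooled variance on request.

    Returns (t, degrees of freedom, two-sided p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    res = stats.ttest_ind(a, b, equal_var=pooled)
    if pooled:
        df = a.size + b.size - 2
    else:
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        if va + vb == 0:  # identical constant groups
            return 0.0, float(a.size + b.size - 2), 1.0
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    t = float(res.statistic)
    p = float(res.pvalue)
    if math.isnan(t):  # zero variance in both groups with equal means
        return 0.0, float(df), 1.0
    return t, float(df), p


_RECORD_COLUMNS = [
    "mouse_id", "group", "organ", "timepoint_h", "organ_mass_g", "organ_cpm",
    "counter_efficiency", "injected_activity_mbq", "tail_remainder_mbq",
    "sacrifice_time_h",
]


def records_to_frame(records: Sequence[BiodistributionRecord]) -> pd.DataFrame:
    """Serialise records to the CSV schema consumed by the pipeline."""
    return pd.DataFrame([[getattr(r, c) for c in _RECORD_COLUMNS] for r in records],
                        columns=_RECORD_COLUMNS)


def records_from_frame(df: pd.DataFrame) -> list[BiodistributionRecord]:
    """Parse records from a DataFrame with the standard column schema."""
    return [
        BiodistributionRecord(**{c: row[c] for c in _RECORD_COLUMNS})
        for _, row in df.iterrows()
    ]
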