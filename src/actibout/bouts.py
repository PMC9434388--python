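"""Intensity bouts and the 8-factor daily behavior features.

A *bout* is a maximal run of consecutive same-class seconds; missing seconds
break runs.  Daily behavior is summarized by eight factors: time and
frequency of MVPA bouts at >=3 s and >=30 s minimum lengths, and of sedentary
bouts at >=60 s and >=300 s — thresholds are cumulative, so a 45 s MVPA run
contributes to both the >=3 s and >=30 s statistics.  Feature extraction is
restricted to a daytime analysis window (default 07:00-22:00), which also
implements the sleep-time exclusion (22:00-07:00) for sedentary accumulation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .processing import EpochSeries, WearAssessment, _parse_clock

__all__ = [
    "Bout",
    "DailyFeatures",
    "GuidelineCompliance",
    "MVPA_THRESHOLDS",
    "SB_THRESHOLDS",
    "ANALYSIS_WINDOW",
    "extract_bouts",
    "bout_features",
    "daily_features",
    "daily_summary",
    "guideline_compliance",
]

#: Cumulative minimum bout lengths (seconds) for MVPA and sedentary behavior.
MVPA_THRESHOLDS = (3, 30)
SB_THRESHOLDS = (60, 300)

#: Daytime clock window for behavior features (hours); its complement is the
#: sleep-time exclusion.
ANALYSIS_WINDOW = (7.0, 22.0)


@dataclass(frozen=True)
class Bout:
    """A maximal same-intensity run: class label, start offset, and duration (s)."""

    label: str
    start: int  # seconds from the start of the scanned sequence
    duration: int

    def __post_init__(self) -> None:
        if self.duration < 1:
            raise ValueError("bout duration must be >= 1 s")


@dataclass(frozen=True)
class DailyFeatures:
    """The 8-factor bout duration/frequency vector for one valid day.

    Times in minutes, frequencies as bout counts.  Invariants: the >=30 s
    (resp. >=300 s) statistics never exceed their >=3 s (>=60 s) counterparts.
    """

    mvpa_time_3s: float
    mvpa_time_30s: float
    sb_time_60s: float
    sb_time_300s: float
    mvpa_freq_3s: int
    mvpa_freq_30s: int
    sb_freq_60s: int
    sb_freq_300s: int
    participant: str | None = None
    period: str | None = None
    day_index: int | None = None

    FEATURE_NAMES = (
        "mvpa_time_3s", "mvpa_time_30s", "sb_time_60s", "sb_time_300s",
        "mvpa_freq_3s", "mvpa_freq_30s", "sb_freq_60s", "sb_freq_300s",
    )

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FEATURE_NAMES], dtype=float)

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class GuidelineCompliance:
    """Daily 60-min-MVPA guideline attainment over a set of valid days."""

    days_meeting: int
    n_days: int
    meets_on_average: bool
    per_week_rate: float  # guideline days per 7-day week


def extract_bouts(labels: "Sequence[str] | pd.Series | np.ndarray") -> list[Bout]:
    """Run-length encode a per-second label sequence into maximal bouts.

    Accepts any sequence of intensity labels; ``None``/NaN entries are missing
    seconds, which break runs and belong to no bout.  Concatenating the
    returned runs (with the gaps) reproduces the input exactly.
    """
    if isinstance(labels, pd.Series):
        arr = labels.to_numpy(dtype=object)
    else:
        arr = np.asarray(labels, dtype=object)
    n = len(arr)
    if n == 0:
        return []
    missing = pd.isna(arr)
    gap = "\x01"  # sentinel for missing seconds (numpy U-dtype drops "\0")
    codes = np.where(missing, gap, arr).astype("U16")
    change = np.flatnonzero(codes[1:] != codes[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    return [
        Bout(label=str(codes[s]), start=int(s), duration=int(e - s))
        for s, e in zip(starts, ends)
        if codes[s] != gap
    ]


def bout_features(
    bouts: Iterable[Bout],
    mvpa_thresholds: tuple[int, int] = MVPA_THRESHOLDS,
    sb_thresholds: tuple[int, int] = SB_THRESHOLDS,
    **identity,
) -> DailyFeatures:
    """Compute the 8-factor vector from one day's bouts.

    For class *c* and minimum length *L*: frequency is the number of class-*c*
    runs with duration >= L and time is the summed duration (minutes) of those
    runs.  Thresholds are cumulative (inclusive >=).
    """
    for t in (*mvpa_thresholds, *sb_thresholds):
        if t <= 0:
            raise ValueError("bout-length thresholds must be positive")
    durs = {"MVPA": [], "sedentary": []}
    for b in bouts:
        if b.label in durs:
            durs[b.label].append(b.duration)
    mv = np.asarray(durs["MVPA"], dtype=float)
    sb = np.asarray(durs["sedentary"], dtype=float)

    def _time(d: np.ndarray, L: int) -> float:
        return float(d[d >= L].sum()) / 60.0

    def _freq(d: np.ndarray, L: int) -> int:
        return int((d >= L).sum())

    m3, m30 = mvpa_thresholds
    s60, s300 = sb_thresholds
    return DailyFeatures(
        mvpa_time_3s=_time(mv, m3),
        mvpa_time_30s=_time(mv, m30),
        sb_time_60s=_time(sb, s60),
        sb_time_300s=_time(sb, s300),
        mvpa_freq_3s=_freq(mv, m3),
        mvpa_freq_30s=_freq(mv, m30),
        sb_freq_60s=_freq(sb, s60),
        sb_freq_300s=_freq(sb, s300),
        **identity,
    )


def daily_features(
    es: EpochSeries,
    wear: WearAssessment,
    window: tuple = ANALYSIS_WINDOW,
) -> pd.DataFrame:
    """8-factor features for every *valid* day of a labeled epoch series.

    Only epochs whose clock time falls inside ``window`` (default
    07:00–22:00) are scanned, and only days flagged valid by the wear
    assessment contribute rows.  Returns one row per valid day with the eight
    features plus participant/period/day_index columns.
    """
    lo, hi = (_parse_clock(v) for v in window)
    ep = es.epochs
    hours = ep.index.hour + ep.index.minute / 60 + ep.index.second / 3600
    in_win = (hours >= lo) & (hours < hi)
    rows = []
    for day in wear.valid_days:
        sel = ep[(ep["day_index"] == day) & in_win]
        labels = sel["label"].to_numpy(dtype=object)
        feats = bout_features(
            extract_bouts(labels),
            participant=es.participant,
            period=es.period,
            day_index=day,
        )
        rows.append(feats.as_dict())
    cols = list(DailyFeatures.FEATURE_NAMES) + ["participant", "period", "day_index"]
    return pd.DataFrame(rows, columns=cols)


def daily_summary(features: pd.DataFrame) -> dict:
    """Per-participant-period daily means: MVPA min/day (>=3 s) and SB h/day (>=60 s).

    Mean and sample SD across valid days; a single day reports SD 0 by
    convention.  Sedentary hours already exclude sleep time because features
    are computed within the daytime analysis window.
    """
    if len(features) == 0:
        raise ValueError("no valid days to summarize")
    mvpa = features["mvpa_time_3s"].to_numpy(dtype=float)
    sb_h = features["sb_time_60s"].to_numpy(dtype=float) / 60.0

    def _sd(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0

    return {
        "n_valid_days": int(len(features)),
        "mvpa_min_per_day_mean": float(mvpa.mean()),
        "mvpa_min_per_day_sd": _sd(mvpa),
        "sb_hours_per_day_mean": float(sb_h.mean()),
        "sb_hours_per_day_sd": _sd(sb_h),
    }


def guideline_compliance(daily_mvpa_minutes: Sequence[float]) -> GuidelineCompliance:
    """Attainment of the 60 min/day MVPA guideline (inclusive boundary).

    ``days_meeting`` counts valid days with >=60 bout-filtered MVPA minutes;
    ``meets_on_average`` is true iff the mean across days is >=60;
    ``per_week_rate`` rescales the meeting-day count to a 7-day week.
    """
    x = np.asarray(list(daily_mvpa_minutes), dtype=float)
    if len(x) == 0:
        raise ValueError("at least one valid day is required")
    meeting = int((x >= 60.0).sum())
    return GuidelineCompliance(
        days_meeting=meeting,
        n_days=int(len(x)),
        meets_on_average=bool(x.mean() >= 60.0),
        per_week_rate=float(meeting / len(x) * 7.0),
    )
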