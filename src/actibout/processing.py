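"""Raw wrist-accelerometer ingestion, 1-s SVM epoching, intensity classification, wear validity.

The processing chain mirrors the standard research-grade wrist-accelerometry
workflow for children: raw triaxial samples (units of g, nominally 60 Hz) are
collapsed into per-second signal-vector-magnitude (SVM) epochs, each second is
classified into sedentary / light / MVPA by population-validated cut points,
and days are screened by a wear-time protocol (minimum hours of data, an
implausibly-sedentary "non-wear" heuristic over a daytime clock window, and a
minimum number of valid days per participant).
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "INTENSITY_LEVELS",
    "CutPoints",
    "WearRules",
    "RawRecording",
    "EpochSeries",
    "WearAssessment",
    "read_raw_csv",
    "write_raw_csv",
    "compute_svm_epochs",
    "classify_intensity",
    "assess_wear",
]

#: Intensity classes, ordered from least to most intense.
INTENSITY_LEVELS = ("sedentary", "light", "MVPA")

RAW_CSV_COLUMNS = ["timestamp_iso8601", "x_g", "y_g", "z_g"]


def _parse_clock(value: "str | float | _dt.time") -> float:
    """Parse a clock time ('06:00', datetime.time, or hour float) to hours."""
    if isinstance(value, _dt.time):
        return value.hour + value.minute / 60 + value.second / 3600
    if isinstance(value, str):
        parts = value.split(":")
        h = float(parts[0])
        m = float(parts[1]) if len(parts) > 1 else 0.0
        s = float(parts[2]) if len(parts) > 2 else 0.0
        return h + m / 60 + s / 3600
    return float(value)


@dataclass(frozen=True)
class CutPoints:
    """Per-second summed-SVM intensity thresholds (g·s per 1-s epoch).

    ``sedentary_upper`` and ``light_upper`` bound the half-open class bands
    [0, sedentary_upper) → sedentary, [sedentary_upper, light_upper) → light,
    [light_upper, ∞) → MVPA.  Defaults derive from youth wrist GENEActiv
    thresholds (Schaefer et al. 2014: mean gravity-subtracted SVM of 0.190 g
    and 0.314 g per second) converted to the summed convention at 60 Hz.
    """

    sedentary_upper: float = 11.40
    light_upper: float = 18.84

    def __post_init__(self) -> None:
        if not (0 < self.sedentary_upper < self.light_upper):
            raise ValueError(
                "cut points must satisfy 0 < sedentary_upper < light_upper, "
                f"got {self.sedentary_upper!r}, {self.light_upper!r}"
            )

    def band(self, label: str) -> tuple[float, float]:
        """Half-open SVM interval for ``label``; MVPA upper bound is +inf."""
        if label == "sedentary":
            return (0.0, self.sedentary_upper)
        if label == "light":
            return (self.sedentary_upper, self.light_upper)
        if label == "MVPA":
            return (self.light_upper, np.inf)
        raise ValueError(f"unknown intensity label {label!r}")


@dataclass(frozen=True)
class WearRules:
    """Day-validity protocol for free-living wear in children.

    A day is *invalid* with fewer than ``min_hours_per_day`` hours of data,
    *non-wear* when more than ``nonwear_sedentary_fraction`` of its classified
    daytime epochs (within ``nonwear_window``, default 06:00–21:00) are
    sedentary, and a participant's record is usable only with at least
    ``min_valid_days`` valid days.
    """

    min_hours_per_day: float = 10.0
    nonwear_sedentary_fraction: float = 0.80
    nonwear_window: tuple[float, float] = (6.0, 21.0)
    min_valid_days: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.nonwear_sedentary_fraction <= 1):
            raise ValueError("nonwear_sedentary_fraction must be in (0, 1]")
        if self.min_valid_days < 1:
            raise ValueError("min_valid_days must be >= 1")
        if self.min_hours_per_day <= 0:
            raise ValueError("min_hours_per_day must be positive")
        object.__setattr__(
            self,
            "nonwear_window",
            tuple(_parse_clock(v) for v in self.nonwear_window),
        )


@dataclass
class RawRecording:
    """One participant-period triaxial acceleration trace.

    ``samples`` is a DataFrame with a strictly increasing DatetimeIndex and
    columns ``x``, ``y``, ``z`` in gravitational units.
    """

    participant: str
    period: str
    rate: float
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not isinstance(self.samples.index, pd.DatetimeIndex):
            raise TypeError("samples must be indexed by timestamps")
        if len(self.samples) and not self.samples.index.is_monotonic_increasing:
            raise ValueError("sample timestamps must be strictly increasing")
        if len(self.samples) and self.samples.index.has_duplicates:
            raise ValueError("sample timestamps must be strictly increasing (duplicates found)")
        vals = self.samples[["x", "y", "z"]].to_numpy()
        if len(vals) and not np.isfinite(vals).all():
            raise ValueError("axis values must be finite")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class EpochSeries:
    """Per-second SVM epochs for one participant-period.

    ``epochs`` is indexed by the epoch's start second and carries ``svm``
    (g·s, NaN where no samples cover the second), ``label`` (intensity class
    or NA) and ``day_index`` (days since the first calendar day of the
    recording; day boundaries at local midnight).
    """

    participant: str
    period: str
    epochs: pd.DataFrame

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def labeled(self) -> bool:
        return self.epochs["label"].notna().any()


@dataclass
class WearAssessment:
    """Per-day wear flags plus the participant-level validity verdict."""

    day_flags: pd.Series  # day_index -> {"valid", "invalid_short", "nonwear"}
    participant_valid: bool
    rules: WearRules = field(repr=False, default_factory=WearRules)

    @property
    def valid_days(self) -> list[int]:
        return [int(d) for d, f in self.day_flags.items() if f == "valid"]


# ---------------------------------------------------------------------------
# I/O


def read_raw_csv(path: "str | Path", participant: str | None = None,
                 period: str | None = None) -> RawRecording:
    """Read a raw recording from CSV (``timestamp_iso8601,x_g,y_g,z_g``).

    The sampling rate is inferred as the reciprocal of the median
    inter-sample gap.  Malformed rows are reported with their line numbers;
    non-monotone timestamps are an error.  ``participant``/``period`` default
    to a ``<participant>_<period>.csv`` file-name convention when parseable.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if list(df.columns) != RAW_CSV_COLUMNS:
        raise ValueError(
            f"{path}: unknown header {list(df.columns)!r}; expected {RAW_CSV_COLUMNS!r}"
        )
    ts = pd.to_datetime(df["timestamp_iso8601"], errors="coerce", format="ISO8601")
    xyz = df[["x_g", "y_g", "z_g"]].apply(pd.to_numeric, errors="coerce")
    bad = ts.isna() | xyz.isna().any(axis=1)
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"{path}: malformed rows at lines {lines}")
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise ValueError(f"{path}: timestamps are not strictly increasing")
    samples = pd.DataFrame(
        {"x": xyz["x_g"].to_numpy(), "y": xyz["y_g"].to_numpy(), "z": xyz["z_g"].to_numpy()},
        index=pd.DatetimeIndex(ts, name="timestamp"),
    )
    if len(samples) >= 2:
        gaps = np.diff(samples.index.to_numpy()).astype("timedelta64[ns]").astype(float)
        rate = 1e9 / float(np.median(gaps))
    else:
        rate = 1.0
    if participant is None or period is None:
        stem = path.stem.rsplit("_", 1)
        if len(stem) == 2:
            participant = participant or stem[0]
            period = period or stem[1]
    return RawRecording(
        participant=participant or "unknown",
        period=period or "unknown",
        rate=rate,
        samples=samples,
    )


def write_raw_csv(rec: RawRecording, path: "str | Path") -> Path:
    """Write a recording in the raw CSV dialect accepted by :func:`read_raw_csv`."""
    path = Path(path)
    out = pd.DataFrame(
        {
            "timestamp_iso8601": rec.samples.index.strftime("%Y-%m-%dT%H:%M:%S.%f"),
            "x_g": rec.samples["x"].to_numpy(),
            "y_g": rec.samples["y"].to_numpy(),
            "z_g": rec.samples["z"].to_numpy(),
        }
    )
    out.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Epoching and classification


def compute_svm_epochs(rec: RawRecording, epoch_length: int = 1,
                       subtract_gravity: bool = True) -> EpochSeries:
    """Collapse raw samples to per-epoch summed SVM values.

    Per epoch, ``svm = Σ |√(x²+y²+z²) − 1|`` over the samples falling in the
    epoch (gravity-subtracted magnitude, units g·s).  Seconds inside the
    recording span that contain no samples are kept as missing (NaN) epochs.
    ``subtract_gravity=False`` switches to the raw-magnitude convention
    ``Σ √(x²+y²+z²)``.
    """
    if epoch_length <= 0:
        raise ValueError("epoch_length must be positive")
    if len(rec) == 0:
        raise ValueError("recording has no samples")
    mags = np.sqrt((rec.samples[["x", "y", "z"]].to_numpy() ** 2).sum(axis=1))
    dev = np.abs(mags - 1.0) if subtract_gravity else mags
    # O(n) epoch aggregation on the integer-second grid
    step = int(epoch_length) * 1_000_000_000
    sec = rec.samples.index.asi8 // step
    offsets = (sec - sec[0]).astype(np.intp)
    n_epochs = int(offsets[-1]) + 1
    sums = np.bincount(offsets, weights=dev, minlength=n_epochs)
    covered = np.bincount(offsets, minlength=n_epochs) > 0
    svm_vals = np.where(covered, sums, np.nan)
    full = pd.date_range(
        pd.Timestamp(sec[0] * step), periods=n_epochs, freq=f"{epoch_length}s"
    )
    svm = pd.Series(svm_vals, index=full)
    day0 = full[0].normalize()
    day_index = ((full.normalize() - day0).days).astype(int)
    epochs = pd.DataFrame(
        {"svm": svm.to_numpy(), "label": pd.array([pd.NA] * len(full), dtype="string"),
         "day_index": day_index},
        index=full,
    )
    epochs.index.name = "timestamp"
    return EpochSeries(rec.participant, rec.period, epochs)


def classify_intensity(es: EpochSeries, cp: CutPoints) -> EpochSeries:
    """Label every non-missing epoch by the cut-point bands.

    Bands are closed on the left of each upper cut: sedentary is
    ``svm < sedentary_upper``, light ``[sedentary_upper, light_upper)`` and
    MVPA ``svm >= light_upper``.  Missing epochs stay missing.  Returns a new
    :class:`EpochSeries`; the input is not mutated.
    """
    svm = es.epochs["svm"].to_numpy()
    labels = np.select(
        [svm < cp.sedentary_upper, svm < cp.light_upper],
        ["sedentary", "light"],
        default="MVPA",
    )
    out = es.epochs.copy()
    out["label"] = pd.array(labels, dtype="string")
    out.loc[out["svm"].isna(), "label"] = pd.NA
    return EpochSeries(es.participant, es.period, out)


def assess_wear(es: EpochSeries, rules: WearRules | None = None) -> WearAssessment:
    """Apply the wear-time validity protocol to a labeled epoch series.

    Order of checks per day: (1) fewer than ``min_hours_per_day`` hours of
    non-missing epochs → ``invalid_short``; (2) otherwise, sedentary fraction
    of the non-missing classified epochs inside the non-wear clock window
    strictly above ``nonwear_sedentary_fraction`` → ``nonwear``; else
    ``valid``.  The participant is valid iff the number of valid days reaches
    ``min_valid_days``.
    """
    rules = rules or WearRules()
    if len(es) == 0:
        raise ValueError("empty epoch series")
    if not es.labeled:
        raise ValueError("epoch series must be classified before wear assessment")
    ep = es.epochs
    min_epochs = rules.min_hours_per_day * 3600
    lo, hi = rules.nonwear_window
    hours = ep.index.hour + ep.index.minute / 60 + ep.index.second / 3600
    in_window = (hours >= lo) & (hours < hi)
    flags: dict[int, str] = {}
    for day, grp in ep.groupby("day_index", sort=True):
        present = grp["svm"].notna()
        if int(present.sum()) < min_epochs:
            flags[int(day)] = "invalid_short"
            continue
        win = grp[in_window[ep["day_index"] == day] & present]
        if len(win) and (win["label"] == "sedentary").mean() > rules.nonwear_sedentary_fraction:
            flags[int(day)] = "nonwear"
        else:
            flags[int(day)] = "valid"
    day_flags = pd.Series(flags, name="day_flag")
    n_valid = int((day_flags == "valid").sum())
    return WearAssessment(day_flags, n_valid >= rules.min_valid_days, rules)
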