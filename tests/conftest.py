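import numpy as np
import pandas as pd
import pytest

from actibout import CutPoints, EpochSeries, RawRecording


@pytest.fixture
def cutpoints():
    return CutPoints(sedentary_upper=11.40, light_upper=18.84)


def make_recording(samples_xyz, start="2021-03-01 08:00:00", rate=60.0,
                   participant="p01", period="pre", times=None):
    """Build a RawRecording from an (n, 3) array, on a regular grid unless
    explicit times are given."""
    xyz = np.asarray(samples_xyz, dtype=float)
    if times is None:
        us = (np.arange(len(xyz), dtype=np.int64) * 1_000_000) // int(rate)
        times = pd.Timestamp(start) + pd.to_timedelta(us, unit="us")
    df = pd.DataFrame({"x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2]},
                      index=pd.DatetimeIndex(times, name="timestamp"))
    return RawRecording(participant=participant, period=period, rate=rate, samples=df)


def make_epoch_series(day_specs, participant="p01", period="pre"):
    """Build a labeled EpochSeries from per-day specs.

    Each spec is (start_hour, labels) where labels is a sequence of intensity
    labels or None (missing second), laid out contiguously from start_hour on
    consecutive days starting 2021-03-01.
    """
    frames = []
    for day, (start_hour, labels) in enumerate(day_specs):
        t0 = pd.Timestamp("2021-03-01") + pd.Timedelta(days=day, hours=start_hour)
        idx = t0 + pd.to_timedelta(np.arange(len(labels)), unit="s")
        lab = pd.array([pd.NA if v is None else v for v in labels], dtype="string")
        svm = np.where(pd.isna(lab), np.nan, 1.0)
        frames.append(pd.DataFrame(
            {"svm": svm, "label": lab, "day_index": day}, index=idx))
    epochs = pd.concat(frames)
    epochs.index.name = "timestamp"
    return EpochSeries(participant, period, epochs)
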