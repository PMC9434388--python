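"""Epoching, intensity classification, wear-protocol, and raw CSV I/O."""

import numpy as np
import pandas as pd
import pytest

from actibout import (
    CutPoints,
    WearRules,
    assess_wear,
    classify_intensity,
    compute_svm_epochs,
    read_raw_csv,
    synthesize_raw,
    write_raw_csv,
)
from conftest import make_epoch_series, make_recording


class TestSVMEpochs:
    @pytest.mark.parametrize(
        "samples, rate, expected_svm",
        [
            ([(0, 0, 1)] * 60, 60, 0.0),  # resting unit gravity
            ([(0, 0, 2)], 1, 1.0),  # |2 - 1|
            ([(0, 1.5 / np.sqrt(2), 1.5 / np.sqrt(2))] * 60, 60, 30.0),  # 60 x 0.5
        ],
    )
    def test_known_aggregates(self, samples, rate, expected_svm):
        rec = make_recording(samples, rate=rate)
        es = compute_svm_epochs(rec)
        assert es.epochs["svm"].iloc[0] == pytest.approx(expected_svm, abs=1e-12)

    def test_uncovered_seconds_are_missing(self):
        times = pd.to_datetime(
            ["2021-03-01 08:00:00.000000", "2021-03-01 08:00:00.500000",
             "2021-03-01 08:00:02.000000"]
        )
        rec = make_recording([(0, 0, 1)] * 3, times=times)
        es = compute_svm_epochs(rec)
        assert len(es) == 3
        assert np.isnan(es.epochs["svm"].iloc[1])
        assert es.epochs["svm"].notna().sum() == 2

    def test_brute_force_oracle_agrees(self):
        rng = np.random.default_rng(7)
        xyz = rng.normal(0, 0.8, size=(600, 3)) + [0, 0, 1]
        rec = make_recording(xyz, rate=60)
        es = compute_svm_epochs(rec)
        # independent per-sample scan
        expected = {}
        for t, row in rec.samples.iterrows():
            sec = t.floor("s")
            mag = np.sqrt(row.x**2 + row.y**2 + row.z**2)
            expected[sec] = expected.get(sec, 0.0) + abs(mag - 1.0)
        for sec, val in expected.items():
            assert es.epochs.loc[sec, "svm"] == pytest.approx(val, abs=1e-9)

    def test_no_gravity_subtraction_mode(self):
        rec = make_recording([(0, 0, 1)] * 60, rate=60)
        es = compute_svm_epochs(rec, subtract_gravity=False)
        assert es.epochs["svm"].iloc[0] == pytest.approx(60.0)

    def test_bad_epoch_length_rejected(self):
        rec = make_recording([(0, 0, 1)] * 10, rate=10)
        with pytest.raises(ValueError):
            compute_svm_epochs(rec, epoch_length=0)


class TestClassification:
    def test_bands_and_boundaries(self):
        cp = CutPoints(sedentary_upper=0.5, light_upper=1.5)
        es = make_epoch_series([(8, ["sedentary"] * 4)])
        es.epochs["svm"] = [0.0, 0.49, 0.5, 1.5]
        labeled = classify_intensity(es, cp)
        assert list(labeled.epochs["label"]) == ["sedentary", "sedentary", "light", "MVPA"]

    def test_missing_epochs_stay_missing_and_partition(self, cutpoints):
        rng = np.random.default_rng(3)
        es = make_epoch_series([(8, ["sedentary"] * 100)])
        svm = rng.uniform(0, 40, size=100)
        svm[::7] = np.nan
        es.epochs["svm"] = svm
        labeled = classify_intensity(es, cutpoints)
        missing = labeled.epochs["svm"].isna()
        assert labeled.epochs.loc[missing, "label"].isna().all()
        counts = labeled.epochs["label"].value_counts()
        assert counts.sum() == (~missing).sum()  # every non-missing epoch labeled once

    def test_synthesized_single_class_day(self, cutpoints):
        labels = np.array(["light"] * 120, dtype=object)
        rec = synthesize_raw(labels, cutpoints, rate=30, seed=5)
        labeled = classify_intensity(compute_svm_epochs(rec), cutpoints)
        assert (labeled.epochs["label"] == "light").all()


class TestWearProtocol:
    def _day(self, hours, sed_frac, start_hour=7.0):
        n = int(hours * 3600)
        n_sed = int(round(n * sed_frac))
        return (start_hour, ["sedentary"] * n_sed + ["light"] * (n - n_sed))

    def test_short_day_invalid(self):
        es = make_epoch_series([self._day(9, 0.5)])
        assert assess_wear(es).day_flags[0] == "invalid_short"

    def test_ten_hour_day_valid(self):
        es = make_epoch_series([self._day(10, 0.5)])
        assert assess_wear(es).day_flags[0] == "valid"

    def test_all_sedentary_daytime_is_nonwear(self):
        es = make_epoch_series([self._day(12, 1.0)])
        assert assess_wear(es).day_flags[0] == "nonwear"

    @pytest.mark.parametrize("frac, flag", [(0.79, "valid"), (0.81, "nonwear")])
    def test_sedentary_fraction_threshold_is_strict(self, frac, flag):
        # 14 h of data lying entirely inside the 06:00-21:00 window
        es = make_epoch_series([self._day(14, frac)])
        assert assess_wear(es).day_flags[0] == flag

    def test_participant_needs_three_valid_days(self):
        days = [self._day(12, 0.5), self._day(12, 0.5), self._day(9, 0.5)]
        wear = assess_wear(make_epoch_series(days))
        assert not wear.participant_valid
        wear = assess_wear(make_epoch_series(days[:2] + [self._day(12, 0.5)]))
        assert wear.participant_valid

    def test_adding_data_never_invalidates_short(self):
        base = self._day(10, 0.5)
        extended = (base[0], base[1] + ["light"] * 3600)
        assert assess_wear(make_epoch_series([base])).day_flags[0] == "valid"
        assert assess_wear(make_epoch_series([extended])).day_flags[0] != "invalid_short"

    def test_unlabeled_or_empty_series_rejected(self):
        es = make_epoch_series([self._day(10, 0.5)])
        es.epochs["label"] = pd.array([pd.NA] * len(es), dtype="string")
        with pytest.raises(ValueError):
            assess_wear(es)

    def test_custom_rules(self):
        es = make_epoch_series([self._day(9, 0.5)])
        rules = WearRules(min_hours_per_day=8, min_valid_days=1)
        wear = assess_wear(es, rules)
        assert wear.day_flags[0] == "valid" and wear.participant_valid


class TestRawCSV:
    def test_small_file_parses(self, tmp_path):
        p = tmp_path / "p02_pre.csv"
        p.write_text(
            "timestamp_iso8601,x_g,y_g,z_g\n"
            "2021-03-01T08:00:00.000000,0.0,0.0,1.0\n"
            "2021-03-01T08:00:00.500000,0.1,0.0,1.0\n"
            "2021-03-01T08:00:01.000000,0.0,0.2,1.0\n"
        )
        rec = read_raw_csv(p)
        assert len(rec) == 3
        assert rec.participant == "p02" and rec.period == "pre"
        assert rec.rate == pytest.approx(2.0)

    def test_write_read_round_trip(self, tmp_path, cutpoints):
        rec = synthesize_raw(np.array(["MVPA"] * 30, dtype=object), cutpoints,
                             rate=60, seed=11)
        path = write_raw_csv(rec, tmp_path / "synthetic_pre.csv")
        back = read_raw_csv(path, participant=rec.participant, period=rec.period)
        assert np.allclose(back.samples.to_numpy(), rec.samples.to_numpy(), atol=1e-9)
        assert (back.samples.index == rec.samples.index).all()

    def test_non_monotone_timestamps_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "timestamp_iso8601,x_g,y_g,z_g\n"
            "2021-03-01T08:00:01,0,0,1\n"
            "2021-03-01T08:00:00,0,0,1\n"
        )
        with pytest.raises(ValueError, match="increasing"):
            read_raw_csv(p)

    def test_unknown_header_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("time,x,y,z\n2021-03-01T08:00:00,0,0,1\n")
        with pytest.raises(ValueError, match="header"):
            read_raw_csv(p)

    def test_malformed_rows_reported_with_line_numbers(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "timestamp_iso8601,x_g,y_g,z_g\n"
            "2021-03-01T08:00:00,0,0,1\n"
            "2021-03-01T08:00:01,oops,0,1\n"
        )
        with pytest.raises(ValueError, match=r"lines \[3\]"):
            read_raw_csv(p)
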