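import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from circarest import ingest, synthio
from circarest.series import ActivitySeries, MinuteSeries, TemperatureSeries

START = pd.Timestamp("2024-03-04 12:00:00")


def _write_csv(path, rows):
    path.write_text("timestamp,value\n" + "\n".join(rows) + "\n")


class TestReadSeries:
    def test_complete_grid(self, tmp_path):
        f = tmp_path / "a.csv"
        _write_csv(f, ["2024-03-04T12:00:00,1", "2024-03-04T12:01:00,2",
                       "2024-03-04T12:02:00,3"])
        s = ingest.read_series(f, "activity")
        assert s.n == 3 and not s.missing.any()
        assert np.array_equal(s.values, [1, 2, 3])

    def test_gap_becomes_masked_entry(self, tmp_path):
        f = tmp_path / "a.csv"
        _write_csv(f, ["2024-03-04T12:00:00,1", "2024-03-04T12:02:00,3"])
        s = ingest.read_series(f, "activity")
        assert s.n == 3
        assert list(s.missing) == [False, True, False]

    def test_non_monotone_rejected_with_row(self, tmp_path):
        f = tmp_path / "a.csv"
        _write_csv(f, ["2024-03-04T12:01:00,1", "2024-03-04T12:00:00,2"])
        with pytest.raises(ingest.IngestError, match="row 2"):
            ingest.read_series(f, "activity")

    def test_unknown_kind_rejected(self, tmp_path):
        with pytest.raises(ingest.IngestError, match="kind"):
            ingest.read_series(tmp_path / "a.csv", "heartrate")

    def test_round_trip_preserves_record(self, robust_record, tmp_path):
        ingest.write_series(robust_record.activity, tmp_path / "a.csv")
        back = ingest.read_series(tmp_path / "a.csv", "activity")
        assert back.start == robust_record.activity.start
        assert np.array_equal(back.values, robust_record.activity.values)
        assert not back.missing.any()

    def test_diary_and_saliva_round_trip(self, robust_record, tmp_path):
        ingest.write_diary(robust_record.diary, tmp_path / "d.csv")
        diary = ingest.read_diary(tmp_path / "d.csv")
        assert len(diary) == len(robust_record.diary)
        assert all(a.retiring == b.retiring and a.exercise == b.exercise
                   for a, b in zip(diary, robust_record.diary))
        ingest.write_saliva([robust_record.cortisol, robust_record.melatonin],
                            tmp_path / "s.csv")
        mel = ingest.read_saliva(tmp_path / "s.csv", "melatonin")
        assert np.allclose(mel.concentrations,
                           robust_record.melatonin.concentrations)


class TestDetectMissingSpans:
    def test_constant_body_temperature_not_flagged(self):
        temp = TemperatureSeries(start=START, values=np.full(120, 35.0),
                                 missing=np.zeros(120, bool))
        mask = ingest.detect_missing_spans(temp)
        assert not mask.any()

    def test_decay_short_of_room_temperature_not_flagged(self):
        v = np.full(120, 35.0)
        v[40:80] = 30.0  # never within 2 degC of the 21 degC room default
        temp = TemperatureSeries(start=START, values=v,
                                 missing=np.zeros(120, bool))
        assert not ingest.detect_missing_spans(temp).any()

    def test_injected_spans_recovered(self, robust_record):
        rec = synthio.inject_missingness(robust_record, 1.0)
        mask = ingest.detect_missing_spans(rec.temperature, rec.activity)
        new = mask & ~rec.temperature.missing
        inj = rec.offbody_truth
        assert (new & inj).sum() / inj.sum() >= 0.90
        assert (new & ~inj).sum() / (~inj).sum() < 0.02

    def test_span_at_series_start_detected_by_plateau(self):
        v = np.full(120, 35.0)
        v[:20] = 21.2  # sensor off from the very first minute
        temp = TemperatureSeries(start=START, values=v,
                                 missing=np.zeros(120, bool))
        mask = ingest.detect_missing_spans(temp)
        assert mask[:20].all() and not mask[25:].any()

    def test_fully_missing_rejected(self):
        temp = TemperatureSeries(start=START, values=np.zeros(60),
                                 missing=np.ones(60, bool))
        with pytest.raises(ingest.IngestError, match="no analyzable"):
            ingest.detect_missing_spans(temp)


class TestAggregate:
    def test_constant_series(self):
        s = ActivitySeries(start=START, values=np.full(60, 10.0),
                           missing=np.zeros(60, bool))
        agg = s and ingest.aggregate(s, 5, "mean")
        assert np.array_equal(agg.values, np.full(12, 10.0))
        assert agg.step_min == 5

    def test_majority_missing_bin_is_missing(self):
        miss = np.ones(60, bool)
        miss[:5] = False  # 5 present + 55 missing in an hourly bin
        s = ActivitySeries(start=START, values=np.full(60, 3.0), missing=miss)
        agg = ingest.aggregate(s, 60, "mean")
        assert agg.missing[0]

    def test_exactly_half_missing_bin_is_missing(self):
        miss = np.zeros(60, bool)
        miss[:30] = True
        s = ActivitySeries(start=START, values=np.full(60, 3.0), missing=miss)
        assert ingest.aggregate(s, 60, "mean").missing[0]

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_hourly_mean_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.gamma(1.0, 20.0, 180)
        miss = rng.random(180) < 0.3
        s = ActivitySeries(start=START, values=v, missing=miss)
        agg = ingest.aggregate(s, 60, "mean")
        for b in range(3):
            sel = slice(60 * b, 60 * (b + 1))
            ok = ~miss[sel]
            if ok.sum() <= 30:
                assert agg.missing[b]
            else:
                assert agg.values[b] == pytest.approx(v[sel][ok].mean())

    def test_bin_must_divide_day(self):
        s = ActivitySeries(start=START, values=np.zeros(120),
                           missing=np.zeros(120, bool))
        with pytest.raises(ingest.IngestError):
            ingest.aggregate(s, 7, "mean")


class TestInterpolate:
    def test_interior_gap_linear(self):
        s = MinuteSeries(start=START, values=np.array([1.0, 0.0, 3.0]),
                         missing=np.array([False, True, False]), step_min=60)
        out = ingest.interpolate_missing(s)
        assert np.allclose(out.series.values, [1, 2, 3])
        assert out.fraction_interpolated == pytest.approx(1 / 3)

    def test_no_gaps_identity(self):
        s = MinuteSeries(start=START, values=np.arange(5.0),
                         missing=np.zeros(5, bool), step_min=60)
        out = ingest.interpolate_missing(s)
        assert np.array_equal(out.series.values, np.arange(5.0))
        assert out.fraction_interpolated == 0.0

    def test_beats_zero_fill_on_gappy_sinusoid(self, rng):
        t = np.arange(168.0)
        truth = 10 + 5 * np.cos(2 * np.pi * t / 24)
        miss = rng.random(168) < 0.10
        miss[0] = miss[-1] = False
        s = MinuteSeries(start=START, values=np.where(miss, 0, truth),
                         missing=miss, step_min=60)
        out = ingest.interpolate_missing(s)
        rmse = np.sqrt(np.mean((out.series.values - truth) ** 2))
        rmse_zero = np.sqrt(np.mean((np.where(miss, 0, truth) - truth) ** 2))
        assert rmse < rmse_zero

    def test_interpolation_stays_within_neighbor_hull(self, rng):
        v = rng.normal(0, 1, 50)
        miss = np.zeros(50, bool)
        miss[10:14] = True
        s = MinuteSeries(start=START, values=np.where(miss, np.nan, v),
                         missing=miss, step_min=60)
        out = ingest.interpolate_missing(s).series
        lo, hi = sorted((v[9], v[14]))
        assert np.all(out.values[10:14] >= lo - 1e-12)
        assert np.all(out.values[10:14] <= hi + 1e-12)

    def test_warning_above_30_percent(self):
        miss = np.zeros(10, bool)
        miss[2:6] = True
        s = MinuteSeries(start=START, values=np.arange(10.0), missing=miss,
                         step_min=60)
        out = ingest.interpolate_missing(s)
        assert out.warning is not None


def test_masks_only_grow(robust_record):
    rec = synthio.inject_missingness(robust_record, 1.0)
    before = rec.activity.missing.copy()
    mask = ingest.detect_missing_spans(rec.temperature, rec.activity)
    after = ingest.apply_mask(rec.activity, mask).missing
    assert np.all(after >= before)
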