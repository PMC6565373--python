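"""Semitone metrics and the nested pitch data model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from songboot.pitch import (
    PitchDataError,
    PitchDataset,
    Timeline,
    compute_baseline,
    daily_trajectory,
    hz_to_semitones,
    washout_delta,
    washout_delta_mean,
    weighted_group_mean,
)

from conftest import flat_syllable, make_dataset


class TestBaseline:
    def test_mean_of_baseline_records(self):
        rows = [("b0", "s0", "baseline", d, hz) for d, hz in ((1, 100.0), (2, 110.0), (3, 120.0))]
        ds = make_dataset(rows)
        assert compute_baseline(ds).loc[("b0", "s0"), "baseline_hz"] == pytest.approx(110.0)

    def test_identical_baseline(self):
        rows = [("b0", "s0", "baseline", d, 2500.0) for d in (1, 2, 3)]
        assert compute_baseline(make_dataset(rows)).iloc[0, 0] == 2500.0

    def test_extended_baseline_uses_last_three_days(self):
        # 6-day baseline: days 1-3 at 100 Hz must be ignored
        tl = Timeline(baseline_days=6)
        rows = [("b0", "s0", "baseline", d, 100.0) for d in (1, 2, 3)]
        rows += [("b0", "s0", "baseline", d, 200.0) for d in (4, 5, 6)]
        assert compute_baseline(make_dataset(rows, tl)).iloc[0, 0] == pytest.approx(200.0)

    def test_syllable_without_baseline_is_rejected(self):
        rows = flat_syllable("b0", "s0", [("baseline", 1)], 100.0)
        rows += flat_syllable("b0", "s1", [("shift", 5)], 100.0)  # no baseline
        with pytest.raises(PitchDataError, match="baseline"):
            make_dataset(rows)


class TestSemitoneConversion:
    @pytest.mark.parametrize(
        "pitch,base,expected",
        [
            (440.0, 440.0, 0.0),
            (220.0 * 2 ** (1 / 12), 220.0, 1.0),
            (220.0, 110.0, 12.0),
            (110.0, 220.0, -12.0),
        ],
    )
    def test_reference_values(self, pitch, base, expected):
        assert hz_to_semitones(pitch, base) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("bad", [(0.0, 440.0), (440.0, -1.0)])
    def test_nonpositive_inputs_rejected(self, bad):
        with pytest.raises(PitchDataError):
            hz_to_semitones(*bad)

    @given(
        a=st.floats(50, 5000), b=st.floats(0.1, 10), c=st.floats(50, 5000)
    )
    @settings(max_examples=100, deadline=None)
    def test_log_ratio_antisymmetry_and_additivity(self, a, b, c):
        assert hz_to_semitones(a * b, a) + hz_to_semitones(a, a * b) == pytest.approx(0, abs=1e-9)
        chained = hz_to_semitones(a, c)
        via = hz_to_semitones(a, a * b) + hz_to_semitones(a * b, c)
        assert via == pytest.approx(chained, abs=1e-9)


class TestWeightedGroupMean:
    def test_all_at_baseline_is_zero(self, constant_dataset):
        assert weighted_group_mean(constant_dataset, [12, 13, 14]) == pytest.approx(0.0, abs=1e-12)

    def test_frequency_weighting_pools_iterations(self):
        # 10 iterations at +1 st and 30 at -1 st: pooled mean (10 - 30)/40
        base = [("b0", s, "baseline", d, 100.0) for s in ("s0", "s1") for d in (1, 2, 3)]
        up = [("b0", "s0", "shift", 12, 100.0 * 2 ** (1 / 12))] * 10
        down = [("b0", "s1", "shift", 12, 100.0 * 2 ** (-1 / 12))] * 30
        ds = make_dataset(base + up + down)
        assert weighted_group_mean(ds, [12]) == pytest.approx(-0.5, abs=1e-9)

    def test_two_birds_at_same_offset(self):
        rows = []
        for bird in ("b0", "b1"):
            rows += [(bird, "s0", "baseline", d, 500.0) for d in (1, 2, 3)]
            rows += [(bird, "s0", "shift", 12, 500.0 * 2 ** (0.2 / 12))] * 7
        assert weighted_group_mean(make_dataset(rows), [12]) == pytest.approx(0.2, abs=1e-9)

    def test_per_bird_averaging_differs_from_pooling(self):
        rows = [("b0", "s0", "baseline", d, 100.0) for d in (1, 2, 3)]
        rows += [("b1", "s0", "baseline", d, 100.0) for d in (1, 2, 3)]
        rows += [("b0", "s0", "shift", 12, 100.0 * 2 ** (1 / 12))] * 90
        rows += [("b1", "s0", "shift", 12, 100.0 * 2 ** (-1 / 12))] * 10
        ds = make_dataset(rows)
        assert weighted_group_mean(ds, [12]) == pytest.approx(0.8, abs=1e-9)
        assert weighted_group_mean(ds, [12], per_bird=True) == pytest.approx(0.0, abs=1e-9)

    def test_empty_window_errors(self, constant_dataset):
        with pytest.raises(PitchDataError):
            weighted_group_mean(constant_dataset, [])


class TestDailyTrajectory:
    def test_constant_dataset_gives_zero_series(self, constant_dataset):
        traj = daily_trajectory(constant_dataset)
        assert len(traj) == constant_dataset.timeline.total_days
        assert np.allclose(traj["mean_semitones"], 0.0)

    def test_missing_day_is_nan(self):
        rows = [("b0", "s0", "baseline", d, 100.0) for d in (1, 2, 3)]
        rows += [("b0", "s0", "shift", 1, 100.0)] * 3  # bird sang only shift day 1
        traj = daily_trajectory(make_dataset(rows))
        shift = traj[traj["epoch"] == "shift"].set_index("day")
        assert shift.loc[1, "mean_semitones"] == pytest.approx(0.0)
        assert np.isnan(shift.loc[2, "mean_semitones"])
        assert shift.loc[2, "n_records"] == 0

    def test_noiseless_linear_ramp_recovered(self):
        ramp = {d: d / 14.0 for d in range(1, 15)}
        rows = [("b0", "s0", "baseline", d, 300.0) for d in (1, 2, 3)]
        for d, s in ramp.items():
            rows += [("b0", "s0", "shift", d, 300.0 * 2 ** (s / 12.0))] * 4
        traj = daily_trajectory(make_dataset(rows))
        shift = traj[traj["epoch"] == "shift"].set_index("day")["mean_semitones"]
        for d, s in ramp.items():
            assert shift.loc[d] == pytest.approx(s, abs=1e-9)
        assert shift.is_monotonic_increasing


class TestWashoutDelta:
    def test_washout_identical_to_last_shift_day(self, constant_dataset):
        deltas = washout_delta(constant_dataset)
        assert np.allclose(deltas["delta_st"], 0.0, atol=1e-12)

    def test_return_toward_baseline_reads_minus_one(self):
        rows = [("b0", "s0", "baseline", d, 100.0) for d in (1, 2, 3)]
        rows += [("b0", "s0", "shift", 14, 100.0 * 2 ** (1 / 12))] * 5
        rows += [("b0", "s0", "washout", 1, 100.0)] * 5
        deltas = washout_delta(make_dataset(rows))
        assert np.allclose(deltas["delta_st"], -1.0, atol=1e-9)

    def test_per_syllable_references_differ(self):
        # both syllables wash out at baseline; refs +1 and +0.5 st
        rows = []
        for syll, ref in (("s0", 1.0), ("s1", 0.5)):
            rows += [("b0", syll, "baseline", d, 200.0) for d in (1, 2, 3)]
            rows += [("b0", syll, "shift", 14, 200.0 * 2 ** (ref / 12))] * 4
            rows += [("b0", syll, "washout", 7, 200.0)] * 4
        deltas = washout_delta(make_dataset(rows)).groupby("syllable_id")["delta_st"].mean()
        assert deltas["s0"] == pytest.approx(-1.0, abs=1e-9)
        assert deltas["s1"] == pytest.approx(-0.5, abs=1e-9)

    def test_fallback_to_most_recent_sung_shift_day(self):
        rows = [("b0", "s0", "baseline", d, 100.0) for d in (1, 2, 3)]
        rows += [("b0", "s0", "shift", 10, 100.0 * 2 ** (2 / 12))] * 4  # silent on day 14
        rows += [("b0", "s0", "washout", 1, 100.0)] * 4
        deltas = washout_delta(make_dataset(rows))
        assert (deltas["reference_day"] == 10).all()
        assert np.allclose(deltas["delta_st"], -2.0, atol=1e-9)

    def test_washout_mean_over_window(self, constant_dataset):
        assert washout_delta_mean(constant_dataset, [6, 7]) == pytest.approx(0.0, abs=1e-12)

    def test_syllable_without_shift_records_errors(self):
        rows = [("b0", "s0", "baseline", d, 100.0) for d in (1, 2, 3)]
        rows += [("b0", "s0", "washout", 1, 100.0)] * 2
        with pytest.raises(PitchDataError, match="shift"):
            washout_delta(make_dataset(rows))


class TestDatasetContract:
    def test_csv_round_trip(self, tmp_path, constant_dataset):
        path = tmp_path / "pitch.csv"
        constant_dataset.to_csv(path)
        back = PitchDataset.from_csv(path)
        pd.testing.assert_frame_equal(
            back.records, constant_dataset.records[back.records.columns]
        )

    def test_nonpositive_pitch_rejected(self):
        with pytest.raises(PitchDataError):
            make_dataset([("b0", "s0", "baseline", 1, -5.0)])

    def test_day_outside_timeline_rejected(self):
        rows = [("b0", "s0", "baseline", d, 100.0) for d in (1, 2, 3)]
        rows += [("b0", "s0", "shift", 15, 100.0)]
        with pytest.raises(PitchDataError):
            make_dataset(rows)

    def test_unknown_epoch_rejected(self):
        with pytest.raises(PitchDataError):
            make_dataset([("b0", "s0", "preshift", 1, 100.0)])
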