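"""Ground-truth fidelity of the synthetic cohort and OD-section generators."""

import io
from dataclasses import replace

import numpy as np
import pytest

from songboot.pitch import Timeline, compute_baseline, daily_trajectory, weighted_group_mean
from songboot.simulate import (
    PRESET_NAMES,
    GeneratorTruth,
    ODGeneratorTruth,
    generate_experiment,
    generate_od_sections,
    preset,
)
from songboot.lesion import lesion_extent, lesion_threshold, od_ratio

FAST = dict(syllables_per_bird_range=(4, 6), iterations_per_day_range=(40, 60))


def noiseless(truth):
    return replace(truth, sigma_bird=0.0, sigma_syllable=0.0, sigma_iteration=0.0)


class TestGenerateExperiment:
    def test_seed_determinism_byte_for_byte(self):
        truth = replace(preset("unlesioned_plus1", seed=11), **FAST)
        bufs = []
        for _ in range(2):
            buf = io.StringIO()
            generate_experiment(truth).records.to_csv(buf, index=False)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]
        other = generate_experiment(replace(truth, seed=12))
        assert not other.records["pitch_hz"].equals(generate_experiment(truth).records["pitch_hz"])

    def test_zero_noise_zero_effect_sits_at_baseline(self):
        truth = noiseless(GeneratorTruth(n_birds=2, seed=3, **FAST))
        ds = generate_experiment(truth)
        traj = daily_trajectory(ds)
        assert np.allclose(traj["mean_semitones"], 0.0, atol=1e-9)

    def test_instant_drift_plateau_reads_asymptote(self):
        truth = noiseless(
            GeneratorTruth(n_birds=2, drift_asymptote=-1.0, drift_timescale=1e-9, seed=4, **FAST)
        )
        ds = generate_experiment(truth)
        for day in (1, 7, 14):
            assert weighted_group_mean(ds, [day]) == pytest.approx(-1.0, abs=1e-9)

    def test_counts_within_configured_ranges(self):
        truth = GeneratorTruth(n_birds=3, seed=5, **FAST)
        ds = generate_experiment(truth)
        per_syll_day = ds.records.groupby(["bird_id", "syllable_id", "epoch", "day"]).size()
        assert per_syll_day.between(40, 60).all()
        per_bird = ds.records.groupby("bird_id")["syllable_id"].nunique()
        assert per_bird.between(4, 6).all()

    def test_baseline_f0_within_range(self):
        truth = noiseless(GeneratorTruth(n_birds=3, seed=6, **FAST))
        ds = generate_experiment(truth)
        baselines = compute_baseline(ds)["baseline_hz"]
        assert ((baselines >= 1000.0) & (baselines <= 6000.0)).all()

    def test_variance_decomposition(self):
        # no iteration noise -> zero within-syllable-day variance
        truth = replace(GeneratorTruth(n_birds=3, drift_asymptote=-0.5, seed=7, **FAST),
                        sigma_iteration=0.0)
        ds = generate_experiment(truth)
        within = ds.records.groupby(["bird_id", "syllable_id", "epoch", "day"])["pitch_hz"].std()
        assert np.allclose(within.fillna(0.0), 0.0, atol=1e-9)
        # no bird/syllable effects -> between-bird spread shrinks with data size
        truth2 = replace(
            GeneratorTruth(n_birds=4, drift_asymptote=-0.5, seed=8,
                           syllables_per_bird_range=(8, 12),
                           iterations_per_day_range=(200, 300)),
            sigma_bird=0.0, sigma_syllable=0.0,
        )
        ds2 = generate_experiment(truth2)
        win = truth2.timeline.end_of_shift_days(3)
        per_bird = [
            weighted_group_mean(ds2, win, per_bird=False)  # pooled reference
        ]
        bl = compute_baseline(ds2)
        from songboot.pitch import _semitone_series

        df = ds2.subset("shift", win)
        s = _semitone_series(df, bl)
        bird_means = s.groupby(df["bird_id"]).mean()
        assert bird_means.std() < 0.02

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            GeneratorTruth(syllables_per_bird_range=(6, 4))
        with pytest.raises(ValueError):
            GeneratorTruth(sigma_bird=-0.1)


class TestPresets:
    #: printed plateau (shift days 12-14) per group, semitones
    PLATEAUS = {
        "unlesioned_plus1": -0.40,
        "unlesioned_minus1": 0.36,
        "unlesioned_noshift": 0.0,
        "lesioned_plus1": -0.38,
        "lesioned_minus1": -0.46,
        "lesioned_noshift": -0.19,
    }
    BIRDS = {
        "unlesioned_plus1": 3,
        "unlesioned_minus1": 3,
        "unlesioned_noshift": 2,
        "lesioned_plus1": 4,
        "lesioned_minus1": 4,
        "lesioned_noshift": 8,
    }
    WASHOUT_DELTAS = {
        "unlesioned_plus1": 0.17,
        "unlesioned_minus1": -0.22,
        "lesioned_plus1": 0.24,
        "lesioned_minus1": -0.28,
    }

    @pytest.mark.parametrize("name", PRESET_NAMES)
    def test_latent_plateau_matches_group_value(self, name):
        t = preset(name)
        assert t.n_birds == self.BIRDS[name]
        win = t.timeline.end_of_shift_days(3)
        assert t.expected_group_mean(win) == pytest.approx(self.PLATEAUS[name], abs=1e-12)

    @pytest.mark.parametrize("name", sorted(WASHOUT_DELTAS))
    def test_latent_washout_delta_matches_group_value(self, name):
        t = preset(name)
        assert t.expected_washout_delta() == pytest.approx(self.WASHOUT_DELTAS[name], abs=1e-12)

    def test_noshift_presets_have_no_adaptation(self):
        assert preset("unlesioned_noshift").drift_asymptote == 0.0
        assert preset("unlesioned_noshift").adapt_asymptote == 0.0
        assert preset("lesioned_noshift").adapt_asymptote == 0.0

    @pytest.mark.parametrize("name", PRESET_NAMES)
    def test_noiseless_trajectory_equals_latent_mean(self, name):
        t = replace(noiseless(preset(name, seed=9)), **FAST)
        ds = generate_experiment(t)
        traj = daily_trajectory(ds)
        for _, row in traj.iterrows():
            latent = t.latent_mean(row["epoch"], np.array([row["day"]]))[0]
            assert row["mean_semitones"] == pytest.approx(latent, abs=1e-9)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            preset("saline")


class TestODSections:
    def test_identical_distributions_give_five_percent(self):
        truth = ODGeneratorTruth(
            sections_per_bird=800, lesion_mean=1.4, target_below_threshold_fraction=None, seed=1
        )
        df = generate_od_sections(truth)
        ratios = od_ratio(df["od_areax"].to_numpy(), df["od_striatum"].to_numpy())
        thr = lesion_threshold(ratios[df["group"] == "saline"])
        frac, _ = lesion_extent(ratios[df["group"] == "lesioned"], thr)
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_target_fraction_recovered_at_scale(self):
        truth = ODGeneratorTruth(sections_per_bird=500, seed=2)  # target 0.375
        df = generate_od_sections(truth)
        ratios = od_ratio(df["od_areax"].to_numpy(), df["od_striatum"].to_numpy())
        thr = lesion_threshold(ratios[df["group"] == "saline"])
        frac, _ = lesion_extent(ratios[df["group"] == "lesioned"], thr)
        assert frac == pytest.approx(0.375, abs=0.04)

    def test_disjoint_supports_give_total_lesion(self):
        truth = ODGeneratorTruth(
            sections_per_bird=50, lesion_mean=0.2,
            target_below_threshold_fraction=None, seed=3,
        )
        df = generate_od_sections(truth)
        ratios = od_ratio(df["od_areax"].to_numpy(), df["od_striatum"].to_numpy())
        thr = lesion_threshold(ratios[df["group"] == "saline"])
        frac, _ = lesion_extent(ratios[df["group"] == "lesioned"], thr)
        assert frac == 1.0

    def test_seed_determinism(self):
        t = ODGeneratorTruth(sections_per_bird=20, seed=4)
        a, b = generate_od_sections(t), generate_od_sections(t)
        assert a.equals(b)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2])
    def test_infeasible_target_rejected(self, bad):
        with pytest.raises(ValueError):
            ODGeneratorTruth(target_below_threshold_fraction=bad)
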