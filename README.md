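# songboot

Hierarchical bootstrap analysis of songbird vocal pitch-shift experiments.

When adult Bengalese finches hear their own song pitch-shifted through
headphones, intact birds adapt by shifting pitch opposite the perturbation,
while dopamine-depleted birds (6-OHDA lesions of Area X) drift downward
regardless. The data from such experiments are deeply nested — a handful of
birds, 4–12 syllables per bird, 40–600 renditions of each syllable per day —
so a pooled standard error wildly overstates the information content.
`songboot` implements the statistical machinery these experiments need, for
behavioral neuroscientists and anyone analyzing similarly nested data:

* **Semitone pitch metrics** — s = 12·log₂(pitch/baseline) against each
  syllable's 3-day baseline; frequency-weighted group means; daily
  trajectories; washout Δ(Pitch) relative to the last shift day.
* **Three-level hierarchical bootstrap** — resample birds, then syllables,
  then iterations (equalized per-syllable counts, baselines recomputed per
  subsample in Hz); the sd of N = 10⁴ subsample means is the SEM and their
  central 67% interval the reported uncertainty.
* **Posterior-probability tests** — P(group ≥ constant) and exact all-pairs
  P(group A ≥ group B) from the joint bootstrap distribution (unity line
  included), two-way significance at 0.025/0.975 with Bonferroni correction.
* **Nested random-intercept LMM** (REML, bird and syllable-within-bird) as
  an independent frequentist cross-check.
* **Lesion-extent metric** — OD(Area X)/OD(striatum) per section, saline
  5th-percentile threshold, two-sample KS test, lesion–behavior Pearson
  correlations.
* **Synthetic cohort generator** — latent drift + adaptation dynamics with
  bird/syllable/iteration variance components and calibrated presets, so the
  whole pipeline is testable for parameter recovery without raw recordings.

## Worked example

```python
from songboot import (preset, generate_experiment, bootstrap_distribution,
                      bootstrap_washout, prob_ge_constant)

truth = preset("unlesioned_plus1", seed=1)   # 3 birds, +1 st feedback shift
ds = generate_experiment(truth)
win = ds.timeline.end_of_shift_days(3)       # shift days 12-14

boot = bootstrap_distribution(ds, win, n_resamples=10_000, seed=2)
test = prob_ge_constant(boot, 0.0)
print(f"end-of-shift pitch change: {boot.point_estimate:+.2f} st "
      f"(SEM {boot.sem:.2f}, 67% CI [{boot.ci67[0]:+.2f}, {boot.ci67[1]:+.2f}])")
print(f"P(mean >= 0) {test.render_probability()}  significant={test.significant}")

wash = bootstrap_washout(ds, n_resamples=10_000, seed=3)
print(f"washout rebound (last 2 d vs last shift day): "
      f"{wash.point_estimate:+.2f} st (SEM {wash.sem:.2f})")
```

prints

```
end-of-shift pitch change: -0.49 st (SEM 0.12, 67% CI [-0.58, -0.30])
P(mean >= 0) p < 0.0001  significant=True
washout rebound (last 2 d vs last shift day): +0.18 st (SEM 0.02)
```

The cohort was generated with a latent adaptation plateau of −0.40 st; this
particular 3-bird draw lands at −0.49 st, within one hierarchical SEM of the
truth, and the bootstrap test resolves the direction at its 1/N resolution
bound. The washout rebound (latent +0.17 st) is recovered as +0.18 st. The
same functions accept your own long-format CSV
(`bird_id,syllable_id,day,epoch,pitch_hz`) via `PitchDataset.from_csv`.

A command-line interface mirrors the library:

```sh
songboot generate --preset lesioned_noshift --seed 1 --out data/
songboot analyze data/lesioned_noshift_pitch.csv --seed 2
songboot run --config experiment.yaml --seed 1 --out results/
```

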