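# Methods

## The problem

Adult songbirds (Bengalese finches) maintain song pitch using auditory
feedback. When headphones shift the pitch of that feedback by ±1 semitone,
intact birds compensate adaptively over days; dopamine-depleted birds
(6-OHDA lesions of Area X) instead drift downward in pitch regardless of the
feedback. Quantifying these group effects is statistically awkward because
the data are deeply nested — each group has 2–8 birds, each bird sings 4–12
quantifiable syllables, and each syllable is repeated 40–600 times per day —
so thousands of iterations carry far fewer than thousands of independent
degrees of freedom. This package implements the full analysis chain for
such experiments, driven by a synthetic cohort generator with known ground
truth so every estimator can be tested for parameter recovery.

## Pitch metrics (`songboot.pitch`)

Each iteration's pitch (Hz) is converted to a semitone change against its
syllable's own baseline,

    s = 12 · log2(pitch / baseline),

where `baseline` is the arithmetic mean pitch (in Hz) of that syllable over
the last 3 baseline days (birds with an extended baseline use only those
last 3 days). Group means over a day window pool all converted iterations,
which weights each syllable by how often it was sung (syllables sung more
received more shifted feedback); an equal-per-bird alternative
(`per_bird=True`) is exposed. Washout dynamics are summarized as Δ(Pitch):
each syllable's mean semitone value on its last sung shift day is subtracted
from every washout iteration. Bird- and syllable-level offsets cancel in
that subtraction, isolating how pitch moves once the shift ends. The
reference mean is taken in the semitone (log) domain, matching the
convert-then-average order used everywhere else.

Averaging baseline pitches in Hz before taking the log introduces a small
Jensen bias: with iteration noise of 0.5 st the baseline is overestimated by
≈0.007 st, so all semitone estimates are shifted by about −0.007 st relative
to the latent truth. This is inherent to the Hz-domain baseline definition
(which the bootstrap requires) and is far below every tolerance used here.

A minimal spectral estimator (`songboot.spectral`) recovers the fundamental
of synthetic harmonic stacks: single Hann-windowed FFT, lowest local maximum
above 10% of the global peak power (at or above 200 Hz), power-weighted mean
frequency over ±3 bins. It exists to exercise the pitch-extraction contract
on synthetic waveforms; segmenting real song is out of scope, and only
recovery on synthetic tones (within one FFT bin for f0 in 1–6 kHz) is
guaranteed.

## Synthetic cohorts (`songboot.simulate`)

The generator emulates the experiment's structure: a 3-day baseline, 14-day
shift, and 6–7-day washout (default 7); syllable counts uniform in [4, 12];
per-syllable per-day iteration counts uniform in [40, 600]; per-syllable
base frequencies log-uniform in [1, 6] kHz (a typical syllable range — not a
measured quantity). The latent semitone response is the sum of two
first-order exponential processes that begin at the end of baseline:

* **drift** — lesion-induced pitch change independent of the feedback,
  asymptote `drift_asymptote` (st), timescale 6 d;
* **adaptation** — compensation opposite the imposed shift, asymptote
  `adapt_asymptote` (st), timescale 5 d; zero in lesioned groups.

Only plateau values, not dynamics, are reported for the real experiments, so
the exponential form and timescales are modeling choices (chosen to give
gradual multi-day changes; both configurable). Drift and the bird/syllable
random offsets apply only after baseline: any offset present during the
baseline epoch would cancel exactly in the semitone conversion and could
never contribute group-level variance, which would defeat the purpose of the
variance components.

Noise has three levels, with defaults σ_bird = 0.10 st, σ_syllable =
0.15 st, σ_iteration = 0.50 st, chosen so that the naive pooled SEM visibly
understates the true uncertainty — the regime the hierarchical bootstrap
exists for. Iterations are conditionally independent given the day's latent
mean; real song has within-day and day-to-day autocorrelation the generator
does not model, so passing tests demonstrate correctness of the estimators
under the assumed variance structure, not robustness to serial dependence.

During washout the learned response either decays exponentially toward
baseline (`revert`, timescale 10 d) or the drift keeps evolving
(`continue-drift`, used for the lesioned no-shift preset, whose pitch keeps
falling after the shift ends). In revert mode the rebound asymptote can be
calibrated so the latent mean Δ(Pitch) over the last 2 washout days equals a
requested value.

Presets encode the six study groups. Asymptotes are solved so the latent
group mean over shift days 12–14 equals the group's plateau (−0.40 / +0.36
st for unlesioned ±1-shift; −0.38 / −0.46 st for lesioned ±1-shift; −0.19 st
for lesioned no-shift; 0 for unlesioned no-shift) and, where washout data
exist, the latent last-2-day Δ(Pitch) equals the group's washout change
(+0.17 / −0.22 unlesioned, +0.24 / −0.28 lesioned). Bird counts are
3/3/2/4/4/8 following the study design. Each bird draws from an
independently spawned random stream, so enlarging a cohort never perturbs
existing birds.

OD-ratio sections are drawn from normal distributions (saline mean 1.4,
sd 0.1; the distributional family is a modeling convenience — only the
threshold logic matters downstream). When a target below-threshold fraction
is requested, the lesioned population's mean is solved numerically so its
mass below the saline population's 5th percentile equals the target.

## Hierarchical bootstrap (`songboot.bootstrap`)

One subsample: draw birds with replacement (as many as the dataset has);
for each drawn bird, draw its syllables with replacement (its own syllable
count by default; a fixed count is available); for each drawn syllable, draw
`m_base` baseline and `m_win` window iterations with replacement, with the
counts fixed — independent of how often the syllable was actually sung — so
that every syllable is treated as equally likely in a hypothetical new bird.
The syllable baseline is recomputed from the resampled baseline iterations,
conversion to semitones happens just before averaging, and the subsample
mean is the unweighted mean over drawn syllables. N = 10⁴ subsamples by
default; the standard deviation of the subsample means is the hierarchical
SEM and their central 67% interval is the reported uncertainty. Point
estimates always come from the actual data (frequency-weighted group mean);
the bootstrap quantifies only measurement uncertainty.

The equalized counts default to `m_base = m_win = m_ref = 50`, inside the
observed 40–600 iterations/day range and cheap at N = 10⁴; they are
configuration, not a claim about the original analysis (which fixed the
counts without publishing the constant). Reproducibility: a master seed
spawns one child stream per resample index, so the resampled-means sequence
is independent of execution order.

The washout variant resamples, per drawn syllable, `m_ref` additional
iterations from its last sung shift day, recomputes that reference mean
inside the subsample, and returns the difference — the subtraction is
performed after resampling so the reference day's estimation error
propagates into the washout uncertainty.

Known behavior: resampling birds already carries syllable-sampling noise
(it is embedded in the bird-to-bird spread), and resampling syllables within
birds adds it again, so the procedure is mildly conservative when syllable
counts per bird are small; with the default 4–12 syllables per bird the
nominal 67% interval covers the latent group mean at roughly 68–71% in our
calibration runs. Two deliberate asymmetries of scale: the bootstrap's
estimand is the syllable-equalized mean while the point estimate is
frequency-weighted; both are unbiased for the latent group mean under the
generator, and the difference is far below the SEM at realistic cohort
sizes.

## Posterior-probability tests (`songboot.inference`)

P(group ≥ c) is the fraction of resampled means at or above c. P(group A ≥
group B) treats the two resampled populations as independent and computes
the exact all-pairs volume of their joint distribution on one side of the
unity line (ties included), by sorting one population and binary-searching
the other — never by subsampling pairs. A paired index-by-index mode exists
for sensitivity analysis, and every report records which mode produced it.
Significance is two-way: p < α/2 or p > 1 − α/2 (0.025/0.975 at α = 0.05),
with α divided by the number of comparisons (Bonferroni). Probabilities of
exactly 0 or 1 are stored numerically but rendered at the 1/N resolution
bound ("p < 0.0001" at N = 10⁴).

## Mixed-model cross-check (`songboot.lmm`)

The nested random-intercept model s_ijk = β₀jk + β₁·x_ij + ε_ij, with
β₀jk = β₀₀k + b₀jk (syllable within bird) and β₀₀k = β₀₀₀ + c₀₀k (bird), is
fit by REML (statsmodels `MixedLM`, bird groups plus a syllable variance
component), with the shift condition x coded −1/0/+1 by shift direction or
0/1 for the pooled shift-vs-no-shift contrast. p-values use the large-sample
normal approximation of the fixed-effect estimate. The response defaults to
per-iteration semitones over shift days 12–14; per-syllable-per-day means
are available and nearly equivalent (within-cell counts are large), and are
used in the simulation tests for speed. Designs with (near-)zero residual
variance cannot support REML; they are detected and fit by OLS with a
`degenerate` diagnostic flag so exact-recovery cases return exact answers.
Birds from different condition cohorts are namespaced per cohort before
fitting, since independently generated groups may reuse bird labels.

## Lesion quantification (`songboot.lesion`)

OD ratio = OD(Area X) / OD(striatum) per section. The lesion threshold is
the 5th percentile of the saline sections' ratios, computed with linear
interpolation between closest ranks (the convention is recorded in output
metadata because it shifts the threshold slightly at small n). A section
counts as lesioned when its ratio is strictly below the threshold; per-bird
extents pool that bird's sections, and their section-count-weighted average
equals the population fraction exactly. Populations are compared with the
two-sample Kolmogorov–Smirnov test (asymptotic p by default, exact below 50
total sections), and per-bird extent is correlated (Pearson r, two-sided p)
against behavioral metrics such as final pitch change and variance changes.

## Problem sizes and numerical choices

Default analyses run N = 10⁴ resamples with equalized counts of 50. The
calibration simulations use reduced but still informative sizes: 8-bird
cohorts with 40–60 iterations/day, N = 2000 resamples for the 400-replicate
67%-CI coverage study and N = 600 for the 200-replicate null
(type-I-error) study; the recovery checks average a handful of replicate
cohorts at full preset scale to separate estimator bias from single-cohort
sampling noise. `scripts/acceptance.py` reports, for each preset, the mean
pipeline estimate over 8 independently seeded replicate cohorts (and the
analogous average for the OD fraction), all generated at run time from the
given master seed.

Ties in the all-pairs comparison count toward "≥" on both sides, so the two
directions sum to exactly 1 only in the absence of ties. Degenerate inputs
(empty day windows, syllables without baselines, silent waveforms, zero
striatum OD, constant condition vectors, zero-variance correlations) raise
typed errors naming the offending entity rather than propagating NaNs.

## Limitations

* The generator's exponential latent dynamics and noise levels are
  assumptions; only plateau/washout endpoints are anchored to measured
  group values.
* No within-day or day-to-day autocorrelation, no circadian structure, no
  directed/undirected song distinction.
* The hierarchical bootstrap is only implemented for the 3-level
  bird/syllable/iteration scheme (plus the washout reference variant), not
  arbitrary nesting depths.
* The spectral estimator is validated on synthetic harmonic stacks only.
* OD values are consumed from tables; image segmentation and stain
  normalization are out of scope.
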