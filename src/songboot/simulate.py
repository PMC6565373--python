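"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure of a headphones pitch-shift experiment:
each bird sings 4-12 quantifiable syllables, each syllable 40-600 times per
day, across a 3-day baseline / 14-day feedback-shift / 6-7-day washout
timeline.  Pitch responses are expressed in semitones relative to each
syllable's baseline and are built from two latent first-order exponential
processes:

* drift — a lesion-induced change in produced pitch that develops after
  baseline regardless of the feedback shift (asymptote ``drift_asymptote``,
  timescale ``drift_timescale``);
* adaptation — compensation opposite in sign to the imposed feedback shift
  (asymptote ``adapt_asymptote``, timescale ``adapt_timescale``); zero for
  dopamine-depleted groups.

Bird- and syllable-level random offsets apply to the post-baseline response
(an offset present during baseline would cancel exactly in the semitone
conversion) and iteration noise applies per rendition, giving the three
variance components the hierarchical bootstrap is designed to propagate.

Washout either reverts the learned response toward baseline (``revert``,
with an optional calibrated rebound magnitude) or lets drift keep evolving
(``continue-drift``).

Ground-truth latent group means are available for any day window, so every
downstream estimator can be checked for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.stats import norm

from .pitch import PitchDataset, Timeline

PRESET_NAMES = (
    "unlesioned_plus1",
    "unlesioned_minus1",
    "unlesioned_noshift",
    "lesioned_plus1",
    "lesioned_minus1",
    "lesioned_noshift",
)


@dataclass(frozen=True)
class GeneratorTruth:
    """Latent parameters a synthetic cohort is generated from."""

    group_label: str = "custom"
    shift_direction: int = 0  # -1, 0 or +1 semitone feedback shift
    drift_asymptote: float = 0.0  # semitones, at plateau
    drift_timescale: float = 6.0  # days
    adapt_asymptote: float = 0.0  # semitones, at plateau
    adapt_timescale: float = 5.0  # days
    washout_mode: str = "revert"  # or "continue-drift"
    washout_timescale: float = 10.0  # days (revert mode)
    washout_rebound: float | None = None  # latent mean Delta over last 2 washout days
    sigma_bird: float = 0.10  # semitones
    sigma_syllable: float = 0.15  # semitones
    sigma_iteration: float = 0.50  # semitones
    n_birds: int = 6
    syllables_per_bird_range: tuple[int, int] = (4, 12)
    iterations_per_day_range: tuple[int, int] = (40, 600)
    baseline_f0_range: tuple[float, float] = (1000.0, 6000.0)
    timeline: Timeline = field(default_factory=Timeline)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_bird < 0 or self.sigma_syllable < 0 or self.sigma_iteration < 0:
            raise ValueError("variance components must be non-negative")
        if self.drift_timescale <= 0 or self.adapt_timescale <= 0 or self.washout_timescale <= 0:
            raise ValueError("timescales must be positive")
        for lo, hi in (
            self.syllables_per_bird_range,
            self.iterations_per_day_range,
            self.baseline_f0_range,
        ):
            if lo > hi or lo <= 0:
                raise ValueError(f"degenerate range ({lo}, {hi})")
        if self.n_birds < 1:
            raise ValueError("need at least one bird")
        if self.washout_mode not in ("revert", "continue-drift"):
            raise ValueError(f"unknown washout_mode {self.washout_mode!r}")

    # ------------------------------------------------------------ latent mean
    def _drift(self, d_post: np.ndarray) -> np.ndarray:
        return self.drift_asymptote * (1.0 - np.exp(-d_post / self.drift_timescale))

    def _adapt(self, d_shift: np.ndarray) -> np.ndarray:
        return self.adapt_asymptote * (1.0 - np.exp(-d_shift / self.adapt_timescale))

    def _washout_rebound_asymptote(self) -> float:
        """Asymptote of the revert-mode washout response.

        Defaults to undoing the end-of-shift adaptation; when
        ``washout_rebound`` is set, the asymptote is solved so the latent
        mean Delta over the last 2 washout days equals that value.
        """
        w_last2 = np.asarray(self.timeline.end_of_washout_days(2), dtype=float)
        frac = float(np.mean(1.0 - np.exp(-w_last2 / self.washout_timescale)))
        if self.washout_rebound is not None:
            return self.washout_rebound / frac
        return -float(self._adapt(np.asarray([float(self.timeline.shift_days)]))[0])

    def latent_washout_delta(self, washout_day: np.ndarray) -> np.ndarray:
        """Latent Delta(Pitch): washout day minus last shift day, group level."""
        w = np.asarray(washout_day, dtype=float)
        ts = float(self.timeline.shift_days)
        if self.washout_mode == "revert":
            amp = self._washout_rebound_asymptote()
            return amp * (1.0 - np.exp(-w / self.washout_timescale))
        return self._drift(ts + w) - self._drift(np.asarray([ts]))[0]

    def latent_mean(self, epoch: str, day: np.ndarray) -> np.ndarray:
        """Group-level latent semitone change for given days of an epoch."""
        d = np.asarray(day, dtype=float)
        ts = float(self.timeline.shift_days)
        if epoch == "baseline":
            return np.zeros_like(d)
        if epoch == "shift":
            return self._drift(d) + self._adapt(d)
        end = self._drift(np.asarray([ts]))[0] + self._adapt(np.asarray([ts]))[0]
        return end + self.latent_washout_delta(d)

    def expected_group_mean(self, days, epoch: str = "shift") -> float:
        """True group mean over a day window (random effects average to zero)."""
        return float(np.mean(self.latent_mean(epoch, np.asarray(list(days)))))

    def expected_washout_delta(self, days=None) -> float:
        if days is None:
            days = self.timeline.end_of_washout_days(2)
        return float(np.mean(self.latent_washout_delta(np.asarray(list(days)))))


def _plateau_fraction(timescale: float, days) -> float:
    d = np.asarray(list(days), dtype=float)
    return float(np.mean(1.0 - np.exp(-d / timescale)))


def preset(name: str, seed: int = 0, timeline: Timeline | None = None) -> GeneratorTruth:
    """Named cohort presets parameterized at the printed group effect sizes.

    Asymptotes are solved so the latent group mean over shift days 12-14
    equals the group's reported plateau, and (where washout data exist for
    the group) the latent Delta(Pitch) over the last 2 washout days equals
    the reported washout change.  Bird counts follow the study design.
    """
    tl = timeline or Timeline()
    base = GeneratorTruth(group_label=name, timeline=tl, seed=seed)
    end_days = tl.end_of_shift_days(3)
    f_drift = _plateau_fraction(base.drift_timescale, end_days)
    f_adapt = _plateau_fraction(base.adapt_timescale, end_days)

    # (plateau st, washout Delta st, n_birds, shift direction, lesioned?)
    table = {
        "unlesioned_plus1": (-0.40, 0.17, 3, +1, False),
        "unlesioned_minus1": (0.36, -0.22, 3, -1, False),
        "unlesioned_noshift": (0.0, None, 2, 0, False),
        "lesioned_plus1": (-0.38, 0.24, 4, +1, True),
        "lesioned_minus1": (-0.46, -0.28, 4, -1, True),
        "lesioned_noshift": (-0.19, None, 8, 0, True),
    }
    try:
        plateau, rebound, n_birds, direction, lesioned = table[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}") from None

    if lesioned:
        # depleted birds show pure drift, no adaptive compensation
        kwargs = dict(drift_asymptote=plateau / f_drift, adapt_asymptote=0.0)
        washout_mode = "continue-drift" if direction == 0 else "revert"
    else:
        kwargs = dict(drift_asymptote=0.0, adapt_asymptote=plateau / f_adapt)
        washout_mode = "revert"
    return replace(
        base,
        group_label=name,
        shift_direction=direction,
        n_birds=n_birds,
        washout_mode=washout_mode,
        washout_rebound=rebound,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_experiment(truth: GeneratorTruth) -> PitchDataset:
    """Draw a full synthetic cohort, reproducibly from ``truth.seed``.

    Each bird gets an independently spawned random stream, so adding birds
    to a cohort does not perturb the ones already generated.
    """
    tl = truth.timeline
    root = np.random.SeedSequence(truth.seed)
    bird_seeds = root.spawn(truth.n_birds)

    epoch_days = [
        ("baseline", d) for d in range(1, tl.baseline_days + 1)
    ] + [
        ("shift", d) for d in range(1, tl.shift_days + 1)
    ] + [
        ("washout", d) for d in range(1, tl.washout_days + 1)
    ]
    n_days = len(epoch_days)

    frames = []
    for ib, ss in enumerate(bird_seeds):
        rng = np.random.default_rng(ss)
        bird_id = f"bird{ib:02d}"
        lo_s, hi_s = truth.syllables_per_bird_range
        n_syll = int(rng.integers(lo_s, hi_s + 1))
        log_lo, log_hi = np.log(truth.baseline_f0_range)
        f0 = np.exp(rng.uniform(log_lo, log_hi, size=n_syll))
        bird_eff = rng.normal(0.0, truth.sigma_bird)
        syll_eff = rng.normal(0.0, truth.sigma_syllable, size=n_syll)

        lo_i, hi_i = truth.iterations_per_day_range
        counts = rng.integers(lo_i, hi_i + 1, size=(n_syll, n_days))

        # latent group-level mean per day; random offsets apply post-baseline
        mu_day = np.empty(n_days)
        post = np.empty(n_days, dtype=bool)
        for j, (epoch, day) in enumerate(epoch_days):
            mu_day[j] = truth.latent_mean(epoch, np.asarray([day]))[0]
            post[j] = epoch != "baseline"

        total = int(counts.sum())
        syll_idx = np.repeat(
            np.repeat(np.arange(n_syll), n_days), counts.reshape(-1)
        )
        day_idx = np.repeat(np.tile(np.arange(n_days), n_syll), counts.reshape(-1))
        mu = mu_day[day_idx] + np.where(
            post[day_idx], bird_eff + syll_eff[syll_idx], 0.0
        )
        eps = rng.normal(0.0, truth.sigma_iteration, size=total)
        pitch_hz = f0[syll_idx] * np.power(2.0, (mu + eps) / 12.0)

        frames.append(
            pd.DataFrame(
                {
                    "bird_id": bird_id,
                    "syllable_id": np.char.add(
                        f"{bird_id}_s", syll_idx.astype(str)
                    ),
                    "day": [epoch_days[j][1] for j in day_idx],
                    "epoch": [epoch_days[j][0] for j in day_idx],
                    "pitch_hz": pitch_hz,
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)
    return PitchDataset(records, timeline=tl, group_label=truth.group_label)


def write_experiment(truth: GeneratorTruth, out_dir: str | Path) -> tuple[Path, Path]:
    """Generate a cohort and write its CSV plus a YAML echo of the truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ds = generate_experiment(truth)
    csv_path = out_dir / f"{truth.group_label}_pitch.csv"
    ds.to_csv(csv_path)
    truth_path = out_dir / f"{truth.group_label}_truth.yaml"
    payload = asdict(truth)
    payload["timeline"] = asdict(truth.timeline)
    with open(truth_path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
    return csv_path, truth_path


# ---------------------------------------------------------------------------
# Optical-density sections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ODGeneratorTruth:
    """Parameters for synthetic per-section optical-density ratio tables.

    OD ratios are drawn from normal distributions (the threshold logic, not
    the family, is what matters downstream); the lesioned population's mean
    is either given directly or solved so that its mass below the saline
    population's 5th percentile matches ``target_below_threshold_fraction``.
    """

    n_saline_birds: int = 4
    n_lesion_birds: int = 16
    sections_per_bird: int = 30
    saline_mean: float = 1.4
    saline_sd: float = 0.1
    lesion_mean: float | None = None
    lesion_sd: float = 0.1
    target_below_threshold_fraction: float | None = 0.375
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sections_per_bird < 1:
            raise ValueError("sections_per_bird must be >= 1")
        t = self.target_below_threshold_fraction
        if t is not None and not 0.0 < t < 1.0:
            raise ValueError(
                "target fraction must be strictly inside (0, 1) for continuous ratios"
            )

    def solved_lesion_mean(self) -> float:
        if self.lesion_mean is not None:
            return self.lesion_mean
        if self.target_below_threshold_fraction is None:
            raise ValueError("provide lesion_mean or target_below_threshold_fraction")
        thr = norm.ppf(0.05, loc=self.saline_mean, scale=self.saline_sd)
        target = self.target_below_threshold_fraction

        def gap(mu: float) -> float:
            return norm.cdf(thr, loc=mu, scale=self.lesion_sd) - target

        lo = thr - 10 * self.lesion_sd
        hi = thr + 10 * self.lesion_sd
        return float(brentq(gap, lo, hi))


def generate_od_sections(truth: ODGeneratorTruth) -> pd.DataFrame:
    """Per-section OD table: bird_id, group, section_index, od_areax, od_striatum.

    Striatum OD is drawn uniformly per section and Area X OD is the target
    ratio times it, so od_areax/od_striatum carries the calibrated signal.
    """
    rng = np.random.default_rng(np.random.SeedSequence(truth.seed))
    lesion_mean = truth.solved_lesion_mean()
    rows = []
    for group, n_birds, mean, sd in (
        ("saline", truth.n_saline_birds, truth.saline_mean, truth.saline_sd),
        ("lesioned", truth.n_lesion_birds, lesion_mean, truth.lesion_sd),
    ):
        for ib in range(n_birds):
            ratios = rng.normal(mean, sd, size=truth.sections_per_bird)
            striatum = rng.uniform(0.8, 1.2, size=truth.sections_per_bird)
            rows.append(
                pd.DataFrame(
                    {
                        "bird_id": f"{group}{ib:02d}",
                        "group": group,
                        "section_index": np.arange(truth.sections_per_bird),
                        "od_areax": ratios * striatum,
                        "od_striatum": striatum,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
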