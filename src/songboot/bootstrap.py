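"""Three-level hierarchical bootstrap for nested pitch data.

Pitch datasets are nested — iterations within syllables within birds — so a
pooled standard error over all iterations badly understates the uncertainty
of a group mean.  The bootstrap here resamples with replacement level by
level: first birds, then each drawn bird's syllables, then each drawn
syllable's iterations.  Two further details follow the method this package
implements:

* Syllable equalization.  Each drawn syllable contributes a fixed number of
  iterations (``m_base`` baseline draws, ``m_win`` window draws) regardless
  of how often it was actually sung, treating every syllable as equally
  likely in a hypothetical new bird.
* Hz-domain resampling.  Raw pitches in Hz are resampled and each
  subsample recomputes its own syllable baselines from the resampled
  baseline iterations, so baseline-estimation error propagates into the
  uncertainty; conversion to semitones happens just before the subsample
  mean is taken.

The standard deviation of the resampled means estimates the group-mean
standard error, and the central 67% interval is the reported uncertainty
(comparable to +/-1 SEM).  Point estimates always come from the real data
via the frequency-weighted group mean, never from the resamples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .pitch import (
    PitchDataError,
    PitchDataset,
    compute_baseline,
    washout_delta_mean,
    weighted_group_mean,
)

DEFAULT_N_RESAMPLES = 10_000
DEFAULT_EQUALIZED_COUNT = 50


@dataclass
class BootstrapResult:
    """Population of resampled group means plus point estimate and uncertainty."""

    resampled_means: np.ndarray
    point_estimate: float
    seed: int

    @property
    def n_resamples(self) -> int:
        return len(self.resampled_means)

    @property
    def sem(self) -> float:
        """Standard deviation of the resampled means (the hierarchical SEM)."""
        return float(np.std(self.resampled_means, ddof=1))

    @property
    def ci67(self) -> tuple[float, float]:
        """Central 67% interval (16.5th-83.5th percentiles) of resampled means."""
        lo, hi = np.percentile(self.resampled_means, [16.5, 83.5])
        return float(lo), float(hi)

    def to_dict(self, include_means: bool = False) -> dict:
        out = {
            "point_estimate": self.point_estimate,
            "sem": self.sem,
            "ci67": list(self.ci67),
            "n_resamples": self.n_resamples,
            "seed": self.seed,
        }
        if include_means:
            out["resampled_means"] = self.resampled_means.tolist()
        return out

    def save(self, path: str | Path, means_csv: str | Path | None = None) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))
        if means_csv is not None:
            pd.DataFrame({"resampled_mean": self.resampled_means}).to_csv(
                means_csv, index=False
            )


# ---------------------------------------------------------------------------
# Internal flattened view of the nesting structure
# ---------------------------------------------------------------------------

class _NestedArrays:
    """Per-syllable flat arrays for fast resampling.

    ``base_hz`` holds baseline-day iterations in Hz; ``win_log2`` (and the
    optional ``ref_log2``) hold log2 pitches so subsample semitone means
    reduce to differences of log2 means.
    """

    def __init__(
        self,
        dataset: PitchDataset,
        days: Iterable[int],
        epoch: str,
        reference_last_shift_day: bool = False,
    ) -> None:
        days = list(days)
        ref_days = dataset.timeline.baseline_reference_days()
        base_df = dataset.subset("baseline", ref_days)
        win_df = dataset.subset(epoch, days)
        if len(win_df) == 0:
            raise PitchDataError(f"no records in {epoch} days {days}")

        sylls = sorted(
            map(tuple, win_df[["bird_id", "syllable_id"]].drop_duplicates().values)
        )
        base_groups = {k: v["pitch_hz"].to_numpy() for k, v in base_df.groupby(["bird_id", "syllable_id"])}
        win_groups = {k: v["pitch_hz"].to_numpy() for k, v in win_df.groupby(["bird_id", "syllable_id"])}

        ref_groups: dict = {}
        if reference_last_shift_day:
            shift = dataset.subset("shift")
            grp = shift.groupby(["bird_id", "syllable_id"])["day"]
            last = shift["day"].to_numpy() == grp.transform("max").to_numpy()
            ref_groups = {
                k: v["pitch_hz"].to_numpy()
                for k, v in shift[last].groupby(["bird_id", "syllable_id"])
            }
            missing = [k for k in sylls if k not in ref_groups]
            if missing:
                raise PitchDataError(
                    f"washout syllables with no shift-epoch records: {missing[:5]}"
                )

        base_list, win_list, ref_list, bird_of_syll = [], [], [], []
        birds = sorted({b for b, _ in sylls})
        bird_index = {b: i for i, b in enumerate(birds)}
        for key in sylls:
            if key not in base_groups or len(base_groups[key]) == 0:
                raise PitchDataError(f"syllable {key} has no baseline records")
            if len(win_groups.get(key, ())) == 0:
                raise PitchDataError(f"syllable {key} has no window records")
            base_list.append(base_groups[key])
            win_list.append(np.log2(win_groups[key]))
            if reference_last_shift_day:
                if len(ref_groups[key]) == 0:
                    raise PitchDataError(f"syllable {key} has no reference-day records")
                ref_list.append(np.log2(ref_groups[key]))
            bird_of_syll.append(bird_index[key[0]])

        self.n_birds = len(birds)
        self.bird_of_syll = np.asarray(bird_of_syll)
        # syllable ids of each bird, as index ranges into the flat lists
        self.syll_ids_per_bird = [
            np.flatnonzero(self.bird_of_syll == i) for i in range(self.n_birds)
        ]
        self.n_syll_per_bird = np.array([len(s) for s in self.syll_ids_per_bird])

        def _flatten(chunks):
            lengths = np.array([len(c) for c in chunks])
            offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
            return np.concatenate(chunks), offsets, lengths

        self.base_flat, self.base_off, self.base_len = _flatten(base_list)
        self.win_flat, self.win_off, self.win_len = _flatten(win_list)
        self.has_ref = reference_last_shift_day
        if reference_last_shift_day:
            self.ref_flat, self.ref_off, self.ref_len = _flatten(ref_list)

    # ------------------------------------------------------------------
    def draw_mean(
        self,
        rng: np.random.Generator,
        m_base: int,
        m_win: int,
        m_ref: int = DEFAULT_EQUALIZED_COUNT,
        syllables_per_bird: int | None = None,
    ) -> float:
        """One hierarchical subsample mean (semitones; Delta if a reference is set)."""
        bird_draw = rng.integers(0, self.n_birds, size=self.n_birds)
        if syllables_per_bird is None:
            n_syll_draw = self.n_syll_per_bird[bird_draw]
        else:
            n_syll_draw = np.full(self.n_birds, syllables_per_bird)
        bird_rep = np.repeat(bird_draw, n_syll_draw)
        # uniform syllable choice within each drawn bird
        u = rng.random(len(bird_rep))
        within = np.floor(u * self.n_syll_per_bird[bird_rep]).astype(np.intp)
        first_syll = np.array([s[0] if len(s) else 0 for s in self.syll_ids_per_bird])
        syll = first_syll[bird_rep] + within

        def _draw(flat, off, lens, m):
            idx = np.floor(
                rng.random((len(syll), m)) * lens[syll][:, None]
            ).astype(np.intp)
            return flat[off[syll][:, None] + idx]

        base_mean_hz = _draw(self.base_flat, self.base_off, self.base_len, m_base).mean(axis=1)
        win_mean_log2 = _draw(self.win_flat, self.win_off, self.win_len, m_win).mean(axis=1)
        s = 12.0 * (win_mean_log2 - np.log2(base_mean_hz))
        if self.has_ref:
            ref_mean_log2 = _draw(self.ref_flat, self.ref_off, self.ref_len, m_ref).mean(axis=1)
            s = 12.0 * (win_mean_log2 - ref_mean_log2)
        return float(s.mean())


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def resample_once(
    dataset: PitchDataset,
    days: Iterable[int],
    rng: np.random.Generator,
    epoch: str = "shift",
    m_base: int = DEFAULT_EQUALIZED_COUNT,
    m_win: int = DEFAULT_EQUALIZED_COUNT,
    syllables_per_bird: int | None = None,
) -> float:
    """Draw one hierarchical subsample and return its mean, in semitones.

    Resamples birds with replacement, then each drawn bird's syllables
    (by default as many as the bird actually has), then ``m_base`` baseline
    and ``m_win`` window iterations per drawn syllable; recomputes the
    syllable baseline from the resampled baseline iterations and converts to
    semitones just before averaging.
    """
    nested = _NestedArrays(dataset, days, epoch)
    return nested.draw_mean(rng, m_base, m_win, syllables_per_bird=syllables_per_bird)


def _run(
    nested: _NestedArrays,
    n_resamples: int,
    seed: int,
    point_estimate: float,
    m_base: int,
    m_win: int,
    m_ref: int = DEFAULT_EQUALIZED_COUNT,
    syllables_per_bird: int | None = None,
) -> BootstrapResult:
    if n_resamples < 2:
        raise ValueError("n_resamples must be at least 2")
    # one child stream per resample index: results are independent of
    # execution order and fully reproducible from the master seed
    children = np.random.SeedSequence(seed).spawn(n_resamples)
    means = np.empty(n_resamples)
    for i, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        means[i] = nested.draw_mean(
            rng, m_base, m_win, m_ref=m_ref, syllables_per_bird=syllables_per_bird
        )
    return BootstrapResult(means, point_estimate=point_estimate, seed=seed)


def bootstrap_distribution(
    dataset: PitchDataset,
    days: Iterable[int] | None = None,
    epoch: str = "shift",
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int = 0,
    m_base: int = DEFAULT_EQUALIZED_COUNT,
    m_win: int = DEFAULT_EQUALIZED_COUNT,
    syllables_per_bird: int | None = None,
) -> BootstrapResult:
    """Hierarchical bootstrap of the group mean pitch change over a day window.

    ``days`` defaults to the end-of-shift window (shift days 12-14).  The
    point estimate is the frequency-weighted group mean of the actual data;
    the resamples quantify only the measurement uncertainty.
    """
    if days is None:
        days = dataset.timeline.end_of_shift_days(3)
    days = list(days)
    nested = _NestedArrays(dataset, days, epoch)
    point = weighted_group_mean(dataset, days, epoch=epoch)
    return _run(
        nested, n_resamples, seed, point, m_base, m_win,
        syllables_per_bird=syllables_per_bird,
    )


def bootstrap_washout(
    dataset: PitchDataset,
    days: Iterable[int] | None = None,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int = 0,
    m_base: int = DEFAULT_EQUALIZED_COUNT,
    m_win: int = DEFAULT_EQUALIZED_COUNT,
    m_ref: int = DEFAULT_EQUALIZED_COUNT,
    syllables_per_bird: int | None = None,
) -> BootstrapResult:
    """Hierarchical bootstrap of washout Delta(Pitch) over a washout window.

    Each subsample additionally resamples ``m_ref`` iterations from every
    drawn syllable's last sung shift day and subtracts that recomputed
    reference mean, so the uncertainty of the last-shift-day estimate
    propagates into the washout uncertainty.  The point estimate is the
    pooled Delta(Pitch) mean of the actual data.
    """
    if days is None:
        days = dataset.timeline.end_of_washout_days(2)
    days = list(days)
    nested = _NestedArrays(dataset, days, "washout", reference_last_shift_day=True)
    point = washout_delta_mean(dataset, days)
    return _run(
        nested, n_resamples, seed, point, m_base, m_win, m_ref=m_ref,
        syllables_per_bird=syllables_per_bird,
    )


def naive_pooled_sem(dataset: PitchDataset, days: Iterable[int], epoch: str = "shift") -> float:
    """sd/sqrt(n) over all pooled iteration semitones — the estimate the
    hierarchical bootstrap exists to correct."""
    baselines = compute_baseline(dataset)
    df = dataset.subset(epoch, list(days))
    from .pitch import _semitone_series

    s = _semitone_series(df, baselines)
    return float(s.std(ddof=1) / np.sqrt(len(s)))
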