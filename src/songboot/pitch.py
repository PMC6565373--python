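"""Nested pitch data model and deterministic semitone metrics.

The central object is :class:`PitchDataset`: a long-format table with one row
per syllable iteration (bird, syllable, experiment day, epoch, pitch in Hz)
plus the experiment timeline.  Every downstream statistic is expressed in
semitones relative to each syllable's own baseline pitch,

    s = 12 * log2(pitch / baseline),

where ``baseline`` is the mean pitch of that syllable over the last three
baseline days.  Records are stored in Hz and converted lazily — the
hierarchical bootstrap needs to resample raw Hz values and recompute
baselines inside each subsample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

EPOCHS = ("baseline", "shift", "washout")

#: Number of trailing baseline days that define a syllable's reference pitch.
BASELINE_REFERENCE_DAYS = 3

RECORD_COLUMNS = ["bird_id", "syllable_id", "day", "epoch", "pitch_hz"]


class PitchDataError(ValueError):
    """Raised when a pitch table violates the nested-data contract."""


@dataclass(frozen=True)
class Timeline:
    """Epoch lengths, in days. Days are 1-based within each epoch."""

    baseline_days: int = 3
    shift_days: int = 14
    washout_days: int = 7

    def __post_init__(self) -> None:
        if self.baseline_days < 1 or self.shift_days < 1 or self.washout_days < 0:
            raise PitchDataError("timeline epochs must have positive length")

    def epoch_length(self, epoch: str) -> int:
        return {
            "baseline": self.baseline_days,
            "shift": self.shift_days,
            "washout": self.washout_days,
        }[epoch]

    def baseline_reference_days(self) -> tuple[int, ...]:
        """The last 3 baseline days (all of them for a standard 3-day baseline).

        One bird in the motivating experiments had an extended 6-day
        baseline; its last 3 days are treated as the reference.
        """
        n = min(BASELINE_REFERENCE_DAYS, self.baseline_days)
        return tuple(range(self.baseline_days - n + 1, self.baseline_days + 1))

    def end_of_shift_days(self, n_days: int = 3) -> tuple[int, ...]:
        """Shift days 12-14 by default ("end of shift")."""
        return tuple(range(self.shift_days - n_days + 1, self.shift_days + 1))

    def end_of_washout_days(self, n_days: int = 2) -> tuple[int, ...]:
        """The last 2 washout days by default ("end of washout")."""
        return tuple(range(self.washout_days - n_days + 1, self.washout_days + 1))

    def global_day(self, epoch: str, day: int) -> int:
        """1-based day index across the whole experiment."""
        offset = {"baseline": 0, "shift": self.baseline_days,
                  "washout": self.baseline_days + self.shift_days}[epoch]
        return offset + day

    @property
    def total_days(self) -> int:
        return self.baseline_days + self.shift_days + self.washout_days


@dataclass
class PitchDataset:
    """Long-format nested pitch measurements for one experimental group."""

    records: pd.DataFrame
    timeline: Timeline = field(default_factory=Timeline)
    group_label: str = ""

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in RECORD_COLUMNS if c not in df.columns]
        if missing:
            raise PitchDataError(f"pitch table is missing columns {missing}")
        if len(df) == 0:
            raise PitchDataError("pitch table is empty")
        if not df["epoch"].isin(EPOCHS).all():
            bad = sorted(set(df["epoch"]) - set(EPOCHS))
            raise PitchDataError(f"unknown epoch labels {bad}")
        if (df["pitch_hz"] <= 0).any():
            raise PitchDataError("pitch_hz must be strictly positive")
        for epoch in EPOCHS:
            sub = df.loc[df["epoch"] == epoch, "day"]
            if len(sub) and (
                (sub < 1).any() or (sub > self.timeline.epoch_length(epoch)).any()
            ):
                raise PitchDataError(
                    f"{epoch} day indices outside 1..{self.timeline.epoch_length(epoch)}"
                )
        self._check_baseline_presence()

    def _check_baseline_presence(self) -> None:
        df = self.records
        ref_days = self.timeline.baseline_reference_days()
        base = df[(df["epoch"] == "baseline") & (df["day"].isin(ref_days))]
        have = set(map(tuple, base[["bird_id", "syllable_id"]].drop_duplicates().values))
        later = df[df["epoch"] != "baseline"]
        need = set(map(tuple, later[["bird_id", "syllable_id"]].drop_duplicates().values))
        orphans = sorted(need - have)
        if orphans:
            raise PitchDataError(
                "syllables lack baseline-reference records: " + repr(orphans[:5])
            )

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_csv(cls, path: str | Path, timeline: Timeline | None = None,
                 group_label: str = "") -> "PitchDataset":
        df = pd.read_csv(path, dtype={"bird_id": str, "syllable_id": str})
        return cls(df, timeline or Timeline(), group_label)

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False, columns=RECORD_COLUMNS)

    # --------------------------------------------------------------- helpers
    def subset(self, epoch: str, days: Iterable[int] | None = None) -> pd.DataFrame:
        df = self.records[self.records["epoch"] == epoch]
        if days is not None:
            df = df[df["day"].isin(list(days))]
        return df

    def birds(self) -> list:
        return sorted(self.records["bird_id"].unique())

    def with_records(self, records: pd.DataFrame) -> "PitchDataset":
        return replace(self, records=records)


# ---------------------------------------------------------------------------
# Semitone conversion
# ---------------------------------------------------------------------------

def hz_to_semitones(pitch_hz, baseline_hz):
    """Convert pitch to semitones relative to a baseline: 12*log2(pitch/baseline).

    Accepts scalars or arrays; both inputs must be strictly positive.
    """
    p = np.asarray(pitch_hz, dtype=float)
    b = np.asarray(baseline_hz, dtype=float)
    if np.any(p <= 0) or np.any(b <= 0):
        raise PitchDataError("frequencies must be strictly positive")
    out = 12.0 * np.log2(p / b)
    return out.item() if np.isscalar(pitch_hz) and np.isscalar(baseline_hz) else out


def compute_baseline(dataset: PitchDataset) -> pd.DataFrame:
    """Per-(bird, syllable) baseline pitch: mean Hz over the last 3 baseline days.

    Returns a DataFrame indexed by (bird_id, syllable_id) with a
    ``baseline_hz`` column.  Every syllable that appears outside the baseline
    epoch must have baseline records (enforced at dataset construction).
    """
    ref_days = dataset.timeline.baseline_reference_days()
    base = dataset.subset("baseline", ref_days)
    if len(base) == 0:
        raise PitchDataError("no baseline records in the reference days")
    out = (
        base.groupby(["bird_id", "syllable_id"])["pitch_hz"]
        .mean()
        .rename("baseline_hz")
        .to_frame()
    )
    return out


def _semitone_series(df: pd.DataFrame, baselines: pd.DataFrame) -> pd.Series:
    """Per-record semitone values against each record's syllable baseline."""
    key = pd.MultiIndex.from_frame(df[["bird_id", "syllable_id"]])
    try:
        base = baselines["baseline_hz"].reindex(key).to_numpy()
    except KeyError as exc:  # pragma: no cover - defensive
        raise PitchDataError(f"missing baseline for {exc}") from exc
    if np.isnan(base).any():
        bad = sorted(set(key[np.isnan(base)]))
        raise PitchDataError(f"missing baseline for syllables {bad[:5]}")
    return pd.Series(
        12.0 * np.log2(df["pitch_hz"].to_numpy() / base), index=df.index, name="semitones"
    )


def weighted_group_mean(
    dataset: PitchDataset,
    days: Iterable[int],
    epoch: str = "shift",
    baselines: pd.DataFrame | None = None,
    per_bird: bool = False,
) -> float:
    """Frequency-weighted group mean pitch change, in semitones.

    All records in the day window are converted to semitones against their
    syllable baselines and pooled; because every iteration contributes one
    value, syllables sung more often are weighted by their frequency of
    occurrence.  With ``per_bird=True`` the mean of per-bird pooled means is
    returned instead (each bird weighted equally).
    """
    days = list(days)
    if not days:
        raise PitchDataError("empty day window")
    if baselines is None:
        baselines = compute_baseline(dataset)
    df = dataset.subset(epoch, days)
    if len(df) == 0:
        raise PitchDataError(f"no records in {epoch} days {days}")
    s = _semitone_series(df, baselines)
    if per_bird:
        return float(s.groupby(df["bird_id"]).mean().mean())
    return float(s.mean())


def daily_trajectory(dataset: PitchDataset, per_bird: bool = False) -> pd.DataFrame:
    """Weighted group mean for every day of the timeline.

    Returns one row per experiment day with columns ``epoch``, ``day``,
    ``global_day``, ``mean_semitones`` and ``n_records``.  Days with no
    records (a bird can skip singing for a day) carry NaN.
    """
    baselines = compute_baseline(dataset)
    tl = dataset.timeline
    rows = []
    for epoch in EPOCHS:
        for day in range(1, tl.epoch_length(epoch) + 1):
            df = dataset.subset(epoch, [day])
            if len(df) == 0:
                mean = np.nan
            else:
                mean = weighted_group_mean(
                    dataset, [day], epoch=epoch, baselines=baselines, per_bird=per_bird
                )
            rows.append(
                {
                    "epoch": epoch,
                    "day": day,
                    "global_day": tl.global_day(epoch, day),
                    "mean_semitones": mean,
                    "n_records": len(df),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Washout
# ---------------------------------------------------------------------------

def last_shift_day_with_records(dataset: PitchDataset, bird_id, syllable_id) -> int:
    """Most recent shift day on which the syllable was sung.

    Normally the last shift day of the timeline; falls back to earlier days
    because a bird may not sing at all on a given day.
    """
    df = dataset.records
    sub = df[
        (df["epoch"] == "shift")
        & (df["bird_id"] == bird_id)
        & (df["syllable_id"] == syllable_id)
    ]
    if len(sub) == 0:
        raise PitchDataError(
            f"syllable ({bird_id}, {syllable_id}) has no shift-epoch records"
        )
    return int(sub["day"].max())


def last_shift_day_references(
    dataset: PitchDataset, baselines: pd.DataFrame | None = None
) -> tuple[pd.Series, pd.Series]:
    """Per-syllable reference day and mean for the washout subtraction.

    Returns two Series indexed by (bird_id, syllable_id): the last shift day
    with records (a bird may skip singing on the final day) and the mean
    semitone value on that day.
    """
    if baselines is None:
        baselines = compute_baseline(dataset)
    shift = dataset.subset("shift").copy()
    if len(shift) == 0:
        raise PitchDataError("dataset has no shift-epoch records")
    shift["semitones"] = _semitone_series(shift, baselines)
    grp = shift.groupby(["bird_id", "syllable_id"])
    ref_day = grp["day"].max().rename("reference_day")
    last = shift["day"].to_numpy() == grp["day"].transform("max").to_numpy()
    ref_mean = (
        shift[last]
        .groupby(["bird_id", "syllable_id"])["semitones"]
        .mean()
        .rename("reference_mean")
    )
    return ref_day, ref_mean


def washout_delta(dataset: PitchDataset) -> pd.DataFrame:
    """Per-record washout pitch change relative to the last shift day.

    For each syllable, the mean semitone value on its last sung shift day is
    subtracted from every washout record's semitone value.  Returns the
    washout records with ``delta_st`` (the Delta(Pitch) of the washout
    analysis) plus ``reference_day`` and ``semitones`` columns.  Bird- and
    syllable-level offsets cancel in the subtraction, which is the point:
    Delta(Pitch) isolates how pitch moves once the feedback shift ends.
    """
    baselines = compute_baseline(dataset)
    wash = dataset.subset("washout")
    if len(wash) == 0:
        raise PitchDataError("dataset has no washout records")
    out = wash.copy()
    out["semitones"] = _semitone_series(wash, baselines)

    ref_day, ref_mean = last_shift_day_references(dataset, baselines)
    key = pd.MultiIndex.from_frame(out[["bird_id", "syllable_id"]])
    missing = sorted(set(key) - set(ref_day.index))
    if missing:
        raise PitchDataError(
            f"washout syllables with no shift-epoch records: {missing[:5]}"
        )
    out["reference_day"] = ref_day.reindex(key).to_numpy()
    out["delta_st"] = out["semitones"] - ref_mean.reindex(key).to_numpy()
    return out


def washout_delta_mean(dataset: PitchDataset, days: Iterable[int] | None = None) -> float:
    """Pooled mean Delta(Pitch) over a washout day window (default: last 2 days)."""
    if days is None:
        days = dataset.timeline.end_of_washout_days()
    days = list(days)
    deltas = washout_delta(dataset)
    sub = deltas[deltas["day"].isin(days)]
    if len(sub) == 0:
        raise PitchDataError(f"no washout records in days {days}")
    return float(sub["delta_st"].mean())
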