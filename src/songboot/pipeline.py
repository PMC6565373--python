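"""End-to-end orchestration: generate -> metrics -> bootstrap -> inference -> LMM.

A run is a pure function of (config, master seed): group cohorts are either
generated from presets/overrides or loaded from user CSVs in the standard
pitch-table format, every random stage draws from a deterministically
spawned child of the master seed, and all results land in a JSON bundle
plus per-group trajectory CSVs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bootstrap import (
    DEFAULT_EQUALIZED_COUNT,
    DEFAULT_N_RESAMPLES,
    BootstrapResult,
    bootstrap_distribution,
    bootstrap_washout,
)
from .inference import prob_ge_constant, prob_group_ge
from .lesion import summarize_lesions
from .lmm import fit_pitch_lmm
from .pitch import PitchDataset, Timeline, daily_trajectory
from .simulate import (
    GeneratorTruth,
    ODGeneratorTruth,
    generate_experiment,
    generate_od_sections,
    preset,
)

log = logging.getLogger("songboot")


class ConfigError(ValueError):
    pass


@dataclass
class GroupSpec:
    """One experimental group: a preset name or CSV path plus overrides."""

    name: str
    preset: str | None = None
    csv: str | None = None
    overrides: dict = field(default_factory=dict)
    condition: float | None = None  # x for the LMM; defaults to shift_direction


@dataclass
class ExperimentConfig:
    groups: list[GroupSpec]
    timeline: Timeline = field(default_factory=Timeline)
    n_resamples: int = DEFAULT_N_RESAMPLES
    alpha: float = 0.05
    m_base: int = DEFAULT_EQUALIZED_COUNT
    m_win: int = DEFAULT_EQUALIZED_COUNT
    m_ref: int = DEFAULT_EQUALIZED_COUNT
    seed: int = 0
    out_dir: str = "songboot_results"
    od: dict | None = None  # ODGeneratorTruth overrides, or None to skip

    def __post_init__(self) -> None:
        if not self.groups:
            raise ConfigError("config defines no groups")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")
        if min(self.n_resamples, self.m_base, self.m_win, self.m_ref) < 1:
            raise ConfigError("counts must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            groups = [GroupSpec(**g) for g in raw.pop("groups", [])]
            timeline = Timeline(**raw.pop("timeline", {}))
            return cls(groups=groups, timeline=timeline, **raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def default_six_groups(cls, seed: int = 0, **kwargs) -> "ExperimentConfig":
        from .simulate import PRESET_NAMES

        groups = [GroupSpec(name=n, preset=n) for n in PRESET_NAMES]
        return cls(groups=groups, seed=seed, **kwargs)


@dataclass
class GroupResult:
    name: str
    dataset: PitchDataset
    truth: GeneratorTruth | None
    trajectory: pd.DataFrame
    end_of_shift: BootstrapResult
    washout: BootstrapResult | None
    condition: float


@dataclass
class ResultsBundle:
    config: ExperimentConfig
    groups: dict[str, GroupResult]
    comparisons: pd.DataFrame
    lmm: dict[str, Any]
    lesion: Any | None
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "groups": {
                name: {
                    "end_of_shift": g.end_of_shift.to_dict(),
                    "washout": g.washout.to_dict() if g.washout else None,
                    "condition": g.condition,
                    "n_records": len(g.dataset.records),
                }
                for name, g in self.groups.items()
            },
            "comparisons": self.comparisons.to_dict(orient="records"),
            "lmm": self.lmm,
            "lesion": self.lesion.to_dict() if self.lesion else None,
        }

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, g in self.groups.items():
            g.trajectory.to_csv(out / f"{name}_trajectory.csv", index=False)
        self.comparisons.to_csv(out / "comparisons.csv", index=False)
        path = out / "results.json"
        path.write_text(json.dumps(self.to_dict(), indent=2, default=str))
        return path


def _stage(name: str):
    log.info("stage: %s", name)
    return time.perf_counter()


def _load_group(spec: GroupSpec, config: ExperimentConfig, seed: int):
    if spec.csv:
        ds = PitchDataset.from_csv(spec.csv, timeline=config.timeline, group_label=spec.name)
        truth = None
    elif spec.preset:
        truth = preset(spec.preset, seed=seed, timeline=config.timeline)
        if spec.overrides:
            truth = dataclasses.replace(truth, **spec.overrides)
        ds = generate_experiment(truth)
    else:
        raise ConfigError(f"group {spec.name!r} needs either a preset or a csv")
    if spec.condition is not None:
        condition = spec.condition
    elif truth is not None:
        condition = float(truth.shift_direction)
    else:
        condition = 0.0
    return ds, truth, condition


def run_experiment(config: ExperimentConfig) -> ResultsBundle:
    """Execute every stage for every configured group."""
    master = np.random.SeedSequence(config.seed)
    group_seeds = master.spawn(len(config.groups) + 1)
    od_seed = group_seeds[-1]

    groups: dict[str, GroupResult] = {}
    for spec, ss in zip(config.groups, group_seeds):
        t0 = _stage(f"group {spec.name}")
        gen_seed, boot_seed, wash_seed = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
        try:
            ds, truth, condition = _load_group(spec, config, gen_seed)
            traj = daily_trajectory(ds)
            eos = bootstrap_distribution(
                ds,
                n_resamples=config.n_resamples,
                seed=boot_seed,
                m_base=config.m_base,
                m_win=config.m_win,
            )
            wash = None
            if (ds.records["epoch"] == "washout").any():
                wash = bootstrap_washout(
                    ds,
                    n_resamples=config.n_resamples,
                    seed=wash_seed,
                    m_base=config.m_base,
                    m_win=config.m_win,
                    m_ref=config.m_ref,
                )
        except Exception as exc:
            raise RuntimeError(f"stage 'group {spec.name}' failed: {exc}") from exc
        log.info("stage: group %s done in %.2fs", spec.name, time.perf_counter() - t0)
        groups[spec.name] = GroupResult(spec.name, ds, truth, traj, eos, wash, condition)

    comparisons = comparison_table(groups, alpha=config.alpha)

    lmm_results: dict[str, Any] = {}
    if len(groups) >= 2:
        try:
            pairs = [(g.dataset, g.condition) for g in groups.values()]
            if len({c for _, c in pairs}) >= 2:
                lmm_results["condition"] = fit_pitch_lmm(
                    pairs, response="syllable-day"
                ).to_dict()
        except Exception as exc:
            lmm_results["condition"] = {"error": str(exc)}

    lesion_summary = None
    if config.od is not None:
        seed = int(od_seed.generate_state(1)[0] % 2**31)
        od_truth = ODGeneratorTruth(**{"seed": seed, **config.od})
        lesion_summary = summarize_lesions(generate_od_sections(od_truth))

    provenance = {
        "songboot_version": __version__,
        "seed": config.seed,
        "n_resamples": config.n_resamples,
        "alpha": config.alpha,
        "equalized_counts": [config.m_base, config.m_win, config.m_ref],
        "groups": [dataclasses.asdict(s) for s in config.groups],
    }
    return ResultsBundle(config, groups, comparisons, lmm_results, lesion_summary, provenance)


def comparison_table(groups: dict[str, GroupResult], alpha: float = 0.05) -> pd.DataFrame:
    """Group-vs-zero and pairwise group-vs-group posterior probabilities.

    Bonferroni-corrects across the total number of comparisons made.
    """
    names = list(groups)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    m = len(names) + len(pairs)
    rows = []
    for name in names:
        cmp_res = prob_ge_constant(groups[name].end_of_shift, 0.0, alpha=alpha, n_comparisons=m)
        rows.append({"first": name, "second": "zero", **cmp_res.to_dict()})
    for a, b in pairs:
        cmp_res = prob_group_ge(
            groups[a].end_of_shift, groups[b].end_of_shift, alpha=alpha, n_comparisons=m
        )
        rows.append({"first": a, "second": b, **cmp_res.to_dict()})
    return pd.DataFrame(rows)


def plot_trajectories(bundle: ResultsBundle, path: str | Path) -> Path:
    """Optional daily-mean trajectory plot, one trace per group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for name, g in bundle.groups.items():
        traj = g.trajectory
        ax.plot(traj["global_day"], traj["mean_semitones"], marker="o", ms=3, label=name)
    tl = bundle.config.timeline
    for x in (tl.baseline_days + 0.5, tl.baseline_days + tl.shift_days + 0.5):
        ax.axvline(x, color="grey", lw=0.8, ls="--")
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("experiment day")
    ax.set_ylabel("pitch change (semitones)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def make_table1(bundle: ResultsBundle, alpha: float = 0.05) -> pd.DataFrame:
    """Statistical-summary matrix for the three lesioned groups.

    Rows are the lesioned no-shift / +1 / -1 groups; columns are zero and
    the two shifted lesioned groups.  Cells that duplicate another row or
    compare a group with itself are explicit nulls.
    """
    order = ["lesioned_noshift", "lesioned_plus1", "lesioned_minus1"]
    missing = [n for n in order if n not in bundle.groups]
    if missing:
        raise ConfigError(f"bundle lacks groups {missing}")
    m = 6  # comparisons in the full matrix
    cols = ["zero", "lesioned_plus1", "lesioned_minus1"]
    data = {}
    for row in order:
        vals = {}
        for col in cols:
            if col == "zero":
                res = prob_ge_constant(
                    bundle.groups[row].end_of_shift, 0.0, alpha=alpha, n_comparisons=m
                )
                vals[col] = res.probability
            elif order.index(row) >= order.index(col):
                # self-comparison, or a pair already reported on an earlier row
                vals[col] = None
            else:
                res = prob_group_ge(
                    bundle.groups[row].end_of_shift,
                    bundle.groups[col].end_of_shift,
                    alpha=alpha,
                    n_comparisons=m,
                )
                vals[col] = res.probability
        data[row] = vals
    table = pd.DataFrame(data).T
    table.index.name = "group"
    return table
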