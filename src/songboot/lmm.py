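"""Nested random-intercept linear mixed model as an inference cross-check.

The model for semitone pitch s of iteration i of syllable j in bird k is

    s_ijk = beta_0jk + beta_1 * x_ij + eps_ij
    beta_0jk = beta_00k + b_0jk          (syllable within bird)
    beta_00k = beta_000 + c_00k          (bird)

with x the shift condition (coded -1/0/+1 by shift direction, or 0/1 for a
pooled shift-vs-no-shift contrast), fit by REML with random intercepts for
bird and for syllable nested within bird.  The fixed-effect t statistic and
its large-sample two-sided p provide a frequentist check on the bootstrap
posterior-probability tests: on cohorts with a real condition effect the two
procedures should agree in direction and significance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .pitch import PitchDataset, compute_baseline, _semitone_series


class LmmError(ValueError):
    pass


@dataclass
class LmmFit:
    """Estimates from the nested random-intercept model."""

    beta0: float  # grand intercept (semitones)
    beta1: float  # fixed effect of shift condition
    beta1_se: float
    t_fixed: float
    p_fixed: float
    residual_sd: float
    bird_intercepts: dict = field(default_factory=dict)
    syllable_intercepts: dict = field(default_factory=dict)
    sigma_bird: float = 0.0
    sigma_syllable: float = 0.0
    n_obs: int = 0
    converged: bool = True
    diagnostics: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "beta1": self.beta1,
            "beta1_se": self.beta1_se,
            "t_fixed": self.t_fixed,
            "p_fixed": self.p_fixed,
            "residual_sd": self.residual_sd,
            "sigma_bird": self.sigma_bird,
            "sigma_syllable": self.sigma_syllable,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "diagnostics": self.diagnostics,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def build_response_table(
    datasets: Iterable[tuple[PitchDataset, float]],
    days: Sequence[int] | None = None,
    epoch: str = "shift",
    response: str = "iteration",
) -> pd.DataFrame:
    """Long table of semitone responses with nesting labels and condition x.

    ``response='iteration'`` keeps every rendition; ``'syllable-day'``
    aggregates to per-syllable per-day means first (smaller and faster,
    nearly identical fixed-effect inference at these within-cell counts).
    """
    frames = []
    for gi, (dataset, x) in enumerate(datasets):
        if days is None:
            use_days = dataset.timeline.end_of_shift_days(3)
        else:
            use_days = days
        baselines = compute_baseline(dataset)
        df = dataset.subset(epoch, list(use_days)).copy()
        if len(df) == 0:
            raise LmmError(f"no {epoch} records in days {list(use_days)}")
        df["st"] = _semitone_series(df, baselines)
        df["x"] = float(x)
        # cohorts may reuse bird labels; qualify with the cohort index so
        # birds from different condition groups are never conflated
        tag = dataset.group_label or f"g{gi}"
        df["bird"] = f"{gi}:{tag}/" + df["bird_id"].astype(str)
        df["syll"] = df["bird"] + "/" + df["syllable_id"].astype(str)
        if response == "syllable-day":
            df = (
                df.groupby(["bird", "syll", "day"], as_index=False)
                .agg(st=("st", "mean"), x=("x", "first"))
            )
        elif response != "iteration":
            raise LmmError(f"unknown response aggregation {response!r}")
        frames.append(df[["bird", "syll", "st", "x"]])
    return pd.concat(frames, ignore_index=True)


def fit_pitch_lmm(
    datasets: Iterable[tuple[PitchDataset, float]],
    days: Sequence[int] | None = None,
    epoch: str = "shift",
    response: str = "iteration",
) -> LmmFit:
    """Fit the nested LMM across condition-labeled cohorts.

    ``datasets`` pairs each cohort with its condition value x (e.g. shift
    direction -1/0/+1, or 0/1 for pooled shift vs no shift).  Raises on a
    constant condition vector; singular or non-converged fits are returned
    with diagnostic flags rather than silently.
    """
    table = build_response_table(datasets, days=days, epoch=epoch, response=response)
    if table["x"].nunique() < 2:
        raise LmmError("condition vector is constant; no contrast to estimate")

    # a (near-)perfect linear design cannot support REML variance estimation;
    # fall back to OLS and flag the fit as degenerate
    ols = smf.ols("st ~ x", table).fit()
    if float(np.std(ols.resid)) < 1e-10:
        return LmmFit(
            beta0=float(ols.params["Intercept"]),
            beta1=float(ols.params["x"]),
            beta1_se=float(ols.bse["x"]),
            t_fixed=float(ols.tvalues["x"]),
            p_fixed=float(ols.pvalues["x"]),
            residual_sd=0.0,
            n_obs=int(ols.nobs),
            converged=True,
            diagnostics=["degenerate: zero residual variance; random effects unidentifiable; OLS fallback"],
        )

    diagnostics: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(
            "st ~ x",
            table,
            groups="bird",
            re_formula="1",
            vc_formula={"syll": "0 + C(syll)"},
        )
        fit = model.fit(reml=True)
        for w in caught:
            diagnostics.append(f"{w.category.__name__}: {w.message}")

    converged = bool(getattr(fit, "converged", True))
    if not converged:
        diagnostics.append("optimizer did not converge")

    bird_re: dict[str, float] = {}
    syll_re: dict[str, float] = {}
    for g, re in fit.random_effects.items():
        for key, val in re.items():
            if key.startswith("syll"):
                syll_re[key.replace("syll[C(syll)[", "").rstrip("]")] = float(val)
            else:  # the group (bird) intercept, whatever statsmodels named it
                bird_re[g] = float(val)

    sigma_bird = float(np.sqrt(max(fit.cov_re.iloc[0, 0], 0.0)))
    sigma_syll = float(np.sqrt(max(fit.vcomp[0], 0.0))) if len(fit.vcomp) else 0.0

    return LmmFit(
        beta0=float(fit.params["Intercept"]),
        beta1=float(fit.params["x"]),
        beta1_se=float(fit.bse["x"]),
        t_fixed=float(fit.tvalues["x"]),
        p_fixed=float(fit.pvalues["x"]),
        residual_sd=float(np.sqrt(fit.scale)),
        bird_intercepts=bird_re,
        syllable_intercepts=syll_re,
        sigma_bird=sigma_bird,
        sigma_syllable=sigma_syll,
        n_obs=int(fit.nobs),
        converged=converged,
        diagnostics=diagnostics,
    )
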