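"""Lesion-extent quantification from per-section optical densities.

Dopaminergic denervation of Area X is read out histologically: in sections
stained for tyrosine hydroxylase, intact Area X is darker than surrounding
striatum, so the optical-density ratio OD_AreaX / OD_striatum drops when
terminals are ablated.  A section counts as lesioned when its OD ratio is
strictly below the 5th percentile of the saline-injected control sections;
the fraction of such sections measures lesion extent at the population and
per-bird level.  A two-sample Kolmogorov-Smirnov test checks that the
lesioned and saline ratio populations are distinct, and Pearson
correlations relate per-bird lesion extent to behavioral pitch metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats


class LesionDataError(ValueError):
    pass


def od_ratio(od_areax, od_striatum):
    """OD ratio of Area X to striatum for a section (vectorized)."""
    a = np.asarray(od_areax, dtype=float)
    s = np.asarray(od_striatum, dtype=float)
    if np.any(s <= 0):
        raise LesionDataError("striatum OD must be strictly positive")
    out = a / s
    return out.item() if np.isscalar(od_areax) and np.isscalar(od_striatum) else out


def lesion_threshold(saline_ratios, percentile: float = 5.0) -> float:
    """Saline-population OD-ratio percentile defining the lesion threshold.

    Uses linear interpolation between closest ranks (numpy's default); the
    convention matters at small section counts and is recorded in output
    metadata.
    """
    x = np.asarray(saline_ratios, dtype=float)
    if len(x) < 2:
        raise LesionDataError("need at least 2 saline sections for a percentile")
    return float(np.percentile(x, percentile, method="linear"))


def lesion_extent(
    ratios, threshold: float, bird_ids=None
) -> tuple[float, dict | None]:
    """Fraction of sections strictly below the threshold.

    Returns the population fraction and, when ``bird_ids`` is given, a
    per-bird map of fractions whose section-count-weighted average equals
    the population fraction exactly.
    """
    x = np.asarray(ratios, dtype=float)
    if not np.isfinite(threshold):
        raise LesionDataError("threshold must be finite")
    below = x < threshold  # strict: a section at the threshold is not lesioned
    overall = float(below.mean()) if len(x) else 0.0
    per_bird = None
    if bird_ids is not None:
        s = pd.Series(below, index=pd.Index(bird_ids, name="bird_id"))
        per_bird = s.groupby(level=0).mean().astype(float).to_dict()
    return overall, per_bird


def ks_compare(saline_ratios, lesion_ratios, method: str | None = None):
    """Two-sample Kolmogorov-Smirnov comparison of OD-ratio populations.

    Uses the asymptotic null distribution by default, switching to the
    exact small-sample computation when fewer than 50 sections total.
    """
    a = np.asarray(saline_ratios, dtype=float)
    b = np.asarray(lesion_ratios, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise LesionDataError("both populations must be non-empty")
    if method is None:
        method = "exact" if len(a) + len(b) < 50 else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def lesion_behavior_correlation(
    per_bird_extent: Mapping, per_bird_metric: Mapping
) -> tuple[float, float]:
    """Pearson correlation between per-bird lesion extent and a song metric."""
    birds = sorted(set(per_bird_extent) & set(per_bird_metric))
    if len(birds) < 3:
        raise LesionDataError("need at least 3 paired birds for a correlation")
    x = np.array([per_bird_extent[b] for b in birds], dtype=float)
    y = np.array([per_bird_metric[b] for b in birds], dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise LesionDataError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class LesionSummary:
    threshold: float
    population_fraction_below: float
    per_bird_extent: dict
    ks_statistic: float
    ks_p: float
    percentile: float = 5.0
    percentile_convention: str = "linear interpolation between closest ranks"

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "population_fraction_below": self.population_fraction_below,
            "per_bird_extent": self.per_bird_extent,
            "ks_statistic": self.ks_statistic,
            "ks_p": self.ks_p,
            "percentile": self.percentile,
            "percentile_convention": self.percentile_convention,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def summarize_lesions(od_table: pd.DataFrame, percentile: float = 5.0) -> LesionSummary:
    """Full lesion analysis from a per-section OD table.

    Expects columns ``bird_id, group, od_areax, od_striatum`` with group
    labels ``saline`` and ``lesioned``.
    """
    for col in ("bird_id", "group", "od_areax", "od_striatum"):
        if col not in od_table.columns:
            raise LesionDataError(f"OD table missing column {col!r}")
    ratios = od_ratio(od_table["od_areax"].to_numpy(), od_table["od_striatum"].to_numpy())
    od_table = od_table.assign(od_ratio=ratios)
    saline = od_table[od_table["group"] == "saline"]
    lesioned = od_table[od_table["group"] == "lesioned"]
    if len(saline) == 0 or len(lesioned) == 0:
        raise LesionDataError("OD table must contain both saline and lesioned groups")
    thr = lesion_threshold(saline["od_ratio"], percentile)
    frac, per_bird = lesion_extent(
        lesioned["od_ratio"].to_numpy(), thr, bird_ids=lesioned["bird_id"]
    )
    k, p = ks_compare(saline["od_ratio"], lesioned["od_ratio"])
    return LesionSummary(
        threshold=thr,
        population_fraction_below=frac,
        per_bird_extent=per_bird,
        ks_statistic=k,
        ks_p=p,
        percentile=percentile,
    )


def correlation_table(
    per_bird_extent: Mapping, metrics: Mapping[str, Mapping]
) -> pd.DataFrame:
    """Lesion-extent vs song-metric correlation table (one row per metric)."""
    rows = []
    for name, metric in metrics.items():
        r, p = lesion_behavior_correlation(per_bird_extent, metric)
        rows.append({"metric": name, "pearson_r": r, "p_value": p})
    return pd.DataFrame(rows)
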