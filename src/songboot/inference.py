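"""Posterior-probability hypothesis tests on bootstrap distributions.

Treating the population of resampled means as a posterior for a group mean,
a comparison against a constant is the fraction of resampled means at or
above the constant, and a comparison between two groups is the volume of
their joint (product) distribution on one side of the unity line, the line
itself included.  A probability is significant two-ways at level alpha when
it falls below alpha/2 or above 1 - alpha/2 (0.025 / 0.975 at alpha=0.05),
with a Bonferroni correction applied to alpha for multiple comparisons.

Because the resampled populations are finite (N draws each), probabilities
of exactly 0 or 1 are reported numerically as such but rendered with the
resolution bound of the procedure ("p < 1/N" / "p > 1 - 1/N").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bootstrap import BootstrapResult


@dataclass(frozen=True)
class ComparisonResult:
    """A posterior probability with its two-way significance decision."""

    probability: float
    alpha: float = 0.05
    n_comparisons: int = 1
    n_resamples: int | None = None  # resolution of the underlying bootstrap
    mode: str = "all-pairs"  # joint-distribution convention for group tests

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_comparisons < 1:
            raise ValueError("n_comparisons must be >= 1")

    @property
    def alpha_adjusted(self) -> float:
        return self.alpha / self.n_comparisons

    @property
    def lower_threshold(self) -> float:
        return self.alpha_adjusted / 2.0

    @property
    def upper_threshold(self) -> float:
        return 1.0 - self.alpha_adjusted / 2.0

    @property
    def direction(self) -> str:
        if self.probability > self.upper_threshold:
            return "greater"
        if self.probability < self.lower_threshold:
            return "lesser"
        return "none"

    @property
    def significant(self) -> bool:
        return self.direction != "none"

    def render_probability(self) -> str:
        """Human-readable p, honoring the 1/N resampling resolution bound."""
        if self.n_resamples:
            bound = 1.0 / self.n_resamples
            if self.probability <= 0.0:
                return f"p < {bound:g}"
            if self.probability >= 1.0:
                return f"p > {1.0 - bound:g}"
        return f"p = {self.probability:.4g}"

    def to_dict(self) -> dict:
        return {
            "probability": self.probability,
            "rendered": self.render_probability(),
            "alpha": self.alpha,
            "n_comparisons": self.n_comparisons,
            "thresholds": [self.lower_threshold, self.upper_threshold],
            "significant": self.significant,
            "direction": self.direction,
            "mode": self.mode,
        }


def decide(
    probability: float,
    alpha: float = 0.05,
    n_comparisons: int = 1,
    n_resamples: int | None = None,
    mode: str = "all-pairs",
) -> ComparisonResult:
    """Two-way significance decision at a Bonferroni-adjusted level."""
    return ComparisonResult(
        probability=float(probability),
        alpha=alpha,
        n_comparisons=n_comparisons,
        n_resamples=n_resamples,
        mode=mode,
    )


def prob_ge_constant(
    result: BootstrapResult,
    c: float = 0.0,
    alpha: float = 0.05,
    n_comparisons: int = 1,
) -> ComparisonResult:
    """P(group mean >= c): fraction of resampled means at or above ``c``."""
    means = np.asarray(result.resampled_means)
    if len(means) == 0:
        raise ValueError("empty bootstrap population")
    p = float(np.count_nonzero(means >= c)) / len(means)
    return decide(p, alpha, n_comparisons, n_resamples=len(means))


def prob_group_ge(
    a: BootstrapResult,
    b: BootstrapResult,
    alpha: float = 0.05,
    n_comparisons: int = 1,
    paired: bool = False,
) -> ComparisonResult:
    """P(mean of group a >= mean of group b) from the joint distribution.

    Default (``paired=False``) treats the two bootstrap populations as
    independent and computes the exact all-pairs probability
    (1/(Na*Nb)) * #{(i, j): a_i >= b_j} by sorting b and binary-searching
    each a_i — never by subsampling pairs.  ``paired=True`` compares
    index-by-index instead (requires equal N), for sensitivity analysis.
    """
    av = np.asarray(a.resampled_means)
    bv = np.asarray(b.resampled_means)
    if len(av) == 0 or len(bv) == 0:
        raise ValueError("empty bootstrap population")
    if paired:
        if len(av) != len(bv):
            raise ValueError("paired comparison requires equal-length populations")
        p = float(np.count_nonzero(av >= bv)) / len(av)
        mode = "paired"
    else:
        b_sorted = np.sort(bv)
        counts = np.searchsorted(b_sorted, av, side="right")
        p = float(counts.sum()) / (len(av) * len(bv))
        mode = "all-pairs"
    return decide(p, alpha, n_comparisons, n_resamples=min(len(av), len(bv)), mode=mode)
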