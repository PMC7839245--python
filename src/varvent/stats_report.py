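"""Study-planning and summary statistics.

Covers the quantitative planning arithmetic of a two-arm animal study:
noncentral-t sample-size estimation for a two-sided two-sample comparison,
inflation of the recruited count for expected dropout, percent change versus
baseline, and the Pearson correlation used to relate tissue elastance to the
oxygenation index.  Routine inferential tests (repeated-measures ANOVA,
Mann-Whitney) are deliberately thin wrappers over standard tooling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PowerSpec",
    "two_sample_power",
    "sample_size_two_groups",
    "inflate_for_dropout",
    "relative_change",
    "pearson_correlation",
    "study_plan",
    "mann_whitney",
]


@dataclass(frozen=True)
class PowerSpec:
    """Power-analysis inputs: detect a 20% between-group difference against
    15% interindividual variation at 80% power, two-sided alpha 0.05, with a
    10% expected dropout."""

    detect_diff: float = 20.0         # percent difference between groups
    interindividual_cv: float = 15.0  # percent
    power: float = 0.8
    alpha: float = 0.05
    dropout_rate: float = 0.10

    def __post_init__(self) -> None:
        if self.detect_diff <= 0 or self.interindividual_cv <= 0:
            raise ValueError("detect_diff and interindividual_cv must be positive")
        if not 0.0 < self.power < 1.0:
            raise ValueError("power must lie in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")

    @property
    def effect_size(self) -> float:
        """Standardized difference d = detect_diff / interindividual_cv."""
        return self.detect_diff / self.interindividual_cv


def two_sample_power(effect_size: float, n_per_group: int,
                     alpha: float = 0.05) -> float:
    """Exact power of the two-sided two-sample t test via the noncentral t."""
    if n_per_group < 2:
        return 0.0
    df = 2 * n_per_group - 2
    nc = effect_size * math.sqrt(n_per_group / 2.0)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(1.0 - stats.nct.cdf(tcrit, df, nc)
                 + stats.nct.cdf(-tcrit, df, nc))


def sample_size_two_groups(spec: PowerSpec,
                           n_max: int = 10**6) -> tuple[int, float]:
    """Smallest per-group n achieving the requested power.

    Iterates n upward, evaluating the exact noncentral-t power at each n
    (the normal approximation undershoots by one animal at these settings).
    Returns ``(n, achieved power)``.
    """
    d = spec.effect_size
    for n in range(2, n_max + 1):
        p = two_sample_power(d, n, spec.alpha)
        if p >= spec.power:
            return n, p
    raise ValueError(f"requested power unreachable within n <= {n_max}")


def inflate_for_dropout(n_total: int, dropout_rate: float) -> int:
    """Recruited count covering an expected dropout: round-half-up of
    ``n_total * (1 + rate)``."""
    if n_total < 1:
        raise ValueError("n_total must be at least 1")
    if not 0.0 <= dropout_rate < 1.0:
        raise ValueError("dropout_rate must lie in [0, 1)")
    return int(math.floor(n_total * (1.0 + dropout_rate) + 0.5))


def relative_change(value: float, baseline: float) -> float:
    """Percent change versus baseline: 100 * (value - baseline) / baseline."""
    if baseline == 0:
        raise ValueError("baseline must be nonzero")
    return 100.0 * (value - baseline) / baseline


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("series must share one length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def study_plan(spec: PowerSpec | None = None) -> dict:
    """Full enrolment plan: per-group n, total, and recruited count."""
    spec = spec or PowerSpec()
    n, power = sample_size_two_groups(spec)
    n_total = 2 * n
    return {"n_per_group": n, "n_total": n_total,
            "n_recruit": inflate_for_dropout(n_total, spec.dropout_rate),
            "achieved_power": power, "effect_size": spec.effect_size}


def mann_whitney(x, y, **kwargs):
    """Thin delegation to the standard rank-sum test."""
    return stats.mannwhitneyu(x, y, **kwargs)
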