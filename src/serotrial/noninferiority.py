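"""Non-inferiority analyses: score intervals, MOVER ratio intervals, gating.

Two co-primary comparisons are supported:

1. *Rate difference* (percentage points) between two groups' seroprotection
   rates, with a Miettinen-Nurminen asymptotic score confidence interval.
   Non-inferiority holds when the CI lower limit is at or above the margin
   (default -10 percentage points).
2. *GMC ratio* of a study group over a fixed external comparator, with a
   MOVER (method of variance estimates recovery) interval built from the
   two groups' separate t-intervals on the log scale — this accommodates
   unequal variances between studies. Non-inferiority holds when the CI
   lower limit is at or above the ratio margin (default 0.67).

The two objectives are assessed hierarchically: the ratio objective is
evaluated only if the rate-difference objective passes.

Notes on the score interval
---------------------------
The Miettinen-Nurminen statistic for a difference ``d = p1 - p2`` uses the
restricted maximum-likelihood estimates of (p1, p2) under the constraint
``p1 - p2 = d`` (the Farrington-Manning closed-form cubic solution) in the
variance, multiplied by the small-sample factor ``N / (N - 1)``. The CI is
the set of ``d`` where the statistic stays below the normal quantile;
bounds are found by root bisection. The Newcombe hybrid-score interval
(square-and-add of the two Wilson intervals) is provided as a labelled
alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .serology import gmc_ci_from_logstats

__all__ = [
    "ComparatorSummary",
    "HierarchyReport",
    "LogStats",
    "NIConfig",
    "NoninferiorityResult",
    "assess_hierarchy",
    "gmc_ratio_ci_mover",
    "gmc_ratio_point",
    "newcombe_hybrid_ci",
    "rate_difference_ci",
]

_BISECT_TOL = 1e-10


class LogStats(NamedTuple):
    """log10-scale summary of one group: mean, SD, sample size."""

    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class NIConfig:
    """Margins and level of the hierarchical non-inferiority assessment."""

    rate_margin: float = -10.0   # percentage points, lower limit must be >= this
    ratio_margin: float = 0.67   # GMC ratio, lower limit must be >= this
    level: float = 0.95
    hierarchy: tuple[str, ...] = ("rate_differences", "gmc_ratios")

    def __post_init__(self) -> None:
        if not self.rate_margin < 0:
            raise ValueError("rate margin must be negative (a deficit)")
        if not 0 < self.ratio_margin < 1:
            raise ValueError("ratio margin must be in (0, 1)")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")


@dataclass(frozen=True)
class ComparatorSummary:
    """Fixed external comparator arm for one antigen.

    The log10-scale SD may be supplied directly or back-solved from a
    GMC confidence interval via the t-based CI formula.
    """

    antigen: str
    n: int
    gmc: float
    sd_log10: Optional[float] = None
    ci: Optional[tuple[float, float]] = None
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("comparator n must be >= 2")
        if self.gmc <= 0:
            raise ValueError("comparator GMC must be positive")
        if self.sd_log10 is None and self.ci is None:
            raise ValueError("supply either sd_log10 or a GMC confidence interval")

    def logstats(self) -> LogStats:
        mean = math.log10(self.gmc)
        if self.sd_log10 is not None:
            sd = self.sd_log10
        else:
            lo, hi = self.ci  # type: ignore[misc]
            if not 0 < lo <= hi:
                raise ValueError("invalid comparator CI")
            if hi == lo:
                raise ValueError("zero-width comparator CI cannot identify the SD")
            half = (math.log10(hi) - math.log10(lo)) / 2.0
            tq = stats.t.ppf(1 - (1 - self.level) / 2, self.n - 1)
            sd = half * math.sqrt(self.n) / tq
        return LogStats(mean, sd, self.n)


@dataclass(frozen=True)
class NoninferiorityResult:
    """One component comparison: estimate, CI, margin, verdict."""

    objective: str
    component: str
    estimate: float
    ci_low: float
    ci_high: float
    margin: float

    @property
    def passes(self) -> bool:
        return self.ci_low >= self.margin


def _restricted_mle(p1h: float, p2h: float, n1: int, n2: int, d: float) -> tuple[float, float]:
    """Restricted MLE of (p1, p2) under p1 - p2 = d (Farrington-Manning)."""
    theta = n2 / n1
    a = 1.0 + theta
    b = -(1.0 + theta + p1h + theta * p2h + d * (theta + 2.0))
    c = d * d + d * (2.0 * p1h + theta + 1.0) + p1h + theta * p2h
    e = -p1h * d * (1.0 + d)
    disc = b * b / (9.0 * a * a) - c / (3.0 * a)
    v = b**3 / (27.0 * a**3) - b * c / (6.0 * a * a) + e / (2.0 * a)
    if disc <= 0:
        p1 = p1h  # degenerate: both rates equal, constraint already satisfied
    else:
        u = math.sqrt(disc)
        w = (math.pi + math.acos(max(-1.0, min(1.0, v / u**3)))) / 3.0
        p1 = 2.0 * u * math.cos(w) - b / (3.0 * a)
    p1 = min(max(p1, max(d, 0.0)), min(1.0, 1.0 + d))
    return p1, p1 - d


def _mn_score(x1: int, n1: int, x2: int, n2: int, d: float, corrected: bool) -> float:
    """Miettinen-Nurminen score statistic at difference d (proportion scale)."""
    p1h, p2h = x1 / n1, x2 / n2
    num = p1h - p2h - d
    p1, p2 = _restricted_mle(p1h, p2h, n1, n2, d)
    var = p1 * (1.0 - p1) / n1 + p2 * (1.0 - p2) / n2
    if corrected:
        total = n1 + n2
        var *= total / (total - 1.0)
    if var <= 0:
        return 0.0 if num == 0 else math.inf * math.copysign(1.0, num)
    return num / math.sqrt(var)


def rate_difference_ci(
    x1: int,
    n1: int,
    x2: int,
    n2: int,
    level: float = 0.95,
    corrected: bool = True,
) -> tuple[float, float, float]:
    """Rate difference (group1 - group2) with Miettinen-Nurminen score CI.

    Parameters
    ----------
    x1, n1, x2, n2
        Successes and sizes of the two groups; the difference is taken as
        ``x1/n1 - x2/n2``.
    level
        Two-sided confidence level.
    corrected
        Apply the ``N/(N-1)`` small-sample variance factor (the default,
        the Miettinen-Nurminen form; False gives the uncorrected
        Mee/Farrington-Manning form).

    Returns
    -------
    (difference, lower, upper) in percentage points.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1:
            raise ValueError("group sizes must be >= 1")
        if not 0 <= x <= n:
            raise ValueError(f"count {x} outside [0, {n}]")
    if n1 + n2 < 3 and corrected:
        raise ValueError("corrected variance undefined for total n < 3")
    z = stats.norm.ppf(1 - (1 - level) / 2)
    diff = x1 / n1 - x2 / n2

    def stat(d: float) -> float:
        return _mn_score(x1, n1, x2, n2, d, corrected)

    eps = 1e-12
    if diff <= -1 + eps:
        lower = -1.0
    else:
        lower = optimize.brentq(
            lambda d: stat(d) - z, -1 + eps, diff, xtol=_BISECT_TOL
        )
    if diff >= 1 - eps:
        upper = 1.0
    else:
        upper = optimize.brentq(
            lambda d: stat(d) + z, diff, 1 - eps, xtol=_BISECT_TOL
        )
    return 100.0 * diff, 100.0 * lower, 100.0 * upper


def newcombe_hybrid_ci(
    x1: int, n1: int, x2: int, n2: int, level: float = 0.95
) -> tuple[float, float, float]:
    """Newcombe hybrid-score (square-and-add Wilson) interval, alternative
    to :func:`rate_difference_ci`. Returns (difference, lower, upper) in
    percentage points."""
    z = stats.norm.ppf(1 - (1 - level) / 2)

    def wilson(x: int, n: int) -> tuple[float, float]:
        p = x / n
        denom = 1 + z * z / n
        center = (p + z * z / (2 * n)) / denom
        half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
        return center - half, center + half

    p1, p2 = x1 / n1, x2 / n2
    l1, u1 = wilson(x1, n1)
    l2, u2 = wilson(x2, n2)
    diff = p1 - p2
    lower = diff - math.sqrt((p1 - l1) ** 2 + (u2 - p2) ** 2)
    upper = diff + math.sqrt((u1 - p1) ** 2 + (p2 - l2) ** 2)
    return 100.0 * diff, 100.0 * lower, 100.0 * upper


def gmc_ratio_point(gmc1: float, gmc2: float) -> float:
    """Point GMC ratio, group1 over group2."""
    if gmc1 <= 0 or gmc2 <= 0:
        raise ValueError("GMCs must be positive")
    return gmc1 / gmc2


def gmc_ratio_ci_mover(
    group1: LogStats, group2: LogStats, level: float = 0.95
) -> tuple[float, float, float]:
    """MOVER confidence interval for a ratio of geometric means.

    Each group's log10-scale mean gets its own t-interval
    ``(l_i, u_i) = m_i -/+ t_{n_i - 1} * s_i / sqrt(n_i)``; the interval for
    the log-ratio ``d = m1 - m2`` recovers the variance estimates from
    those bounds::

        L = d - sqrt((m1 - l1)^2 + (u2 - m2)^2)
        U = d + sqrt((u1 - m1)^2 + (m2 - l2)^2)

    and the result is anti-logged. With unequal group variances this keeps
    closer to nominal coverage than a pooled two-sample t interval.

    Returns
    -------
    (ratio, lower, upper) on the concentration-ratio scale.
    """
    for g in (group1, group2):
        if g.n < 2:
            raise ValueError("each group needs n >= 2")
        if g.sd <= 0:
            raise ValueError("each group needs a positive log-scale SD")
    l1, u1 = np.log10(gmc_ci_from_logstats(group1.mean, group1.sd, group1.n, level))
    l2, u2 = np.log10(gmc_ci_from_logstats(group2.mean, group2.sd, group2.n, level))
    d = group1.mean - group2.mean
    lower = d - math.sqrt((group1.mean - l1) ** 2 + (u2 - group2.mean) ** 2)
    upper = d + math.sqrt((u1 - group1.mean) ** 2 + (group2.mean - l2) ** 2)
    return 10.0**d, 10.0**lower, 10.0**upper


@dataclass(frozen=True)
class HierarchyReport:
    """Outcome of the hierarchical co-primary assessment."""

    objective1_pass: bool
    objective2_evaluated: bool
    objective2_pass: Optional[bool]
    results: tuple[NoninferiorityResult, ...] = field(default=())

    @property
    def overall_pass(self) -> bool:
        return self.objective1_pass and bool(self.objective2_pass)

    def describe(self) -> str:
        lines = []
        o1 = "PASS" if self.objective1_pass else "FAIL"
        lines.append(f"Objective 1 (seroprotection rate differences): {o1}")
        if not self.objective2_evaluated:
            lines.append("Objective 2 (GMC ratios): not evaluated (gated)")
        else:
            o2 = "PASS" if self.objective2_pass else "FAIL"
            lines.append(f"Objective 2 (GMC ratios): {o2}")
        verdict = "met" if self.overall_pass else "not met"
        lines.append(f"Overall: co-primary non-inferiority objectives {verdict}")
        for r in self.results:
            lines.append(
                f"  [{r.objective}] {r.component}: estimate {r.estimate:.2f}, "
                f"95% CI ({r.ci_low:.2f}, {r.ci_high:.2f}), margin {r.margin}, "
                f"{'pass' if r.passes else 'fail'}"
            )
        return "\n".join(lines)


def assess_hierarchy(
    results: Sequence[NoninferiorityResult], config: NIConfig = NIConfig()
) -> HierarchyReport:
    """Apply the hierarchical gate to the component comparisons.

    ``results`` must contain at least one result labelled with each
    objective in ``config.hierarchy``. Objective 1 passes iff every one of
    its components' CI lower limits is at or above the rate margin;
    objective 2 is evaluated only then, and passes iff every ratio lower
    limit is at or above the ratio margin.
    """
    obj1_name, obj2_name = config.hierarchy
    obj1 = [r for r in results if r.objective == obj1_name]
    obj2 = [r for r in results if r.objective == obj2_name]
    if not obj1 or not obj2:
        raise ValueError(
            f"results must include components for both {obj1_name!r} and {obj2_name!r}"
        )
    obj1_pass = all(r.passes for r in obj1)
    if not obj1_pass:
        return HierarchyReport(False, False, None, tuple(results))
    obj2_pass = all(r.passes for r in obj2)
    return HierarchyReport(True, True, obj2_pass, tuple(results))
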