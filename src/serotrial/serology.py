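"""Core serology estimators.

Censoring imputation, geometric mean concentrations (GMC) with t-based
confidence intervals on the log10 scale, threshold rates with exact
(Clopper-Pearson) confidence intervals, and fold-rise ratios.

Conventions
-----------
* Concentrations are IU/ml and strictly positive.
* Left-censored values (below the assay cut-off) are imputed to half the
  cut-off before any analysis.
* Threshold comparisons are inclusive (``>=``).
* GMC = 10**(mean of log10 concentrations); its CI uses the Student t
  quantile with n-1 degrees of freedom on the log10 scale.
* Rates are reported on the percentage scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assays import AssayDefinition

__all__ = [
    "GMCResult",
    "ThresholdRate",
    "clopper_pearson_ci",
    "fold_rise",
    "gmc_ci_from_logstats",
    "gmc_with_ci",
    "impute_censored",
    "rate_above_threshold",
    "summarize_serology",
]

#: serology table schema (one row per participant x antigen x visit)
SEROLOGY_COLUMNS = [
    "participant_id",
    "group",
    "antigen",
    "visit",
    "concentration_IU_ml",
    "censored",
]


def clopper_pearson_ci(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval, percentage scale.

    The Clopper-Pearson interval: lower bound is the ``alpha/2`` quantile of
    Beta(x, n-x+1), upper the ``1-alpha/2`` quantile of Beta(x+1, n-x); the
    lower bound is 0 when ``x == 0`` and the upper 100 when ``x == n``.

    Parameters
    ----------
    x
        Number of successes, ``0 <= x <= n``.
    n
        Number of trials, ``n >= 1``.
    level
        Two-sided confidence level in (0, 1).

    Returns
    -------
    (lower, upper) in percent.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= x <= n:
        raise ValueError(f"x must be in [0, {n}], got {x}")
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else stats.beta.ppf(alpha / 2, x, n - x + 1)
    upper = 1.0 if x == n else stats.beta.ppf(1 - alpha / 2, x + 1, n - x)
    return 100.0 * lower, 100.0 * upper


@dataclass(frozen=True)
class GMCResult:
    """Geometric mean concentration with its confidence interval (IU/ml)."""

    gmc: float
    lower: float
    upper: float
    n: int

    @property
    def ci_defined(self) -> bool:
        return not (math.isnan(self.lower) or math.isnan(self.upper))


@dataclass(frozen=True)
class ThresholdRate:
    """Rate of concentrations at or above a threshold, with exact CI."""

    threshold: float
    x: int
    n: int
    pct: float
    lower: float
    upper: float


def impute_censored(records: pd.DataFrame, assay: AssayDefinition) -> pd.DataFrame:
    """Replace left-censored concentrations by half the assay cut-off.

    Parameters
    ----------
    records
        Serology rows for a single antigen, with columns
        ``concentration_IU_ml`` and ``censored`` (0/1 or bool). An
        ``antigen`` column, if present, must match ``assay.antigen``.
    assay
        The assay whose cut-off applies.

    Returns
    -------
    A copy with every censored row's concentration set to ``cutoff / 2``
    and ``censored`` preserved; uncensored rows and row order unchanged.
    """
    if "antigen" in records.columns:
        foreign = set(records["antigen"].unique()) - {assay.antigen}
        if foreign:
            raise ValueError(
                f"records contain antigens {sorted(foreign)} but assay is "
                f"{assay.antigen!r}"
            )
    out = records.copy()
    mask = out["censored"].astype(bool)
    out.loc[mask, "concentration_IU_ml"] = assay.cutoff / 2.0
    return out


def rate_above_threshold(
    concentrations: Iterable[float], threshold: float, level: float = 0.95
) -> ThresholdRate:
    """Count concentrations at or above ``threshold`` (inclusive) with exact CI.

    Imputation must already have been applied; imputed values (half the
    cut-off) can never reach a threshold at or above the cut-off, so the
    count is insensitive to the imputation constant.
    """
    conc = np.asarray(list(concentrations), dtype=float)
    if conc.size == 0:
        raise ValueError("empty record set")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    n = int(conc.size)
    x = int(np.count_nonzero(conc >= threshold))
    lower, upper = clopper_pearson_ci(x, n, level)
    return ThresholdRate(threshold, x, n, 100.0 * x / n, lower, upper)


def gmc_with_ci(concentrations: Iterable[float], level: float = 0.95) -> GMCResult:
    """Geometric mean concentration with a t-based CI on the log10 scale.

    ``GMC = 10**mean(log10 c)``; the CI is
    ``10**(mean +/- t_{n-1, 1-alpha/2} * sd / sqrt(n))``. For ``n == 1``
    the interval is undefined and returned as NaN bounds.
    """
    conc = np.asarray(list(concentrations), dtype=float)
    if conc.size == 0:
        raise ValueError("empty record set")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    logs = np.log10(conc)
    n = int(conc.size)
    mean = float(np.mean(logs))
    if n == 1:
        return GMCResult(10.0**mean, math.nan, math.nan, 1)
    sd = float(np.std(logs, ddof=1))
    lower, upper = gmc_ci_from_logstats(mean, sd, n, level)
    return GMCResult(10.0**mean, lower, upper, n)


def gmc_ci_from_logstats(
    mean_log10: float, sd_log10: float, n: int, level: float = 0.95
) -> tuple[float, float]:
    """CI for a GMC from its log10-scale summary statistics.

    Shared by :func:`gmc_with_ci`, the cohort calibration round-trip and
    the MOVER per-group intervals, so all three use one formula.
    """
    if n < 2:
        raise ValueError("log-stat CI requires n >= 2")
    if sd_log10 < 0:
        raise ValueError("sd must be nonnegative")
    tq = stats.t.ppf(1 - (1 - level) / 2, n - 1)
    half = tq * sd_log10 / math.sqrt(n)
    return 10.0 ** (mean_log10 - half), 10.0 ** (mean_log10 + half)


def fold_rise(pre_gmc: float, post_gmc: float) -> float:
    """Post/pre GMC ratio. Both inputs must be positive."""
    if pre_gmc <= 0 or post_gmc <= 0:
        raise ValueError("GMCs must be positive")
    return post_gmc / pre_gmc


def summarize_serology(
    records: pd.DataFrame,
    assays: dict[str, AssayDefinition],
    level: float = 0.95,
    impute: bool = True,
) -> pd.DataFrame:
    """Per group x antigen x visit summary: N, threshold rates, GMC.

    Parameters
    ----------
    records
        Serology table with :data:`SEROLOGY_COLUMNS`.
    assays
        Assay definitions keyed by antigen; every antigen in ``records``
        must be defined.
    level
        Confidence level for all intervals.
    impute
        Apply half-cut-off imputation first (the standard analysis path).
        Set False only if the input is already imputed.

    Returns
    -------
    DataFrame with one row per (group, antigen, visit, threshold):
    columns ``group, antigen, visit, N, threshold, x, pct, ci_low, ci_high,
    gmc, gmc_low, gmc_high``. The GMC columns repeat across an antigen's
    threshold rows.
    """
    missing = set(records["antigen"].unique()) - set(assays)
    if missing:
        raise ValueError(f"no assay definition for antigens {sorted(missing)}")
    rows = []
    for (group, antigen, visit), sub in records.groupby(
        ["group", "antigen", "visit"], sort=True, observed=True
    ):
        assay = assays[antigen]
        if impute:
            sub = impute_censored(sub, assay)
        conc = sub["concentration_IU_ml"].to_numpy(dtype=float)
        g = gmc_with_ci(conc, level)
        for thr in assay.rate_thresholds:
            r = rate_above_threshold(conc, thr, level)
            rows.append(
                {
                    "group": group,
                    "antigen": antigen,
                    "visit": visit,
                    "N": r.n,
                    "threshold": thr,
                    "x": r.x,
                    "pct": r.pct,
                    "ci_low": r.lower,
                    "ci_high": r.upper,
                    "gmc": g.gmc,
                    "gmc_low": g.lower,
                    "gmc_high": g.upper,
                }
            )
    return pd.DataFrame(rows)


def fold_rise_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Post/pre GMC fold-rise per group x antigen from a serology summary.

    Expects the output of :func:`summarize_serology` containing both
    ``pre`` and ``post`` visits.
    """
    gmcs = (
        summary.drop_duplicates(["group", "antigen", "visit"])
        .pivot(index=["group", "antigen"], columns="visit", values="gmc")
        .reset_index()
    )
    if not {"pre", "post"} <= set(gmcs.columns):
        raise ValueError("summary must contain both 'pre' and 'post' visits")
    gmcs["fold_rise"] = [
        fold_rise(pre, post) for pre, post in zip(gmcs["pre"], gmcs["post"])
    ]
    return gmcs[["group", "antigen", "pre", "post", "fold_rise"]]
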