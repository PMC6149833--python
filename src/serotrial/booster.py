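"""Tiered booster-response classification.

A booster response is judged one month post-vaccination from the pair
(pre, post) of antibody concentrations, with the criterion depending on
baseline serostatus:

Diphtheria / tetanus (standard definition)
    * initially seronegative (pre < 0.1 IU/ml): responder iff
      post >= 0.4 IU/ml;
    * initially seropositive (pre >= 0.1 IU/ml): responder iff a >=4-fold
      rise.

Diphtheria / tetanus (alternative definition)
    Participants with pre >= 6.0 IU/ml are excluded, then:
    * pre < 0.1: responder iff post >= 0.4;
    * 0.1 <= pre < 1.0: responder iff >=4-fold rise;
    * 1.0 <= pre < 6.0: responder iff >=2-fold rise.

Pertussis antigens (single definition, thresholds scale with the assay
cut-off c)
    * seronegative (pre < c): responder iff post >= 4c;
    * seropositive with pre < 4c: responder iff >=4-fold rise;
    * seropositive with pre >= 4c: responder iff >=2-fold rise.

All ">="-phrased boundaries are inclusive; "<" is strict. Fold ratios are
computed on imputed concentrations (censored values already set to half
the cut-off).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .assays import AssayDefinition
from .serology import clopper_pearson_ci

__all__ = [
    "BoosterRules",
    "ResponseCall",
    "classify_dt",
    "classify_dt_alternative",
    "classify_pertussis",
    "tabulate_responses",
]

# stratum labels as used in reporting
SERONEG = "S-"
SEROPOS = "S+"
SEROPOS_LOW = "S+ (<4*cutoff)"
SEROPOS_HIGH = "S+ (>=4*cutoff)"


@dataclass(frozen=True)
class BoosterRules:
    """Thresholds and fold factors of the booster-response definitions.

    Defaults are the protocol values; all concentrations in IU/ml.
    """

    dt_seroneg_threshold: float = 0.1   # below: initially seronegative (D/T)
    dt_response_level: float = 0.4      # absolute post level for seronegatives
    dt_fold_seropos: float = 4.0        # fold rise for seropositives
    alt_exclusion_level: float = 6.0    # alternative definition: pre >= 6 excluded
    alt_mid_level: float = 1.0          # alternative: boundary of 4-fold / 2-fold tiers
    alt_fold_low: float = 4.0
    alt_fold_mid: float = 2.0
    pert_fold_low: float = 4.0          # pertussis seropositive, pre < 4*cutoff
    pert_fold_high: float = 2.0         # pertussis seropositive, pre >= 4*cutoff
    pert_high_multiplier: float = 4.0   # high stratum bound = multiplier * cutoff

    def __post_init__(self) -> None:
        levels = (
            self.dt_seroneg_threshold,
            self.dt_response_level,
            self.alt_exclusion_level,
            self.alt_mid_level,
        )
        if any(v <= 0 for v in levels):
            raise ValueError("all concentration levels must be positive")
        folds = (
            self.dt_fold_seropos,
            self.alt_fold_low,
            self.alt_fold_mid,
            self.pert_fold_low,
            self.pert_fold_high,
            self.pert_high_multiplier,
        )
        if any(v < 1 for v in folds):
            raise ValueError("fold factors must be >= 1")
        if not self.alt_mid_level < self.alt_exclusion_level:
            raise ValueError("alt_mid_level must be below alt_exclusion_level")


DEFAULT_RULES = BoosterRules()


@dataclass(frozen=True)
class ResponseCall:
    """Classification of one participant x antigen pair.

    ``responder`` is None when the participant is excluded (alternative
    definition with high baseline).
    """

    stratum: str
    responder: Optional[bool]
    excluded: bool = False


def _check_pair(pre: float, post: float) -> None:
    if pre <= 0 or post <= 0:
        raise ValueError(f"concentrations must be positive, got pre={pre}, post={post}")


def classify_dt(
    pre: float, post: float, rules: BoosterRules = DEFAULT_RULES
) -> ResponseCall:
    """Standard diphtheria/tetanus booster-response call."""
    _check_pair(pre, post)
    if pre < rules.dt_seroneg_threshold:
        return ResponseCall(SERONEG, post >= rules.dt_response_level)
    return ResponseCall(SEROPOS, post / pre >= rules.dt_fold_seropos)


def classify_dt_alternative(
    pre: float, post: float, rules: BoosterRules = DEFAULT_RULES
) -> ResponseCall:
    """Alternative diphtheria/tetanus call (high baselines excluded)."""
    _check_pair(pre, post)
    if pre >= rules.alt_exclusion_level:
        return ResponseCall("excluded", None, excluded=True)
    if pre < rules.dt_seroneg_threshold:
        return ResponseCall(SERONEG, post >= rules.dt_response_level)
    if pre < rules.alt_mid_level:
        return ResponseCall(SEROPOS, post / pre >= rules.alt_fold_low)
    return ResponseCall(SEROPOS, post / pre >= rules.alt_fold_mid)


def classify_pertussis(
    pre: float,
    post: float,
    assay: AssayDefinition,
    rules: BoosterRules = DEFAULT_RULES,
) -> ResponseCall:
    """Pertussis booster-response call; strata scale with the assay cut-off."""
    _check_pair(pre, post)
    if assay.has_seroprotection:
        raise ValueError(
            f"{assay.antigen!r} has seroprotection thresholds; the pertussis "
            "rule applies only to antigens classified by assay cut-off"
        )
    cutoff = assay.cutoff
    high = rules.pert_high_multiplier * cutoff
    if pre < cutoff:
        return ResponseCall(SERONEG, post >= high)
    if pre < high:
        return ResponseCall(SEROPOS_LOW, post / pre >= rules.pert_fold_low)
    return ResponseCall(SEROPOS_HIGH, post / pre >= rules.pert_fold_high)


def tabulate_responses(
    calls: pd.DataFrame,
    level: float = 0.95,
    strata_order: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Stratified responder rates with exact CIs, plus an overall row.

    Parameters
    ----------
    calls
        One row per classified participant, columns ``stratum``,
        ``responder`` (bool) and ``excluded`` (bool). Excluded rows are
        dropped from every denominator.
    level
        Confidence level for the Clopper-Pearson intervals.
    strata_order
        Strata to report, in order; strata absent from the data are still
        emitted with ``N=0`` and NaN rate/CI (rendered as a dash in
        reports). Defaults to the strata present.

    Returns
    -------
    DataFrame with columns ``stratum, N, responders, pct, ci_low, ci_high``;
    the last row is ``overall``.
    """
    if len(calls) == 0:
        return pd.DataFrame(
            columns=["stratum", "N", "responders", "pct", "ci_low", "ci_high"]
        )
    kept = calls.loc[~calls["excluded"].astype(bool)]
    if strata_order is None:
        strata_order = sorted(kept["stratum"].unique())
    rows = []
    groups = {s: sub for s, sub in kept.groupby("stratum")}
    for stratum in list(strata_order) + ["overall"]:
        sub = kept if stratum == "overall" else groups.get(stratum)
        if sub is None or len(sub) == 0:
            rows.append(
                {
                    "stratum": stratum,
                    "N": 0,
                    "responders": 0,
                    "pct": float("nan"),
                    "ci_low": float("nan"),
                    "ci_high": float("nan"),
                }
            )
            continue
        n = int(len(sub))
        x = int(sub["responder"].astype(bool).sum())
        lo, hi = clopper_pearson_ci(x, n, level)
        rows.append(
            {
                "stratum": stratum,
                "N": n,
                "responders": x,
                "pct": 100.0 * x / n,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows)
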