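"""End-to-end analysis orchestration.

Assembles the analysis cohorts (total vaccinated and according-to-protocol),
runs the immunogenicity estimators on the ATP cohort, the booster-response
classification, the hierarchical non-inferiority assessment, and the safety
tabulation on the total vaccinated cohort, and writes one CSV per table
plus a plain-text decision report. Every number in the outputs comes from
one library operation; the report layer only rounds for display
(percentages and GMCs to one decimal, ratios to two, em-dash for empty
strata).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .assays import DEFAULT_ASSAYS, DT_ANTIGENS, PERTUSSIS_ANTIGENS, AssayDefinition
from .booster import (
    DEFAULT_RULES,
    SERONEG,
    SEROPOS,
    SEROPOS_HIGH,
    SEROPOS_LOW,
    BoosterRules,
    classify_dt,
    classify_dt_alternative,
    classify_pertussis,
    tabulate_responses,
)
from .cohort import Cohort
from .constants import COMPARATOR_DTAP, GROUP_TD, GROUP_TDAP
from .noninferiority import (
    ComparatorSummary,
    HierarchyReport,
    LogStats,
    NIConfig,
    NoninferiorityResult,
    assess_hierarchy,
    gmc_ratio_ci_mover,
    rate_difference_ci,
)
from .safety import (
    DEFAULT_GRADING,
    SOLICITED_WINDOW,
    UNSOLICITED_WINDOW,
    GradingRules,
    tabulate_ae,
)
from .serology import fold_rise_table, impute_censored, summarize_serology

logger = logging.getLogger("serotrial")

__all__ = ["AnalysisConfig", "build_cohorts", "run_full_analysis"]


@dataclass
class AnalysisConfig:
    """Configuration of one full analysis run."""

    assays: dict[str, AssayDefinition] = field(default_factory=lambda: dict(DEFAULT_ASSAYS))
    booster_rules: BoosterRules = DEFAULT_RULES
    ni_config: NIConfig = field(default_factory=NIConfig)
    grading: GradingRules = DEFAULT_GRADING
    comparators: dict[str, ComparatorSummary] = field(
        default_factory=lambda: dict(COMPARATOR_DTAP)
    )
    test_group: str = GROUP_TDAP       # the group under evaluation
    reference_group: str = GROUP_TD    # reference for the rate difference
    seroprotection_threshold: float = 0.1
    immunogenicity_cohort: str = "atp"  # "atp" or "tvc"
    level: float = 0.95


def build_cohorts(participants: pd.DataFrame, serology: pd.DataFrame) -> pd.DataFrame:
    """Derive total-vaccinated and according-to-protocol membership.

    TVC = all vaccinated participants. ATP = protocol-compliant (the
    ``atp`` flag) with both serology visits available. Per-stage counts
    are logged consort-style.
    """
    has_visit = serology.groupby(["participant_id", "visit"]).size().unstack(fill_value=0)
    both = set(
        has_visit.index[(has_visit.get("pre", 0) > 0) & (has_visit.get("post", 0) > 0)]
    )
    out = participants[["participant_id", "group"]].copy()
    out["in_tvc"] = True
    compliant = participants["atp"].astype(bool).to_numpy()
    out["in_atp"] = compliant & participants["participant_id"].isin(both).to_numpy()
    logger.info(
        "cohorts: vaccinated=%d completed=%d atp=%d",
        len(participants),
        int(participants["completed"].astype(bool).sum()),
        int(out["in_atp"].sum()),
    )
    return out


def _imputed(serology: pd.DataFrame, assays: dict[str, AssayDefinition]) -> pd.DataFrame:
    parts = [
        impute_censored(sub, assays[antigen])
        for antigen, sub in serology.groupby("antigen")
    ]
    return pd.concat(parts).sort_index()


def _pairs(serology: pd.DataFrame, antigen: str) -> pd.DataFrame:
    """(pre, post) concentration pairs per participant for one antigen."""
    sub = serology.loc[serology["antigen"] == antigen]
    wide = sub.pivot_table(
        index=["participant_id", "group"],
        columns="visit",
        values="concentration_IU_ml",
        aggfunc="first",
    ).reset_index()
    return wide.dropna(subset=["pre", "post"])


def booster_response_tables(
    serology_imputed: pd.DataFrame,
    assays: dict[str, AssayDefinition],
    rules: BoosterRules = DEFAULT_RULES,
    level: float = 0.95,
) -> pd.DataFrame:
    """All booster-response tables: standard and alternative D/T, pertussis."""
    frames = []
    for antigen in sorted(serology_imputed["antigen"].unique()):
        assay = assays[antigen]
        pairs = _pairs(serology_imputed, antigen)
        for group, sub in pairs.groupby("group"):
            defs: list[tuple[str, list, list[str]]]
            if assay.has_seroprotection:
                std = [classify_dt(r.pre, r.post, rules) for r in sub.itertuples()]
                alt = [
                    classify_dt_alternative(r.pre, r.post, rules)
                    for r in sub.itertuples()
                ]
                defs = [
                    ("booster_response", std, [SERONEG, SEROPOS]),
                    ("alternative_booster_response", alt, [SERONEG, SEROPOS]),
                ]
            else:
                calls = [
                    classify_pertussis(r.pre, r.post, assay, rules)
                    for r in sub.itertuples()
                ]
                defs = [
                    ("booster_response", calls, [SERONEG, SEROPOS_LOW, SEROPOS_HIGH])
                ]
            for name, calls, order in defs:
                df = pd.DataFrame(
                    {
                        "stratum": [c.stratum for c in calls],
                        "responder": [bool(c.responder) for c in calls],
                        "excluded": [c.excluded for c in calls],
                    }
                )
                tab = tabulate_responses(df, level=level, strata_order=order)
                tab.insert(0, "definition", name)
                tab.insert(0, "antigen", antigen)
                tab.insert(0, "group", group)
                frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def noninferiority_analysis(
    serology_imputed: pd.DataFrame,
    atp: pd.DataFrame,
    config: AnalysisConfig,
) -> tuple[HierarchyReport, pd.DataFrame]:
    """Both co-primary comparisons plus the hierarchical gate.

    Objective 1: difference (test - reference) in post-booster
    seroprotection rates for the diphtheria/tetanus antigens, ATP cohort,
    Miettinen-Nurminen interval against the rate margin. Objective 2:
    post-booster GMC ratios of the test group over the fixed external
    comparator for the pertussis antigens, total vaccinated cohort, MOVER
    interval against the ratio margin.
    """
    ni = config.ni_config
    atp_ids = set(atp.loc[atp["in_atp"], "participant_id"])
    post = serology_imputed.loc[serology_imputed["visit"] == "post"]
    results = []
    for antigen in DT_ANTIGENS:
        sub = post.loc[
            (post["antigen"] == antigen) & post["participant_id"].isin(atp_ids)
        ]
        counts = {}
        for grp in (config.test_group, config.reference_group):
            conc = sub.loc[sub["group"] == grp, "concentration_IU_ml"]
            counts[grp] = (
                int((conc >= config.seroprotection_threshold).sum()),
                int(len(conc)),
            )
        (x1, n1), (x2, n2) = counts[config.test_group], counts[config.reference_group]
        diff, lo, hi = rate_difference_ci(x1, n1, x2, n2, ni.level)
        results.append(
            NoninferiorityResult(
                "rate_differences", antigen, diff, lo, hi, ni.rate_margin
            )
        )
    for antigen in PERTUSSIS_ANTIGENS:
        if antigen not in config.comparators:
            continue
        conc = post.loc[
            (post["antigen"] == antigen) & (post["group"] == config.test_group),
            "concentration_IU_ml",
        ].to_numpy()
        logs = np.log10(conc)
        g1 = LogStats(float(logs.mean()), float(logs.std(ddof=1)), len(logs))
        g2 = config.comparators[antigen].logstats()
        ratio, lo, hi = gmc_ratio_ci_mover(g1, g2, ni.level)
        results.append(
            NoninferiorityResult("gmc_ratios", antigen, ratio, lo, hi, ni.ratio_margin)
        )
    report = assess_hierarchy(results, ni)
    table = pd.DataFrame(
        {
            "objective": [r.objective for r in results],
            "component": [r.component for r in results],
            "estimate": [r.estimate for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "margin": [r.margin for r in results],
            "pass": [r.passes for r in results],
        }
    )
    return report, table


def run_full_analysis(
    cohort: Cohort,
    config: Optional[AnalysisConfig] = None,
    outdir: Optional[str | Path] = None,
) -> dict[str, object]:
    """Run every analysis stage on a participant-level cohort.

    Returns a dict with the serology summary, fold-rise summary,
    booster-response table, non-inferiority table and report, and safety
    tables; writes them as CSVs plus ``decision_report.txt`` when
    ``outdir`` is given. Deterministic given the cohort.
    """
    config = config or AnalysisConfig()
    cohorts = build_cohorts(cohort.participants, cohort.serology)
    imputed = _imputed(cohort.serology, config.assays)

    if config.immunogenicity_cohort == "atp":
        immuno_ids = set(cohorts.loc[cohorts["in_atp"], "participant_id"])
    else:
        immuno_ids = set(cohorts["participant_id"])
    immuno = imputed.loc[imputed["participant_id"].isin(immuno_ids)]

    summary = summarize_serology(immuno, config.assays, config.level, impute=False)
    folds = fold_rise_table(summary)
    fold_summary = {
        "min_fold_rise": float(folds["fold_rise"].min()),
        "max_fold_rise": float(folds["fold_rise"].max()),
    }
    boosters = booster_response_tables(
        immuno, config.assays, config.booster_rules, config.level
    )
    ni_report, ni_table = noninferiority_analysis(imputed, cohorts, config)

    tvc_ids = cohorts.loc[cohorts["in_tvc"]]
    tvc_n = tvc_ids.groupby("group")["participant_id"].nunique().to_dict()
    ae = cohort.ae
    solicited = tabulate_ae(
        ae.loc[ae["solicited"].astype(bool)] if len(ae) else ae,
        tvc_n,
        SOLICITED_WINDOW,
        config.grading,
        config.level,
    )
    unsolicited = tabulate_ae(
        ae.loc[~ae["solicited"].astype(bool)] if len(ae) else ae,
        tvc_n,
        UNSOLICITED_WINDOW,
        config.grading,
        config.level,
    )

    out = {
        "cohorts": cohorts,
        "serology_summary": summary,
        "fold_rise": folds,
        "fold_rise_summary": fold_summary,
        "booster_response": boosters,
        "noninferiority": ni_table,
        "ni_report": ni_report,
        "safety_solicited": solicited,
        "safety_unsolicited": unsolicited,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in (
            "serology_summary",
            "fold_rise",
            "booster_response",
            "noninferiority",
            "safety_solicited",
            "safety_unsolicited",
        ):
            render_table(out[name]).to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "decision_report.txt").write_text(
            ni_report.describe()
            + "\n\nFold-rise range (post/pre GMC): "
            + f"{fold_summary['min_fold_rise']:.1f}-{fold_summary['max_fold_rise']:.1f}\n",
            encoding="utf-8",
        )
    return out


#: display precision per column kind
_ONE_DECIMAL = ("pct", "ci_low", "ci_high", "gmc", "gmc_low", "gmc_high")
_TWO_DECIMAL = ("fold_rise", "estimate", "ratio")


def render_table(df: pd.DataFrame) -> pd.DataFrame:
    """Apply the display rounding conventions; NaN rates become an em-dash."""
    out = df.copy()
    for col in out.columns:
        if col in _ONE_DECIMAL:
            out[col] = [
                "—" if isinstance(v, float) and math.isnan(v) else round(v, 1)
                for v in out[col]
            ]
        elif col in _TWO_DECIMAL:
            out[col] = out[col].round(2)
    return out
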