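"""Published summary constants of the decennial Tdap booster study.

These are the fixed configuration inputs of the analysis: group-level GMC
summaries per antigen and visit (used to calibrate the synthetic cohort
generator), the infant-DTaP comparator arm for the pertussis
immuno-bridging objective, cohort attrition, and solicited/unsolicited
adverse-event incidences. Everything here is a printed group-level
summary, not raw data.

Study structure: two groups of 19-30-year-olds boosted with Tdap, who ten
years earlier received either Td (``Td`` group, n=37) or Tdap (``Tdap``
group, n=128); 165 vaccinated, 160 completed, 150 in the
according-to-protocol (ATP) immunogenicity cohort (35 Td + 115 Tdap).
"""

from __future__ import annotations

import pandas as pd

from .noninferiority import ComparatorSummary

GROUP_TD = "Td"
GROUP_TDAP = "Tdap"

#: vaccinated participants per group (total vaccinated cohort)
DEFAULT_GROUP_SIZES = {GROUP_TD: 37, GROUP_TDAP: 128}

#: 165 vaccinated -> 160 completed -> 150 ATP
DEFAULT_DROPOUT_PROB = 5 / 165
DEFAULT_ATP_EXCLUSION_PROB = 10 / 160

#: ATP group sizes with available immunogenicity results
ATP_GROUP_SIZES = {GROUP_TD: 35, GROUP_TDAP: 115}

#: GMCs (IU/ml) with exact-level 95% CIs, ATP cohort, per group/antigen/visit.
#: These drive generator calibration; the CI back-solves the log10 SD.
GMC_SUMMARIES = pd.DataFrame(
    [
        # group, antigen, visit, n, gmc, ci_low, ci_high
        (GROUP_TD, "diphtheria", "pre", 35, 1.6, 1.1, 2.3),
        (GROUP_TD, "diphtheria", "post", 35, 6.8, 5.4, 8.6),
        (GROUP_TDAP, "diphtheria", "pre", 115, 1.6, 1.3, 2.1),
        (GROUP_TDAP, "diphtheria", "post", 115, 6.0, 5.3, 6.9),
        (GROUP_TD, "tetanus", "pre", 35, 1.8, 1.4, 2.4),
        (GROUP_TD, "tetanus", "post", 35, 9.9, 7.9, 12.5),
        (GROUP_TDAP, "tetanus", "pre", 115, 1.8, 1.5, 2.2),
        (GROUP_TDAP, "tetanus", "post", 115, 9.7, 8.5, 11.0),
        (GROUP_TD, "PT", "pre", 35, 5.3, 3.4, 8.2),
        (GROUP_TD, "PT", "post", 35, 66.2, 50.8, 86.2),
        (GROUP_TDAP, "PT", "pre", 115, 9.9, 8.1, 12.2),
        (GROUP_TDAP, "PT", "post", 115, 87.3, 74.5, 102.4),
        (GROUP_TD, "FHA", "pre", 35, 21.7, 13.4, 35.4),
        (GROUP_TD, "FHA", "post", 35, 336.2, 250.0, 452.2),
        (GROUP_TDAP, "FHA", "pre", 115, 36.9, 31.5, 43.3),
        (GROUP_TDAP, "FHA", "post", 115, 290.5, 252.5, 334.2),
        (GROUP_TD, "PRN", "pre", 35, 27.8, 13.7, 56.3),
        (GROUP_TD, "PRN", "post", 35, 425.5, 281.9, 642.3),
        (GROUP_TDAP, "PRN", "pre", 115, 71.6, 56.7, 90.6),
        (GROUP_TDAP, "PRN", "post", 115, 463.3, 390.8, 549.3),
    ],
    columns=["group", "antigen", "visit", "n", "gmc", "ci_low", "ci_high"],
)

#: Post-booster pertussis GMCs of the Tdap group in the total vaccinated
#: cohort (N = 124 with available results) — the numerators of the
#: immuno-bridging GMC ratios.
TDAP_TVC_PERTUSSIS_GMCS = {"PT": 83.5, "FHA": 285.5, "PRN": 442.6}
TDAP_TVC_PERTUSSIS_N = 124

#: Comparator arm: infants after a 3-dose DTaP series in a household-contact
#: efficacy study. Only N and GMC are published; the log10-scale SD of 0.45
#: is a synthetic stand-in (a typical ELISA between-subject spread) chosen
#: so the MOVER machinery is runnable end to end — comparator-based ratio
#: CIs computed with it are illustrative, not reproductions.
COMPARATOR_SD_LOG10 = 0.45
COMPARATOR_DTAP = {
    "PT": ComparatorSummary("PT", 2884, 41.7, sd_log10=COMPARATOR_SD_LOG10),
    "FHA": ComparatorSummary("FHA", 685, 47.2, sd_log10=COMPARATOR_SD_LOG10),
    "PRN": ComparatorSummary("PRN", 631, 113.0, sd_log10=COMPARATOR_SD_LOG10),
}

#: Adverse-event denominators: documented doses (solicited diary cards
#: returned) and administered doses (unsolicited follow-up).
SOLICITED_N = {GROUP_TD: 36, GROUP_TDAP: 125}
UNSOLICITED_N = {GROUP_TD: 37, GROUP_TDAP: 128}

#: Participant counts reporting each event at least once (x) and at grade 3,
#: over the section denominator above. ``related_x`` is investigator-assessed
#: causality for unsolicited events.
AE_COUNTS = pd.DataFrame(
    [
        # group, event, solicited, local, x, grade3_x, related_x
        (GROUP_TD, "pain", 1, 1, 21, 2, None),
        (GROUP_TD, "redness", 1, 1, 15, 0, None),
        (GROUP_TD, "swelling", 1, 1, 7, 0, None),
        (GROUP_TD, "fatigue", 1, 0, 8, 0, None),
        (GROUP_TD, "gastrointestinal", 1, 0, 1, 0, None),
        (GROUP_TD, "headache", 1, 0, 8, 0, None),
        (GROUP_TD, "fever", 1, 0, 1, 0, None),
        (GROUP_TD, "unsolicited", 0, 0, 10, 2, 1),
        (GROUP_TDAP, "pain", 1, 1, 97, 6, None),
        (GROUP_TDAP, "redness", 1, 1, 47, 1, None),
        (GROUP_TDAP, "swelling", 1, 1, 30, 0, None),
        (GROUP_TDAP, "fatigue", 1, 0, 38, 3, None),
        (GROUP_TDAP, "gastrointestinal", 1, 0, 11, 2, None),
        (GROUP_TDAP, "headache", 1, 0, 40, 3, None),
        (GROUP_TDAP, "fever", 1, 0, 3, 0, None),
        (GROUP_TDAP, "unsolicited", 0, 0, 33, 3, 5),
    ],
    columns=["group", "event", "solicited", "local", "x", "grade3_x", "related_x"],
)


def default_cohort_config(seed: int = 0, corr: float = 0.5) -> "CohortConfig":
    """Generator config calibrated to the study's published summaries.

    Group sizes, attrition, per-antigen log-normal parameters and
    adverse-event incidences all come from the constants in this module;
    only the seed and the (unidentifiable) pre/post correlation are free.
    """
    from .cohort import calibrate_from_summaries

    return calibrate_from_summaries(
        GMC_SUMMARIES,
        group_sizes=DEFAULT_GROUP_SIZES,
        corr=corr,
        dropout_prob=DEFAULT_DROPOUT_PROB,
        atp_exclusion_prob=DEFAULT_ATP_EXCLUSION_PROB,
        ae_probs=default_ae_probs(),
        seed=seed,
    )


def default_ae_probs() -> dict[str, dict[str, "EventParams"]]:
    """Per-group event probabilities implied by the published counts."""
    from .cohort import EventParams  # local import: avoid cycle

    probs: dict[str, dict[str, EventParams]] = {}
    for row in AE_COUNTS.itertuples():
        n = (SOLICITED_N if row.solicited else UNSOLICITED_N)[row.group]
        probs.setdefault(row.group, {})[row.event] = EventParams(
            incidence=row.x / n,
            grade3=row.grade3_x / n,
            related=(row.related_x / n) if pd.notna(row.related_x) else 0.0,
            solicited=bool(row.solicited),
            local=bool(row.local),
        )
    return probs
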