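"""Adverse-event grading and tabulation.

Solicited local (injection-site) and general adverse events are collected
on diary cards for days 0-3 post-vaccination; unsolicited, medically
attended and serious events for days 0-30. Severity is graded 1-3:

* redness / swelling: grade 3 iff diameter > 50 mm (strict);
* fever: a fever case iff temperature >= 37.5 deg C, grade 3 iff > 39.0
  (strict);
* all other events: grade 3 iff the event prevented normal activity
  (recorded as diary grade 3).

A *large swelling reaction* is swelling with diameter > 100 mm or a
noticeable diffuse swelling. Solicited local events are causally related
to vaccination by definition; causality of other events is the recorded
investigator assessment.

Tabulation is participant-level: a participant counts at most once per
event row regardless of how many diary days report it. Denominators are
supplied per group and section (documented doses for solicited events,
administered doses for unsolicited), so they may differ from the number
of participants with diary entries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .serology import clopper_pearson_ci

__all__ = [
    "AE_COLUMNS",
    "EventGrade",
    "GradingRules",
    "grade_event",
    "tabulate_ae",
]

#: ae diary table schema
AE_COLUMNS = [
    "participant_id",
    "group",
    "event",
    "day",
    "measurement",
    "grade",
    "solicited",
    "local",
    "related",
    "serious",
    "medically_attended",
]

#: events whose measurement is a diameter in mm
DIAMETER_EVENTS = ("redness", "swelling")
#: event whose measurement is a temperature in deg C
FEVER_EVENT = "fever"

SOLICITED_WINDOW = (0, 3)
UNSOLICITED_WINDOW = (0, 30)


@dataclass(frozen=True)
class GradingRules:
    """Severity boundaries. Diameters in mm, temperatures in deg C."""

    grade3_diameter: float = 50.0
    large_swelling_diameter: float = 100.0
    fever_threshold: float = 37.5
    grade3_fever: float = 39.0

    def __post_init__(self) -> None:
        if not self.large_swelling_diameter > self.grade3_diameter:
            raise ValueError("large-swelling bound must exceed the grade-3 bound")
        if not self.grade3_fever > self.fever_threshold:
            raise ValueError("grade-3 fever bound must exceed the fever threshold")


DEFAULT_GRADING = GradingRules()


@dataclass(frozen=True)
class EventGrade:
    """Derived severity of one diary entry."""

    grade: int                 # 1..3
    is_case: bool              # counts toward the event's incidence row
    large_swelling: bool = False


def grade_event(
    event: str,
    measurement: Optional[float],
    recorded_grade: int,
    rules: GradingRules = DEFAULT_GRADING,
    diffuse_swelling: bool = False,
) -> EventGrade:
    """Derive the analysis grade of one diary entry.

    Parameters
    ----------
    event
        Event name; ``"redness"``/``"swelling"`` are graded from diameter,
        ``"fever"`` from temperature, anything else from the recorded
        activity-impact grade.
    measurement
        Diameter (mm) or temperature (deg C) for measurable events;
        ignored otherwise.
    recorded_grade
        Diary severity 1-3 (activity impact) for non-measurable events.
    diffuse_swelling
        Diffuse-swelling code: forces the large-swelling flag.
    """
    if event in DIAMETER_EVENTS:
        if measurement is None or np.isnan(measurement):
            raise ValueError(f"{event} requires a diameter measurement")
        g3 = measurement > rules.grade3_diameter
        large = event == "swelling" and (
            measurement > rules.large_swelling_diameter or diffuse_swelling
        )
        return EventGrade(3 if g3 else max(1, min(recorded_grade, 2)), True, large)
    if event == FEVER_EVENT:
        if measurement is None or np.isnan(measurement):
            raise ValueError("fever requires a temperature measurement")
        is_case = measurement >= rules.fever_threshold
        g3 = measurement > rules.grade3_fever
        return EventGrade(3 if g3 else max(1, min(recorded_grade, 2)), is_case)
    if recorded_grade not in (1, 2, 3):
        raise ValueError(f"recorded grade must be 1-3, got {recorded_grade}")
    return EventGrade(recorded_grade, True)


def _group_row(
    ids_with: pd.Series, n_total: int, level: float
) -> dict[str, float]:
    x = int(ids_with.nunique())
    lo, hi = clopper_pearson_ci(x, n_total, level)
    return {"n": x, "N": n_total, "pct": 100.0 * x / n_total, "ci_low": lo, "ci_high": hi}


def tabulate_ae(
    records: pd.DataFrame,
    group_sizes: dict[str, int],
    window: tuple[int, int],
    rules: GradingRules = DEFAULT_GRADING,
    level: float = 0.95,
    events: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Participant-level incidence table with exact CIs for one window.

    Parameters
    ----------
    records
        Diary table with :data:`AE_COLUMNS`. Rows outside ``window`` are
        excluded.
    group_sizes
        Denominator per group for this section (documented doses for the
        solicited window, administered doses for the unsolicited one).
    window
        Inclusive day range, e.g. ``(0, 3)`` or ``(0, 30)``.
    events
        Event rows to emit (with zero rows even if absent from data);
        defaults to the events present.

    Returns
    -------
    One row per group x event x category, columns ``group, event,
    category, n, N, pct, ci_low, ci_high`` where category is ``any``,
    ``grade3``, and for relevant events ``related`` / ``serious`` /
    ``medically_attended`` / ``large_swelling``.
    """
    lo_day, hi_day = window
    recs = records.loc[(records["day"] >= lo_day) & (records["day"] <= hi_day)].copy()

    graded = [
        grade_event(
            r.event,
            r.measurement if not pd.isna(r.measurement) else None,
            int(r.grade),
            rules,
        )
        for r in recs.itertuples()
    ]
    recs["derived_grade"] = [g.grade for g in graded]
    recs["is_case"] = [g.is_case for g in graded]
    recs["large_swelling"] = [g.large_swelling for g in graded]
    # solicited local reactions are causally related by definition
    recs.loc[recs["solicited"].astype(bool) & recs["local"].astype(bool), "related"] = 1
    recs = recs.loc[recs["is_case"]]

    if events is None:
        events = sorted(recs["event"].unique())

    rows = []
    for group, n_total in group_sizes.items():
        sub = recs.loc[recs["group"] == group]
        for event in events:
            ev = sub.loc[sub["event"] == event]
            base = {"group": group, "event": event}
            rows.append(
                base | {"category": "any"} | _group_row(ev["participant_id"], n_total, level)
            )
            g3 = ev.loc[ev["derived_grade"] == 3]
            rows.append(
                base | {"category": "grade3"} | _group_row(g3["participant_id"], n_total, level)
            )
            for flag in ("related", "serious", "medically_attended"):
                sel = ev.loc[ev[flag].astype(bool)]
                rows.append(
                    base
                    | {"category": flag}
                    | _group_row(sel["participant_id"], n_total, level)
                )
        # window-level summary rows
        rows.append(
            {"group": group, "event": "large_swelling", "category": "any"}
            | _group_row(
                sub.loc[sub["large_swelling"].astype(bool), "participant_id"],
                n_total,
                level,
            )
        )
        rows.append(
            {"group": group, "event": "serious_adverse_event", "category": "any"}
            | _group_row(
                sub.loc[sub["serious"].astype(bool), "participant_id"], n_total, level
            )
        )
    return pd.DataFrame(rows)
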