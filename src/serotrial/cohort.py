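"""Synthetic participant-level cohort generator.

Emulates the data structure a booster-immunogenicity trial produces:

* two (or more) groups of vaccinated participants;
* per antigen, a bivariate log-normal pair of pre- and post-booster
  antibody concentrations on the log10 scale, with configurable
  within-subject correlation;
* left-censoring at the assay cut-off: values below it are stored at the
  cut-off with ``censored=1`` (half-cut-off imputation is an analysis
  step, never applied at generation time);
* attrition: a per-participant completion draw (dropouts lack the post
  visit) and an according-to-protocol (ATP) exclusion draw on completers;
* an adverse-event diary with configurable marginal incidences per group
  and event, grade-3 incidences nested within them, and measurements
  consistent with the intended grade.

Randomness is a single global seed feeding one counter-based substream
per participant (``SeedSequence(seed, spawn_key=(group_index,
participant_index))``), so enlarging a group never perturbs records
already generated for earlier participants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .assays import DEFAULT_ASSAYS, AssayDefinition
from .safety import AE_COLUMNS, SOLICITED_WINDOW, UNSOLICITED_WINDOW
from .serology import SEROLOGY_COLUMNS

__all__ = [
    "AntigenParams",
    "Cohort",
    "CohortConfig",
    "EventParams",
    "calibrate_from_summaries",
    "generate_cohort",
]


@dataclass(frozen=True)
class AntigenParams:
    """Bivariate log10-normal parameters of one group x antigen.

    ``mean_pre``/``mean_post`` are log10 IU/ml means, ``sd_pre``/``sd_post``
    log10 SDs, ``corr`` the within-subject pre/post correlation.
    """

    mean_pre: float
    mean_post: float
    sd_pre: float
    sd_post: float
    corr: float = 0.5

    def __post_init__(self) -> None:
        if self.sd_pre <= 0 or self.sd_post <= 0:
            raise ValueError("log10 SDs must be positive")
        if not -1.0 <= self.corr <= 1.0:
            raise ValueError("correlation must lie in [-1, 1]")


@dataclass(frozen=True)
class EventParams:
    """Marginal probabilities of one group x event.

    ``grade3``, ``related`` and ``serious`` are marginal incidences nested
    within ``incidence`` (a grade-3 case is also a case).
    """

    incidence: float
    grade3: float = 0.0
    related: float = 0.0
    serious: float = 0.0
    medically_attended: float = 0.0
    solicited: bool = True
    local: bool = False

    def __post_init__(self) -> None:
        for name in ("incidence", "grade3", "related", "serious", "medically_attended"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("grade3", "related", "serious", "medically_attended"):
            if getattr(self, name) > self.incidence:
                raise ValueError(f"{name} cannot exceed the overall incidence")


@dataclass(frozen=True)
class CohortConfig:
    """Full generator configuration.

    ``antigen_params`` maps group -> antigen -> :class:`AntigenParams`;
    ``ae_probs`` maps group -> event -> :class:`EventParams` (empty to
    skip diary generation).
    """

    group_sizes: dict[str, int]
    antigen_params: dict[str, dict[str, AntigenParams]]
    dropout_prob: float = 0.0
    atp_exclusion_prob: float = 0.0
    ae_probs: dict[str, dict[str, EventParams]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.group_sizes:
            raise ValueError("at least one group required")
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ValueError(f"group {g!r} size must be >= 1")
            if g not in self.antigen_params:
                raise ValueError(f"no antigen parameters for group {g!r}")
        for p in (self.dropout_prob, self.atp_exclusion_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p}")


@dataclass
class Cohort:
    """Generated participant-level tables.

    ``participants`` has one row per vaccinated participant with
    ``completed`` and ``atp`` flags (ATP is a subset of completers,
    completers of the vaccinated); ``serology`` and ``ae`` link to it via
    ``participant_id``.
    """

    participants: pd.DataFrame
    serology: pd.DataFrame
    ae: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write participants.csv, serology.csv and ae.csv (UTF-8, '.' decimal)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (
            ("participants", self.participants),
            ("serology", self.serology),
            ("ae", self.ae),
        ):
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        return paths


def cohort_config_from_dict(data: dict) -> CohortConfig:
    """Build a :class:`CohortConfig` from plain nested dicts (YAML/JSON)."""
    antigen_params = {
        g: {a: AntigenParams(**p) for a, p in by_antigen.items()}
        for g, by_antigen in data["antigen_params"].items()
    }
    ae_probs = {
        g: {e: EventParams(**p) for e, p in by_event.items()}
        for g, by_event in data.get("ae_probs", {}).items()
    }
    return CohortConfig(
        group_sizes={g: int(n) for g, n in data["group_sizes"].items()},
        antigen_params=antigen_params,
        dropout_prob=float(data.get("dropout_prob", 0.0)),
        atp_exclusion_prob=float(data.get("atp_exclusion_prob", 0.0)),
        ae_probs=ae_probs,
        seed=int(data.get("seed", 0)),
    )


def load_cohort_config(path: str | Path) -> CohortConfig:
    """Read a generator config from a YAML (or JSON, a YAML subset) file."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        return cohort_config_from_dict(yaml.safe_load(fh))


def _participant_rng(seed: int, group_idx: int, idx: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(group_idx, idx))
    )


def _draw_ae_rows(
    rng: np.random.Generator, pid: str, group: str, events: dict[str, EventParams]
) -> list[dict]:
    rows = []
    for event, p in events.items():
        u = rng.uniform()
        if u >= p.incidence:
            continue
        grade3 = u < p.grade3           # nested: worst cases are the earliest u
        related = u < p.related
        serious = u < p.serious
        attended = u < p.medically_attended
        window = SOLICITED_WINDOW if p.solicited else UNSOLICITED_WINDOW
        day = int(rng.integers(window[0], window[1] + 1))
        measurement = math.nan
        grade = 3 if grade3 else int(rng.integers(1, 3))
        if event in ("redness", "swelling"):
            measurement = rng.uniform(51.0, 95.0) if grade3 else rng.uniform(5.0, 50.0)
        elif event == "fever":
            measurement = rng.uniform(39.1, 40.2) if grade3 else rng.uniform(37.5, 39.0)
        rows.append(
            {
                "participant_id": pid,
                "group": group,
                "event": event,
                "day": day,
                "measurement": measurement,
                "grade": grade,
                "solicited": int(p.solicited),
                "local": int(p.local),
                "related": int(related or p.local),
                "serious": int(serious),
                "medically_attended": int(attended),
            }
        )
    return rows


def generate_cohort(
    config: CohortConfig,
    assays: dict[str, AssayDefinition] = DEFAULT_ASSAYS,
) -> Cohort:
    """Draw a full synthetic cohort. Deterministic given ``config.seed``."""
    part_rows, sero_rows, ae_rows = [], [], []
    for group_idx, (group, n) in enumerate(sorted(config.group_sizes.items())):
        params = config.antigen_params[group]
        events = config.ae_probs.get(group, {})
        missing = set(params) - set(assays)
        if missing:
            raise ValueError(f"no assay definition for antigens {sorted(missing)}")
        for i in range(n):
            rng = _participant_rng(config.seed, group_idx, i)
            pid = f"{group}-{i + 1:04d}"
            completed = rng.uniform() >= config.dropout_prob
            atp = completed and rng.uniform() >= config.atp_exclusion_prob
            part_rows.append(
                {
                    "participant_id": pid,
                    "group": group,
                    "completed": int(completed),
                    "atp": int(atp),
                }
            )
            for antigen in sorted(params):
                ap = params[antigen]
                cutoff = assays[antigen].cutoff
                e1, e2 = rng.standard_normal(2)
                log_pre = ap.mean_pre + ap.sd_pre * e1
                log_post = ap.mean_post + ap.sd_post * (
                    ap.corr * e1 + math.sqrt(1.0 - ap.corr**2) * e2
                )
                visits = [("pre", 10.0**log_pre)]
                if completed:
                    visits.append(("post", 10.0**log_post))
                for visit, conc in visits:
                    censored = conc < cutoff
                    sero_rows.append(
                        {
                            "participant_id": pid,
                            "group": group,
                            "antigen": antigen,
                            "visit": visit,
                            "concentration_IU_ml": cutoff if censored else conc,
                            "censored": int(censored),
                        }
                    )
            if events:
                ae_rows.extend(_draw_ae_rows(rng, pid, group, events))
    participants = pd.DataFrame(part_rows)
    serology = pd.DataFrame(sero_rows, columns=SEROLOGY_COLUMNS)
    ae = pd.DataFrame(ae_rows, columns=AE_COLUMNS)
    return Cohort(participants, serology, ae)


def backsolve_sd_log10(
    gmc: float, ci_low: float, ci_high: float, n: int, level: float = 0.95
) -> float:
    """log10 SD implied by a t-based GMC confidence interval.

    Inverts ``half_width = t_{n-1} * sd / sqrt(n)`` with the half-width
    measured on the log10 scale.
    """
    if n < 2:
        raise ValueError("back-solving an SD requires n >= 2")
    if not 0 < ci_low <= gmc <= ci_high:
        raise ValueError("CI must bracket the GMC with positive bounds")
    if ci_low == ci_high:
        raise ValueError("zero-width CI cannot come from continuous data")
    half = (math.log10(ci_high) - math.log10(ci_low)) / 2.0
    tq = stats.t.ppf(1 - (1 - level) / 2, n - 1)
    return half * math.sqrt(n) / tq


def calibrate_from_summaries(
    summaries: pd.DataFrame,
    group_sizes: Optional[dict[str, int]] = None,
    corr: float = 0.5,
    dropout_prob: float = 0.0,
    atp_exclusion_prob: float = 0.0,
    ae_probs: Optional[dict[str, dict[str, EventParams]]] = None,
    seed: int = 0,
    level: float = 0.95,
) -> CohortConfig:
    """Build a generator config whose implied GMCs match printed summaries.

    Parameters
    ----------
    summaries
        One row per group x antigen x visit with columns
        ``group, antigen, visit, n, gmc, ci_low, ci_high`` (visits ``pre``
        and ``post`` both required). The log10 mean is ``log10(gmc)`` and
        the log10 SD is back-solved from the CI half-width under the
        t-based CI formula, so the round trip through the GMC estimator
        reproduces the printed interval.
    group_sizes
        Participants to generate per group; defaults to the summary ``n``.
    corr
        Within-subject pre/post correlation (not identifiable from
        marginal summaries; free parameter).
    """
    antigen_params: dict[str, dict[str, AntigenParams]] = {}
    sizes: dict[str, int] = {}
    for (group, antigen), sub in summaries.groupby(["group", "antigen"]):
        byvisit = sub.set_index("visit")
        if not {"pre", "post"} <= set(byvisit.index):
            raise ValueError(f"{group}/{antigen}: need both pre and post rows")
        pre, post = byvisit.loc["pre"], byvisit.loc["post"]
        ap = AntigenParams(
            mean_pre=math.log10(pre["gmc"]),
            mean_post=math.log10(post["gmc"]),
            sd_pre=backsolve_sd_log10(
                pre["gmc"], pre["ci_low"], pre["ci_high"], int(pre["n"]), level
            ),
            sd_post=backsolve_sd_log10(
                post["gmc"], post["ci_low"], post["ci_high"], int(post["n"]), level
            ),
            corr=corr,
        )
        antigen_params.setdefault(group, {})[antigen] = ap
        sizes[group] = max(sizes.get(group, 0), int(pre["n"]), int(post["n"]))
    return CohortConfig(
        group_sizes=dict(group_sizes) if group_sizes else sizes,
        antigen_params=antigen_params,
        dropout_prob=dropout_prob,
        atp_exclusion_prob=atp_exclusion_prob,
        ae_probs=ae_probs or {},
        seed=seed,
    )
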