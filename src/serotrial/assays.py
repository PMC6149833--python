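"""Assay definitions: quantification cut-offs and interpretive thresholds.

Each serological assay has a lower quantification cut-off (concentrations
below it are reported as left-censored) and, for antigens with an accepted
correlate of protection, one or more seroprotection thresholds. For the
pertussis antigens no correlate exists, so the assay cut-off itself is the
only interpretive threshold (seropositivity).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class AssayDefinition:
    """One antigen's assay: cut-off and interpretive thresholds (IU/ml).

    Parameters
    ----------
    antigen
        Antigen name (free string, e.g. ``"diphtheria"`` or ``"PT"``).
    cutoff
        Lower quantification limit of the assay, IU/ml. Concentrations
        below it are left-censored.
    seroprotection_thresholds
        Ascending thresholds with a protective interpretation (e.g.
        0.1 and 1.0 IU/ml for diphtheria and tetanus). Empty for antigens
        without a correlate of protection.
    """

    antigen: str
    cutoff: float
    seroprotection_thresholds: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.cutoff > 0:
            raise ValueError(f"assay cut-off must be positive, got {self.cutoff}")
        thresholds = tuple(float(t) for t in self.seroprotection_thresholds)
        if any(t <= 0 for t in thresholds):
            raise ValueError("seroprotection thresholds must be strictly positive")
        if list(thresholds) != sorted(thresholds):
            raise ValueError("seroprotection thresholds must be sorted ascending")
        object.__setattr__(self, "seroprotection_thresholds", thresholds)

    @property
    def rate_thresholds(self) -> tuple[float, ...]:
        """Thresholds at which rates are tabulated.

        Seroprotection thresholds where defined, otherwise the assay
        cut-off (seropositivity).
        """
        return self.seroprotection_thresholds or (self.cutoff,)

    @property
    def has_seroprotection(self) -> bool:
        return bool(self.seroprotection_thresholds)


#: Default assay panel for a Tdap booster study. Cut-offs are the validated
#: ELISA lower quantification limits; 0.1 IU/ml is the conservative
#: seroprotection threshold for diphtheria and tetanus, 1.0 IU/ml a
#: long-term-protection threshold.
DEFAULT_ASSAYS: dict[str, AssayDefinition] = {
    "diphtheria": AssayDefinition("diphtheria", 0.057, (0.1, 1.0)),
    "tetanus": AssayDefinition("tetanus", 0.043, (0.1, 1.0)),
    "PT": AssayDefinition("PT", 2.693),
    "FHA": AssayDefinition("FHA", 2.046),
    "PRN": AssayDefinition("PRN", 2.187),
}

#: Antigens analysed under the diphtheria/tetanus booster-response rules.
DT_ANTIGENS = ("diphtheria", "tetanus")
#: Acellular pertussis antigens (single booster-response definition).
PERTUSSIS_ANTIGENS = ("PT", "FHA", "PRN")
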