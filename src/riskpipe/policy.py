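"""Risk-stratified screening assignment.

Maps age, combined 5-year risk, breast density and pathogenic-variant (PV)
status to a screening recommendation through a configurable threshold
table.  PV carriers always receive guideline-based screening and bypass
the risk thresholds.  Density overrides (e.g. extremely dense breasts ->
at least annual mammography) are applied after the risk rules and only
ever escalate.  Risk intervals are half-open and lower-inclusive, so a
risk exactly on a boundary resolves upward to the higher-intensity rule.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ScreeningRecommendation",
    "ThresholdRule",
    "AgeBand",
    "ThresholdTable",
    "AssignmentRecord",
    "ThresholdTableError",
    "DEFAULT_FREQ_MAP",
    "assign_screening",
    "apply_override",
    "screens_per_year",
    "recommendation_intensity",
]


class ScreeningRecommendation(str, enum.Enum):
    NONE_OR_STOP = "NONE_OR_STOP"
    BIENNIAL = "BIENNIAL"
    ANNUAL_RISK = "ANNUAL_RISK"
    ANNUAL_DENSITY = "ANNUAL_DENSITY"
    Q6MO_ALTERNATING = "Q6MO_ALTERNATING"
    PV_GUIDELINE = "PV_GUIDELINE"

    def __str__(self) -> str:
        return self.value


#: Screening modality implied by each recommendation.
MODALITY = {
    ScreeningRecommendation.NONE_OR_STOP: "no screening / stop screening",
    ScreeningRecommendation.BIENNIAL: "mammogram every other year",
    ScreeningRecommendation.ANNUAL_RISK: "yearly mammogram (risk)",
    ScreeningRecommendation.ANNUAL_DENSITY: "yearly mammogram (density)",
    ScreeningRecommendation.Q6MO_ALTERNATING: "alternating mammogram and MRI every 6 months",
    ScreeningRecommendation.PV_GUIDELINE: "per established carrier guidelines (MRI + mammogram)",
}

# NONE < BIENNIAL < ANNUAL (risk or density) < Q6MO; PV is outside the
# risk-based ladder and deliberately not ranked.
_INTENSITY = {
    ScreeningRecommendation.NONE_OR_STOP: 0,
    ScreeningRecommendation.BIENNIAL: 1,
    ScreeningRecommendation.ANNUAL_RISK: 2,
    ScreeningRecommendation.ANNUAL_DENSITY: 2,
    ScreeningRecommendation.Q6MO_ALTERNATING: 3,
}

#: Projected screening encounters per year implied by each recommendation.
#: PV carriers are excluded from utilization analyses, hence absent here.
DEFAULT_FREQ_MAP: dict[ScreeningRecommendation, float] = {
    ScreeningRecommendation.NONE_OR_STOP: 0.0,
    ScreeningRecommendation.BIENNIAL: 0.5,
    ScreeningRecommendation.ANNUAL_RISK: 1.0,
    ScreeningRecommendation.ANNUAL_DENSITY: 1.0,
    ScreeningRecommendation.Q6MO_ALTERNATING: 2.0,
}


def recommendation_intensity(rec: ScreeningRecommendation) -> int:
    try:
        return _INTENSITY[rec]
    except KeyError:
        raise ValueError(f"{rec} has no position on the risk-based intensity ladder") from None


class ThresholdTableError(ValueError):
    """Raised when a threshold table fails its partition audit."""


@dataclass(frozen=True)
class ThresholdRule:
    risk_lo: float
    risk_hi: float
    recommendation: ScreeningRecommendation


@dataclass(frozen=True)
class AgeBand:
    age_lo: int
    age_hi: int
    rules: tuple[ThresholdRule, ...]


@dataclass(frozen=True)
class ThresholdTable:
    """Validated age-band x risk-interval rule table plus density overrides.

    ``density_overrides`` maps a BI-RADS category to a minimum
    recommendation; it escalates but never de-escalates a risk-based rule.
    """

    bands: tuple[AgeBand, ...]
    density_overrides: Mapping[str, ScreeningRecommendation] = None  # type: ignore[assignment]
    age_min: int = 40
    age_max: int = 74

    def __post_init__(self) -> None:
        if self.density_overrides is None:
            object.__setattr__(self, "density_overrides", {})
        self.validate()

    def validate(self) -> None:
        """Prove age-band and risk-interval coverage and disjointness."""
        if not self.bands:
            raise ThresholdTableError("threshold table has no age bands")
        bands = sorted(self.bands, key=lambda b: b.age_lo)
        if bands[0].age_lo != self.age_min or bands[-1].age_hi != self.age_max:
            raise ThresholdTableError(
                f"age bands must span {self.age_min}-{self.age_max}"
            )
        for prev, cur in zip(bands, bands[1:]):
            if cur.age_lo != prev.age_hi + 1:
                raise ThresholdTableError(
                    f"age bands {prev.age_lo}-{prev.age_hi} and "
                    f"{cur.age_lo}-{cur.age_hi} do not partition the age range"
                )
        for band in bands:
            if band.age_lo > band.age_hi:
                raise ThresholdTableError(f"empty age band {band.age_lo}-{band.age_hi}")
            rules = sorted(band.rules, key=lambda r: r.risk_lo)
            if not rules:
                raise ThresholdTableError(f"age band {band.age_lo}-{band.age_hi} has no rules")
            if rules[0].risk_lo != 0.0 or rules[-1].risk_hi != 1.0:
                raise ThresholdTableError(
                    f"risk intervals in band {band.age_lo}-{band.age_hi} must span (0, 1)"
                )
            for rule in rules:
                if not rule.risk_lo < rule.risk_hi:
                    raise ThresholdTableError(
                        f"empty/inverted risk interval [{rule.risk_lo}, {rule.risk_hi})"
                    )
            for prev, cur in zip(rules, rules[1:]):
                if cur.risk_lo != prev.risk_hi:
                    raise ThresholdTableError(
                        f"risk intervals [{prev.risk_lo}, {prev.risk_hi}) and "
                        f"[{cur.risk_lo}, {cur.risk_hi}) overlap or leave a gap"
                    )

    def band_for(self, age: int) -> AgeBand:
        for band in self.bands:
            if band.age_lo <= age <= band.age_hi:
                return band
        if age > self.age_max:  # yearly recalculation can age past the table
            return max(self.bands, key=lambda b: b.age_hi)
        raise ThresholdTableError(f"age {age} not covered by the threshold table")

    def rule_for(self, age: int, risk: float) -> ThresholdRule:
        for rule in self.band_for(age).rules:
            if rule.risk_lo <= risk < rule.risk_hi:
                return rule
        raise ThresholdTableError(f"no rule matches age {age}, risk {risk}")


@dataclass(frozen=True)
class AssignmentRecord:
    """Recommendations for one participant-year under both risk models."""

    participant_id: str
    year: int
    rec_bcsc: ScreeningRecommendation
    rec_combined: ScreeningRecommendation
    rec_final: ScreeningRecommendation | None = None


def assign_screening(participant, risk_5yr: float, thresholds: ThresholdTable):
    """Deterministic recommendation for one participant.

    PV carriers dominate everything; otherwise the unique age-band/risk
    rule fires and density overrides may escalate the result.
    """
    if participant.pv_carrier:
        return ScreeningRecommendation.PV_GUIDELINE
    if not 0.0 < risk_5yr < 1.0:
        raise ValueError(f"risk {risk_5yr} must lie strictly in (0, 1)")
    rec = thresholds.rule_for(participant.age, risk_5yr).recommendation
    override = thresholds.density_overrides.get(participant.density)
    if override is not None and recommendation_intensity(override) > recommendation_intensity(rec):
        rec = override
    return rec


def apply_override(
    record: AssignmentRecord,
    overrides: Mapping[str, ScreeningRecommendation] | None = None,
) -> AssignmentRecord:
    """Apply a manual-review override; pass through rec_combined otherwise."""
    if overrides and record.participant_id in overrides:
        return replace(record, rec_final=overrides[record.participant_id])
    return replace(record, rec_final=record.rec_combined)


def apply_overrides(
    records: Iterable[AssignmentRecord],
    overrides: Mapping[str, ScreeningRecommendation] | None = None,
) -> list[AssignmentRecord]:
    records = list(records)
    if overrides:
        known = {r.participant_id for r in records}
        for pid in overrides:
            if pid not in known:
                warnings.warn(f"override for unknown participant id {pid!r} ignored")
    return [apply_override(r, overrides) for r in records]


def screens_per_year(
    rec: ScreeningRecommendation,
    freq_map: Mapping[ScreeningRecommendation, float] | None = None,
) -> float:
    """Projected screening encounters per year for one recommendation."""
    fm = DEFAULT_FREQ_MAP if freq_map is None else freq_map
    try:
        return float(fm[rec])
    except KeyError:
        raise KeyError(f"no screens-per-year frequency for {rec}") from None
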