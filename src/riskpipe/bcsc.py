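"""BCSC-style 5-year absolute breast cancer risk.

Implements a Gail-type absolute-risk projection in the style of the Breast
Cancer Surveillance Consortium (BCSC) v2 model: a participant's covariates
(BI-RADS breast density, binary first-degree family history, worst prior
biopsy pathology, age band) look up a relative risk that multiplies a
race/ethnicity- and age-specific baseline breast cancer hazard, projected
over five years against a competing (non-breast-cancer mortality) hazard:

    risk = sum_{t=0..4} [ rr*h1(a+t) / (rr*h1(a+t) + h2(a+t)) ]
                        * (1 - exp(-(rr*h1 + h2)(a+t)))
                        * exp(-sum_{s<t} (rr*h1 + h2)(a+s))

All coefficients (relative risks, baseline and competing hazards) are
loaded from configuration, never hard-coded: the bundled coefficient file
is a synthetic, structurally faithful stand-in and the published tables can
be dropped in without code changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

__all__ = [
    "Participant",
    "BcscCoefficients",
    "RiskEstimate",
    "hazard_group",
    "relative_risk",
    "absolute_5yr_risk",
    "project_start_year",
]

BIOPSY_CATEGORIES = (
    "none",
    "nonproliferative",
    "proliferative_no_atypia",
    "atypia",
    "lcis",
    "unknown",
)
DENSITY_CATEGORIES = ("a", "b", "c", "d", "unknown")


@dataclass(frozen=True)
class Participant:
    """Demographics, clinical risk factors and carrier status for one woman."""

    id: str
    age: int
    race: str | None
    hispanic: bool | None
    fdr_bc: int = 0
    sdr_bc: int = 0
    biopsy: str = "none"
    density: str = "unknown"
    pv_carrier: bool = False

    def __post_init__(self) -> None:
        if not 18 <= self.age <= 100:
            raise ValueError(f"{self.id}: age {self.age} outside 18-100")
        if self.fdr_bc < 0 or self.sdr_bc < 0:
            raise ValueError(f"{self.id}: relative counts must be >= 0")
        if self.biopsy not in BIOPSY_CATEGORIES:
            raise ValueError(f"{self.id}: biopsy {self.biopsy!r} not in {BIOPSY_CATEGORIES}")
        if self.density not in DENSITY_CATEGORIES:
            raise ValueError(f"{self.id}: density {self.density!r} not in {DENSITY_CATEGORIES}")

    @property
    def fdr_binary(self) -> bool:
        """Family history enters the model as a binary first-degree term."""
        return self.fdr_bc > 0

    def aged(self, years: int) -> "Participant":
        return replace(self, age=self.age + years)


def hazard_group(participant: Participant) -> str:
    """Map self-reported race/ethnicity to a hazard-table group label."""
    if participant.hispanic:
        return "hispanic"
    label = (participant.race or "unknown").strip().lower()
    if label in ("black", "african american"):
        return "black"
    if label in (
        "asian",
        "native hawaiian",
        "pacific islander",
        "native hawaiian or pacific islander",
        "asian or pacific islander",
    ):
        return "asian_pi"
    if label == "white":
        return "white"
    return "other"


@dataclass
class BcscCoefficients:
    """Relative-risk table plus per-group annual hazard vectors.

    ``rr_table`` is cross-classified on (density, fdr '0'/'1', biopsy,
    age_band); the loader expands multiplicative component shorthand into
    this form.  Hazards are indexed by hazard-group label then integer age.
    """

    rr_table: Mapping[tuple[str, str, str, str], float]
    baseline_hazard: Mapping[str, Mapping[int, float]]
    competing_hazard: Mapping[str, Mapping[int, float]]
    age_bands: tuple[tuple[int, int], ...] = ((40, 49), (50, 74))
    _band_labels: dict[tuple[int, int], str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for key, rr in self.rr_table.items():
            if not rr > 0:
                raise ValueError(f"relative risk for {key} must be > 0")
        for table in (self.baseline_hazard, self.competing_hazard):
            for grp, vec in table.items():
                for age, h in vec.items():
                    if h < 0:
                        raise ValueError(f"hazard {grp}/{age} must be >= 0")
        self._band_labels = {(lo, hi): f"{lo}-{hi}" for lo, hi in self.age_bands}

    def age_band(self, age: int) -> str:
        for (lo, hi), label in self._band_labels.items():
            if lo <= age <= hi:
                return label
        # ages past the last band keep its coefficients (risk projection of
        # a 74-year-old reaches age 78)
        lo, hi = self.age_bands[-1]
        if age > hi:
            return self._band_labels[(lo, hi)]
        raise KeyError(f"age {age} not covered by any relative-risk age band")

    def hazards(self, group: str, age: int) -> tuple[float, float]:
        try:
            h1 = self.baseline_hazard[group][age]
            h2 = self.competing_hazard[group][age]
        except KeyError as exc:
            raise KeyError(
                f"no hazard entry for group {group!r} at age {age}: {exc}"
            ) from None
        return h1, h2


@dataclass(frozen=True)
class RiskEstimate:
    """Clinical risk, PRS and their Bayesian combination for one woman."""

    bcsc_5yr: float
    prs: float
    combined_5yr: float

    def __post_init__(self) -> None:
        for name in ("bcsc_5yr", "combined_5yr"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name}={p} must lie strictly in (0, 1)")
        if not self.prs > 0:
            raise ValueError("prs must be > 0")


def relative_risk(participant: Participant, coeffs: BcscCoefficients) -> float:
    """Covariate relative risk; the reference pattern returns exactly 1."""
    key = (
        participant.density,
        "1" if participant.fdr_binary else "0",
        participant.biopsy,
        coeffs.age_band(participant.age),
    )
    try:
        return coeffs.rr_table[key]
    except KeyError:
        raise KeyError(
            f"no relative-risk entry for (density={key[0]!r}, fdr={key[1]}, "
            f"biopsy={key[2]!r}, age_band={key[3]!r})"
        ) from None


def absolute_5yr_risk(
    rr: float,
    age: int,
    race_eth: str,
    coeffs: BcscCoefficients,
    window: int = 5,
) -> float:
    """Absolute risk of breast cancer within ``window`` years from ``age``.

    Annual-interval cause-specific competing-risk projection: within each
    year the total hazard is rr*h1 + h2, a fraction rr*h1/(rr*h1+h2) of
    events are breast cancers, and survival discounts later years.
    """
    if rr <= 0:
        raise ValueError("relative risk must be > 0")
    risk = 0.0
    cum = 0.0
    for t in range(window):
        h1, h2 = coeffs.hazards(race_eth, age + t)
        htot = rr * h1 + h2
        if htot > 0:
            risk += (rr * h1 / htot) * (1.0 - math.exp(-htot)) * math.exp(-cum)
        cum += htot
    return risk


def project_start_year(
    participant: Participant,
    coeffs: BcscCoefficients,
    thresholds,
    horizon: int = 5,
) -> int | None:
    """First study year (1-based) whose clinical-risk-only recommendation
    is to screen, or None within the horizon.

    Risk estimates are recalculated yearly with age incremented; used to
    ask whether a woman recommended to start screening by the combined
    model would have started anyway under the clinical model in a later
    year.
    """
    from .policy import ScreeningRecommendation, assign_screening

    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    for year in range(1, horizon + 1):
        aged = participant.aged(year - 1)
        rr = relative_risk(aged, coeffs)
        risk = absolute_5yr_risk(rr, aged.age, hazard_group(aged), coeffs)
        rec = assign_screening(aged, risk, thresholds)
        if rec is not ScreeningRecommendation.NONE_OR_STOP:
            return year
    return None
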