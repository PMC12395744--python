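"""Ancestry-tailored multiplicative polygenic risk scores (PRS).

A woman's PRS is the product over panel SNPs of ``OR**g / mu`` where ``g``
is her risk-allele dosage (0, 1 or 2), ``OR`` the per-allele odds ratio for
her self-reported race/ethnicity group, and ``mu`` the Hardy-Weinberg
population mean of ``OR**g`` computed from the group's risk-allele
frequency:

    mu = (1-p)**2 + 2*p*(1-p)*OR + p**2 * OR**2

Dividing each per-SNP relative risk by its population mean centers the
cohort mean PRS at ~1 in cancer-free women, so the score can be read
directly as a relative-risk multiplier on a clinical absolute-risk
estimate.  Scores are accumulated as sums of logs and exponentiated at the
end for numerical stability; missing genotypes contribute a neutral factor
of 1 and are counted against a scoreability threshold.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "AncestryGroup",
    "SnpRecord",
    "SnpPanel",
    "PrsResult",
    "assign_prs_group",
    "hwe_genotype_distribution",
    "snp_mean_relative_risk",
    "snp_adjusted_risk",
    "compute_prs",
    "compute_prs_matrix",
    "quintile_cutpoints",
]

#: Sentinel dosage for a missing genotype call.
MISSING = -1


class AncestryGroup(str, enum.Enum):
    """The four self-reported race/ethnicity groups with separate PRSs."""

    NH_ASIAN = "NH_ASIAN"
    NH_BLACK = "NH_BLACK"
    HISPANIC = "HISPANIC"
    NH_WHITE = "NH_WHITE"

    def __str__(self) -> str:  # cleaner CSV / CLI output
        return self.value


# Self-reported race labels routed to each group when ethnicity is
# non-Hispanic.  Labels without group-specific GWAS parameters fall back to
# NH_WHITE (Native American, other, mixed, unknown).
_RACE_ROUTING: dict[str, AncestryGroup] = {
    "asian": AncestryGroup.NH_ASIAN,
    "native hawaiian": AncestryGroup.NH_ASIAN,
    "pacific islander": AncestryGroup.NH_ASIAN,
    "native hawaiian or pacific islander": AncestryGroup.NH_ASIAN,
    "asian or pacific islander": AncestryGroup.NH_ASIAN,
    "black": AncestryGroup.NH_BLACK,
    "african american": AncestryGroup.NH_BLACK,
    "white": AncestryGroup.NH_WHITE,
    "american indian or alaska native": AncestryGroup.NH_WHITE,
    "native american": AncestryGroup.NH_WHITE,
    "other": AncestryGroup.NH_WHITE,
    "mixed": AncestryGroup.NH_WHITE,
    "more than one race": AncestryGroup.NH_WHITE,
    "unknown": AncestryGroup.NH_WHITE,
}


def assign_prs_group(race: str | None, hispanic: bool | None) -> AncestryGroup:
    """Route self-reported race and Hispanic ethnicity to a PRS group.

    Hispanic ethnicity dominates race: any participant reporting Hispanic
    ethnicity is scored with Hispanic parameters regardless of race.
    Unknown ethnicity is treated as non-Hispanic.  Races without a
    dedicated PRS (Native American, other, mixed, unreported) are scored
    with NH White parameters.

    Raises
    ------
    ValueError
        If the race label is not in the study vocabulary and ethnicity is
        not Hispanic (no silent default for genuinely unrecognized input).
    """
    if hispanic:
        return AncestryGroup.HISPANIC
    label = "unknown" if race is None or str(race).strip() == "" else str(race).strip().lower()
    try:
        return _RACE_ROUTING[label]
    except KeyError:
        raise ValueError(
            f"unrecognized self-reported race label {race!r}; expected one of "
            f"{sorted(_RACE_ROUTING)}"
        ) from None


@dataclass(frozen=True)
class SnpRecord:
    """One panel SNP with per-group effect size and risk-allele frequency."""

    rsid: str
    chrom: str
    pos: int
    risk_allele: str
    other_allele: str
    per_group_or: Mapping[AncestryGroup, float]
    per_group_freq: Mapping[AncestryGroup, float]

    def validate(self) -> None:
        if self.risk_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: risk and other allele are identical")
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: position must be 1-based positive")
        for g, or_ in self.per_group_or.items():
            if not or_ > 0:
                raise ValueError(f"{self.rsid}: odds ratio for {g} must be > 0")
        for g, p in self.per_group_freq.items():
            if not 0.0 < p < 1.0:
                raise ValueError(
                    f"{self.rsid}: risk-allele frequency for {g} must be in (0,1)"
                )

    @property
    def strand_ambiguous(self) -> bool:
        """A/T and C/G SNPs cannot be strand-resolved from alleles alone."""
        pair = {self.risk_allele.upper(), self.other_allele.upper()}
        return pair in ({"A", "T"}, {"C", "G"})


@dataclass
class SnpPanel:
    """An ordered SNP panel restricted to one ancestry group's parameters."""

    group: AncestryGroup
    snps: Sequence[SnpRecord]
    _ors: np.ndarray = field(init=False, repr=False)
    _freqs: np.ndarray = field(init=False, repr=False)
    _mus: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.snps) < 1:
            raise ValueError("panel must contain at least one SNP")
        for snp in self.snps:
            snp.validate()
            if self.group not in snp.per_group_or or self.group not in snp.per_group_freq:
                raise ValueError(f"{snp.rsid}: no parameters for group {self.group}")
        self._ors = np.array([s.per_group_or[self.group] for s in self.snps], dtype=float)
        self._freqs = np.array([s.per_group_freq[self.group] for s in self.snps], dtype=float)
        self._mus = snp_mean_relative_risk(self._ors, self._freqs)

    @property
    def size(self) -> int:
        return len(self.snps)

    @property
    def rsids(self) -> list[str]:
        return [s.rsid for s in self.snps]

    @property
    def ors(self) -> np.ndarray:
        return self._ors

    @property
    def freqs(self) -> np.ndarray:
        return self._freqs

    @property
    def mus(self) -> np.ndarray:
        """Per-SNP Hardy-Weinberg mean relative risks."""
        return self._mus


@dataclass(frozen=True)
class PrsResult:
    """A scored PRS with missingness accounting."""

    prs: float
    n_used: int
    n_missing: int
    group: AncestryGroup
    scoreable: bool = True


def hwe_genotype_distribution(freq: float | np.ndarray) -> tuple:
    """Hardy-Weinberg genotype probabilities ((1-p)^2, 2p(1-p), p^2)."""
    p = np.asarray(freq, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("allele frequency must lie in [0, 1]")
    q = 1.0 - p
    out = (q * q, 2.0 * p * q, p * p)
    if np.isscalar(freq) or np.ndim(freq) == 0:
        return tuple(float(x) for x in out)
    return out


def snp_mean_relative_risk(or_per_allele, freq):
    """Population mean of OR**g under Hardy-Weinberg genotype frequencies.

    mu = (1-p)^2 + 2 p (1-p) OR + p^2 OR^2.  Dividing per-genotype relative
    risks by mu makes their population expectation exactly 1.
    """
    or_ = np.asarray(or_per_allele, dtype=float)
    p = np.asarray(freq, dtype=float)
    if np.any(or_ <= 0):
        raise ValueError("odds ratio must be > 0")
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("risk-allele frequency must lie strictly in (0, 1)")
    q = 1.0 - p
    mu = q * q + 2.0 * p * q * or_ + p * p * or_ * or_
    return float(mu) if mu.ndim == 0 else mu


def snp_adjusted_risk(dosage: int, or_per_allele: float, mu: float) -> float:
    """Normalized per-SNP risk factor OR**g / mu; missing dosage -> 1.0."""
    if dosage == MISSING:
        return 1.0
    if dosage not in (0, 1, 2):
        raise ValueError(f"dosage must be 0, 1, 2 or MISSING, got {dosage}")
    return float(or_per_allele**dosage / mu)


def compute_prs(
    genotypes: Sequence[int] | np.ndarray,
    panel: SnpPanel,
    max_missing_fraction: float = 0.0,
) -> PrsResult:
    """Score one genotype vector against a panel.

    The PRS is the product of per-SNP normalized risk factors, accumulated
    as a sum of logs.  Missing dosages contribute log(1) = 0; if the
    fraction missing exceeds ``max_missing_fraction`` the result is flagged
    non-scoreable (the trial excluded such participants rather than
    imputing).
    """
    g = np.asarray(genotypes)
    if g.ndim != 1 or g.shape[0] != panel.size:
        raise ValueError(
            f"genotype vector length {g.shape} does not match panel size {panel.size}"
        )
    if not 0.0 <= max_missing_fraction < 1.0:
        raise ValueError("max_missing_fraction must lie in [0, 1)")
    prs, scoreable, n_missing = compute_prs_matrix(
        g[None, :], panel, max_missing_fraction
    )
    return PrsResult(
        prs=float(prs[0]),
        n_used=panel.size - int(n_missing[0]),
        n_missing=int(n_missing[0]),
        group=panel.group,
        scoreable=bool(scoreable[0]),
    )


def compute_prs_matrix(
    dosage_matrix: np.ndarray,
    panel: SnpPanel,
    max_missing_fraction: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized scoring of an (n_individuals, n_snps) dosage matrix.

    Returns ``(prs, scoreable, n_missing)`` arrays.  Dosage entries must be
    0/1/2 or :data:`MISSING`.
    """
    D = np.asarray(dosage_matrix)
    if D.ndim != 2 or D.shape[1] != panel.size:
        raise ValueError(
            f"dosage matrix shape {D.shape} does not match panel size {panel.size}"
        )
    valid = (D == 0) | (D == 1) | (D == 2) | (D == MISSING)
    if not valid.all():
        bad = np.unique(D[~valid])
        raise ValueError(f"invalid dosage values {bad!r}")
    missing = D == MISSING
    g = np.where(missing, 0, D).astype(float)
    log_or = np.log(panel.ors)
    log_mu = np.log(panel.mus)
    # sum over SNPs of g*log(OR) - log(mu); missing SNPs contribute neither
    log_prs = g @ log_or - np.where(missing, 0.0, log_mu[None, :]).sum(axis=1)
    n_missing = missing.sum(axis=1)
    scoreable = n_missing <= max_missing_fraction * panel.size
    return np.exp(log_prs), scoreable, n_missing


def quintile_cutpoints(prs_values: Iterable[float], group: AncestryGroup | None = None):
    """20/40/60/80th percentile cutoffs, linear interpolation convention.

    The ``group`` argument is informational only (cutpoints are computed
    per race/ethnicity group by the caller).
    """
    values = np.asarray(list(prs_values), dtype=float)
    if values.size < 5:
        raise ValueError(f"need at least 5 values for quintile cutpoints, got {values.size}")
    cuts = np.percentile(values, [20, 40, 60, 80], method="linear")
    return tuple(float(c) for c in cuts)
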