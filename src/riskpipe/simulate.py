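"""Synthetic SNP panels, genotypes and phenotype tables.

Generates cohorts with the statistical structure the downstream pipeline
assumes, so every stage is testable without access to the (unreleased)
trial data:

* per-group SNP panels with log-normal odds ratios and uniform risk-allele
  frequencies (placeholders for a real panel file in the same format);
* Hardy-Weinberg genotypes drawn with group-specific frequencies, which is
  exactly the regime in which mean-relative-risk normalization centers the
  cohort mean PRS at 1;
* demographics matching the composition of a large US risk-based screening
  cohort (N=21,631): race/ethnicity mix, family-history and BI-RADS
  density mixes, 3.1% pathogenic-variant carriers, ages 40-74 with median
  ~53 and IQR ~45-62;
* family-history extent and density drawn conditionally on the realized
  PRS through ordinal-logistic links, reproducing the direction of the
  observed PRS gradients (higher PRS with more extensive family history
  and denser breasts); zero slopes give independence.

All draws flow from one :class:`numpy.random.Generator` seeded in the
config, so identical configs give byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bcsc import Participant
from .prs import AncestryGroup, SnpPanel, SnpRecord, assign_prs_group, compute_prs_matrix

__all__ = [
    "CohortConfig",
    "SimulatedCohort",
    "simulate_panel",
    "simulate_genotypes",
    "simulate_cohort",
    "write_fixtures",
]

# Composition of the reference trial cohort (exact counts out of 21,631),
# used as generator defaults.
_N_REF = 21631
_GROUP_MIX = {
    "hispanic": 1932 / _N_REF,
    "nh_aian": 44 / _N_REF,
    "nh_asian_pi": 1029 / _N_REF,
    "nh_black": 969 / _N_REF,
    "nh_other": 875 / _N_REF,
    "nh_white": 16782 / _N_REF,
}
_FH_MIX = {
    "none": 10433 / _N_REF,
    "sdr_only": 5302 / _N_REF,
    "fdr_only": 3369 / _N_REF,
    "both": 2527 / _N_REF,
}
_DENSITY_MIX = {  # a..d conditional mix re-normalized after the unknown draw
    "a": 1009 / _N_REF,
    "b": 7565 / _N_REF,
    "c": 8581 / _N_REF,
    "d": 1876 / _N_REF,
    "unknown": 2600 / _N_REF,
}
# Prior-biopsy mix is not tabulated in the reference cohort; plausible
# screening-population values.
_BIOPSY_MIX = {
    "none": 0.80,
    "nonproliferative": 0.08,
    "proliferative_no_atypia": 0.06,
    "atypia": 0.02,
    "lcis": 0.005,
    "unknown": 0.035,
}

# Demographic category -> (race label, hispanic flag) for phenotype tables.
_GROUP_TO_RACE = {
    "hispanic": ("white", True),
    "nh_aian": ("american indian or alaska native", False),
    "nh_asian_pi": ("asian", False),
    "nh_black": ("black", False),
    "nh_other": ("other", False),
    "nh_white": ("white", False),
}


def _check_mix(name: str, mix: Mapping[str, float]) -> None:
    total = float(sum(mix.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} proportions sum to {total}, not 1")
    if any(p < 0 for p in mix.values()):
        raise ValueError(f"{name} contains negative proportions")


@dataclass
class CohortConfig:
    """Generator configuration; defaults emulate the reference trial cohort."""

    n: int = 21631
    seed: int = 0
    group_mix: Mapping[str, float] = field(default_factory=lambda: dict(_GROUP_MIX))
    fh_mix: Mapping[str, float] = field(default_factory=lambda: dict(_FH_MIX))
    density_mix: Mapping[str, float] = field(default_factory=lambda: dict(_DENSITY_MIX))
    biopsy_mix: Mapping[str, float] = field(default_factory=lambda: dict(_BIOPSY_MIX))
    pv_rate: float = 669 / _N_REF
    age_min: int = 40
    age_max: int = 74
    #: log-odds slope tying family-history extent to log(PRS)
    fh_prs_link: float = 0.35
    #: log-odds slope tying BI-RADS density to log(PRS)
    density_prs_link: float = 0.25
    missing_rate: float = 0.0
    n_snps: int = 120

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("cohort size must be >= 0")
        for name in ("group_mix", "fh_mix", "density_mix", "biopsy_mix"):
            _check_mix(name, getattr(self, name))
        if not 0.0 <= self.pv_rate <= 1.0:
            raise ValueError("pv_rate must lie in [0, 1]")
        for name in ("fh_prs_link", "density_prs_link"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class SimulatedCohort:
    participants: list[Participant]
    dosages: np.ndarray  # (n, n_snps), aligned to the shared panel SNP order
    panels: dict[AncestryGroup, SnpPanel]
    prs: np.ndarray
    prs_groups: list[AncestryGroup]


def simulate_panel(
    n_snps: int = 120,
    seed: int = 0,
    or_log_sd: float = 0.08,
    freq_range: tuple[float, float] = (0.05, 0.95),
) -> dict[AncestryGroup, SnpPanel]:
    """Synthetic per-group SNP panels sharing one SNP set.

    Odds ratios are log-normal around 1 (small per-SNP effects, as in
    GWAS-derived breast cancer panels) and risk-allele frequencies uniform
    on ``freq_range``, drawn independently per ancestry group.
    """
    if n_snps < 1:
        raise ValueError("panel must contain at least one SNP")
    rng = np.random.default_rng(seed)
    groups = list(AncestryGroup)
    ors = {g: np.exp(rng.normal(0.0, or_log_sd, size=n_snps)) for g in groups}
    freqs = {g: rng.uniform(*freq_range, size=n_snps) for g in groups}
    alleles = np.array(list("ACGT"))
    positions = np.sort(rng.choice(np.arange(1, 10_000_000), size=n_snps, replace=False))
    records = []
    for i in range(n_snps):
        a, b = rng.choice(4, size=2, replace=False)
        records.append(
            SnpRecord(
                rsid=f"rs{1_000_000 + i}",
                chrom=str(1 + i % 22),
                pos=int(positions[i]),
                risk_allele=str(alleles[a]),
                other_allele=str(alleles[b]),
                per_group_or={g: float(ors[g][i]) for g in groups},
                per_group_freq={g: float(freqs[g][i]) for g in groups},
            )
        )
    return {g: SnpPanel(group=g, snps=records) for g in groups}


def simulate_genotypes(
    panel: SnpPanel,
    n: int,
    rng: np.random.Generator | int = 0,
    missing_rate: float = 0.0,
) -> np.ndarray:
    """Independent Hardy-Weinberg dosages: Binomial(2, p_snp) per SNP."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    D = rng.binomial(2, panel.freqs, size=(n, panel.size)).astype(np.int8)
    if missing_rate > 0:
        D[rng.random(size=D.shape) < missing_rate] = -1
    return D


def _ordinal_draw(
    rng: np.random.Generator,
    categories: Sequence[str],
    base_probs: np.ndarray,
    z: np.ndarray,
    slope: float,
) -> np.ndarray:
    """Proportional-odds draw: P(cat <= k | z) = expit(logit(F_k) - slope*z)."""
    F = np.cumsum(base_probs)
    cut = np.log(F[:-1] / (1.0 - F[:-1]))  # logit of interior cumulative probs
    u = rng.random(size=z.shape[0])
    # cumulative probability at each cutpoint, shifted by the PRS link
    cum = 1.0 / (1.0 + np.exp(-(cut[None, :] - slope * z[:, None])))
    idx = (u[:, None] > cum).sum(axis=1)
    return np.asarray(categories, dtype=object)[idx]


def simulate_cohort(
    config: CohortConfig,
    panels: dict[AncestryGroup, SnpPanel] | None = None,
) -> SimulatedCohort:
    """Draw a full synthetic cohort (phenotypes + genotypes + PRS)."""
    rng = np.random.default_rng(config.seed)
    if panels is None:
        panels = simulate_panel(n_snps=config.n_snps, seed=config.seed)
    n = config.n
    any_panel = next(iter(panels.values()))
    n_snps = any_panel.size

    demo_cats = list(config.group_mix)
    demo = rng.choice(demo_cats, size=n, p=[config.group_mix[c] for c in demo_cats])
    ages = (config.age_min + np.floor(
        (config.age_max - config.age_min + 1) * rng.beta(1.2, 1.7, size=n)
    )).astype(int)
    ages = np.minimum(ages, config.age_max)
    pv = rng.random(size=n) < config.pv_rate

    prs_groups = [
        assign_prs_group(*_GROUP_TO_RACE[c]) for c in demo
    ]
    group_arr = np.array([g.value for g in prs_groups])

    dosages = np.empty((n, n_snps), dtype=np.int8)
    for g in AncestryGroup:
        mask = group_arr == g.value
        if mask.any():
            dosages[mask] = simulate_genotypes(
                panels[g], int(mask.sum()), rng, config.missing_rate
            )

    prs = np.empty(n, dtype=float)
    for g in AncestryGroup:
        mask = group_arr == g.value
        if mask.any():
            prs[mask], _, _ = compute_prs_matrix(dosages[mask], panels[g], 1.0 - 1e-9)

    z = np.log(prs)
    fh_cats = ["none", "sdr_only", "fdr_only", "both"]
    fh = _ordinal_draw(
        rng, fh_cats, np.array([config.fh_mix[c] for c in fh_cats]), z, config.fh_prs_link
    )
    unknown_density = rng.random(size=n) < config.density_mix["unknown"]
    dens_cats = ["a", "b", "c", "d"]
    dens_probs = np.array([config.density_mix[c] for c in dens_cats])
    density = _ordinal_draw(
        rng, dens_cats, dens_probs / dens_probs.sum(), z, config.density_prs_link
    )
    density[unknown_density] = "unknown"
    biopsy_cats = list(config.biopsy_mix)
    biopsy = rng.choice(biopsy_cats, size=n, p=[config.biopsy_mix[c] for c in biopsy_cats])

    extra_rel = rng.binomial(1, 0.2, size=(n, 2))  # some women have >1 affected relative
    participants = []
    for i in range(n):
        race, hisp = _GROUP_TO_RACE[demo[i]]
        has_fdr = fh[i] in ("fdr_only", "both")
        has_sdr = fh[i] in ("sdr_only", "both")
        participants.append(
            Participant(
                id=f"P{i:06d}",
                age=int(ages[i]),
                race=race,
                hispanic=hisp,
                fdr_bc=int(has_fdr) * (1 + int(extra_rel[i, 0])),
                sdr_bc=int(has_sdr) * (1 + int(extra_rel[i, 1])),
                biopsy=str(biopsy[i]),
                density=str(density[i]),
                pv_carrier=bool(pv[i]),
            )
        )
    return SimulatedCohort(
        participants=participants,
        dosages=dosages,
        panels=panels,
        prs=prs,
        prs_groups=prs_groups,
    )


def cohort_frame(cohort: SimulatedCohort) -> pd.DataFrame:
    """Phenotype table (one row per participant) as a DataFrame."""
    rows = []
    for part, g, prs in zip(cohort.participants, cohort.prs_groups, cohort.prs):
        rows.append(
            {
                "id": part.id,
                "age": part.age,
                "race": part.race,
                "hispanic": part.hispanic,
                "fdr_bc": part.fdr_bc,
                "sdr_bc": part.sdr_bc,
                "biopsy": part.biopsy,
                "density": part.density,
                "pv_carrier": part.pv_carrier,
                "prs_group": g.value,
                "prs": prs,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id", "age", "race", "hispanic", "fdr_bc", "sdr_bc",
            "biopsy", "density", "pv_carrier", "prs_group", "prs",
        ],
    )


def write_fixtures(cohort: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write cohort CSV, dosage CSV, panel TSV and genotype VCF.

    Files round-trip losslessly through the :mod:`riskpipe.io` readers.
    """
    from . import io as rio  # local import to avoid a cycle at import time

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": out / "cohort.csv",
        "dosages": out / "dosages.csv",
        "panel": out / "panel.tsv",
        "vcf": out / "genotypes.vcf",
    }
    cohort_frame(cohort).to_csv(paths["cohort"], index=False)
    any_panel = next(iter(cohort.panels.values()))
    ids = [p.id for p in cohort.participants]
    rio.write_dosage_csv(paths["dosages"], ids, any_panel.rsids, cohort.dosages)
    rio.write_panel(paths["panel"], cohort.panels)
    rio.write_vcf(paths["vcf"], ids, any_panel.snps, cohort.dosages)
    return paths
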