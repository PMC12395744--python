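"""Readers and writers for panels, genotypes, phenotypes and config tables.

File formats
------------
* SNP panel: TSV with columns ``rsid chrom pos risk_allele other_allele``
  then ``or_<group>`` and ``freq_<group>`` per ancestry group.
* Genotypes: VCF (dosage = count of risk alleles in GT, matched on rsid
  first, then on chrom/pos + alleles; strand-ambiguous A/T and C/G SNPs
  are flagged) or a plain dosage CSV (rows = participants, columns =
  rsids, missing as empty or -1).
* Clinical coefficients, screening thresholds, screens-per-year frequency
  map and reference cross-tabs: YAML.  Bundled defaults under
  ``riskpipe/data/`` are synthetic, structurally faithful stand-ins; the
  real published tables load without code changes.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from .analysis import ReassignmentTable
from .bcsc import BcscCoefficients, Participant
from .policy import (
    AgeBand,
    ScreeningRecommendation,
    ThresholdRule,
    ThresholdTable,
)
from .prs import MISSING, AncestryGroup, SnpPanel, SnpRecord

__all__ = [
    "load_panel",
    "write_panel",
    "load_dosage_csv",
    "write_dosage_csv",
    "load_vcf_dosages",
    "write_vcf",
    "load_cohort_csv",
    "load_bcsc_coefficients",
    "load_thresholds",
    "load_freq_map",
    "load_reference_crosstabs",
    "default_coefficients_path",
    "default_thresholds_path",
]


def _data_path(name: str) -> Path:
    return Path(str(resources.files("riskpipe").joinpath("data", name)))


def default_coefficients_path() -> Path:
    return _data_path("bcsc_coefficients_synthetic.yaml")


def default_thresholds_path() -> Path:
    return _data_path("screening_thresholds_placeholder.yaml")


# ---------------------------------------------------------------- panels


def load_panel(path: str | Path) -> dict[AncestryGroup, SnpPanel]:
    """Read a panel TSV into one :class:`SnpPanel` per ancestry group."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"rsid", "chrom", "pos", "risk_allele", "other_allele"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel file missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        per_or = {
            g: float(getattr(row, f"or_{g.value.lower()}")) for g in AncestryGroup
        }
        per_freq = {
            g: float(getattr(row, f"freq_{g.value.lower()}")) for g in AncestryGroup
        }
        records.append(
            SnpRecord(
                rsid=row.rsid,
                chrom=str(row.chrom),
                pos=int(row.pos),
                risk_allele=row.risk_allele,
                other_allele=row.other_allele,
                per_group_or=per_or,
                per_group_freq=per_freq,
            )
        )
    return {g: SnpPanel(group=g, snps=records) for g in AncestryGroup}


def write_panel(path: str | Path, panels: Mapping[AncestryGroup, SnpPanel]) -> None:
    snps = next(iter(panels.values())).snps
    rows = []
    for snp in snps:
        row = {
            "rsid": snp.rsid,
            "chrom": snp.chrom,
            "pos": snp.pos,
            "risk_allele": snp.risk_allele,
            "other_allele": snp.other_allele,
        }
        for g in AncestryGroup:
            row[f"or_{g.value.lower()}"] = snp.per_group_or[g]
            row[f"freq_{g.value.lower()}"] = snp.per_group_freq[g]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -------------------------------------------------------------- genotypes


def load_dosage_csv(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    """Read a dosage CSV -> (participant ids, rsids, dosage matrix)."""
    df = pd.read_csv(path, index_col=0)
    D = df.to_numpy(dtype=float)
    D = np.where(np.isnan(D), MISSING, D).astype(np.int8)
    return [str(i) for i in df.index], [str(c) for c in df.columns], D


def write_dosage_csv(
    path: str | Path, ids: Sequence[str], rsids: Sequence[str], dosages: np.ndarray
) -> None:
    df = pd.DataFrame(np.asarray(dosages), index=list(ids), columns=list(rsids))
    df = df.astype(object).mask(df == MISSING, "")
    df.to_csv(path, index_label="id")


def write_vcf(
    path: str | Path,
    sample_ids: Sequence[str],
    snps: Sequence[SnpRecord],
    dosages: np.ndarray,
) -> None:
    """Write genotypes as an uncompressed VCF (REF = other allele,
    ALT = risk allele, GT from the risk-allele dosage)."""
    D = np.asarray(dosages)
    if D.shape != (len(sample_ids), len(snps)):
        raise ValueError("dosage matrix does not match samples x SNPs")
    def chrom_key(c: str):
        return (0, int(c)) if c.isdigit() else (1, c)

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    order = sorted(range(len(snps)), key=lambda i: (chrom_key(snps[i].chrom), snps[i].pos))
    for chrom in sorted({s.chrom for s in snps}, key=chrom_key):
        header.contigs.add(chrom)
    for sid in sample_ids:
        header.add_sample(str(sid))
    gt_by_dosage = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i in order:
            snp = snps[i]
            rec = vcf.new_record(
                contig=snp.chrom,
                start=snp.pos - 1,
                stop=snp.pos - 1 + len(snp.other_allele),
                alleles=(snp.other_allele, snp.risk_allele),
                id=snp.rsid,
            )
            for j, sid in enumerate(sample_ids):
                rec.samples[str(sid)]["GT"] = gt_by_dosage[int(D[j, i])]
                rec.samples[str(sid)].phased = False
            vcf.write(rec)


def load_vcf_dosages(
    path: str | Path, panel: SnpPanel
) -> tuple[list[str], np.ndarray, list[str]]:
    """Extract risk-allele dosages aligned to a panel from a VCF.

    Matching is by rsid (ID column) first, then by chrom/pos + allele
    pair.  Returns (sample ids, dosage matrix, flagged rsids) where flags
    name strand-ambiguous (A/T, C/G) panel SNPs; these are scored by
    default but reported so callers can exclude them.
    """
    by_rsid = {snp.rsid: k for k, snp in enumerate(panel.snps)}
    by_locus = {
        (snp.chrom, snp.pos, frozenset((snp.risk_allele, snp.other_allele))): k
        for k, snp in enumerate(panel.snps)
    }
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        D = np.full((len(samples), panel.size), MISSING, dtype=np.int8)
        for rec in vcf:
            k = by_rsid.get(rec.id)
            if k is None:
                if rec.alts is None or len(rec.alts) != 1:
                    continue
                k = by_locus.get(
                    (str(rec.chrom), rec.pos, frozenset((rec.ref, rec.alts[0])))
                )
            if k is None:
                continue
            snp = panel.snps[k]
            # which VCF allele index carries the panel risk allele
            alleles = (rec.ref,) + tuple(rec.alts or ())
            if snp.risk_allele not in alleles:
                continue
            risk_idx = alleles.index(snp.risk_allele)
            for j, sid in enumerate(samples):
                gt = rec.samples[sid]["GT"]
                if gt is None or any(a is None for a in gt):
                    continue
                D[j, k] = sum(1 for a in gt if a == risk_idx)
    flagged = [snp.rsid for snp in panel.snps if snp.strand_ambiguous]
    if flagged:
        warnings.warn(
            f"{len(flagged)} strand-ambiguous (A/T or C/G) panel SNPs scored as-is"
        )
    return [str(s) for s in samples], D, flagged


# ------------------------------------------------------------- phenotypes


def load_cohort_csv(path: str | Path) -> list[Participant]:
    df = pd.read_csv(path, dtype={"id": str}, keep_default_na=False, na_values=[""])
    participants = []
    for row in df.itertuples(index=False):
        hisp = row.hispanic
        if isinstance(hisp, str):
            hisp = hisp.strip().lower() in ("true", "1", "yes")
        elif pd.isna(hisp):
            hisp = None
        participants.append(
            Participant(
                id=str(row.id),
                age=int(row.age),
                race=None if pd.isna(row.race) else str(row.race),
                hispanic=None if hisp is None else bool(hisp),
                fdr_bc=int(row.fdr_bc),
                sdr_bc=int(row.sdr_bc),
                biopsy=str(row.biopsy),
                density=str(row.density),
                pv_carrier=str(row.pv_carrier).strip().lower() in ("true", "1", "yes"),
            )
        )
    return participants


# ----------------------------------------------------------- config tables


def _expand_age_keys(vec: Mapping) -> dict[int, float]:
    """Accept integer-age keys or 'lo-hi' band keys; expand to per-age."""
    out: dict[int, float] = {}
    for key, value in vec.items():
        if isinstance(key, int):
            out[key] = float(value)
        else:
            lo, hi = (int(x) for x in str(key).split("-"))
            for age in range(lo, hi + 1):
                out[age] = float(value)
    return out


def load_bcsc_coefficients(path: str | Path | None = None) -> BcscCoefficients:
    """Load a clinical-risk coefficient file.

    Relative risks may be given either as an explicit cross-classified
    ``rr_table`` (keys ``density|fdr|biopsy|age_band``) or as
    ``rr_components`` (per-covariate multipliers combined
    multiplicatively, optionally age-band specific for density).
    """
    if path is None:
        path = default_coefficients_path()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    age_bands = tuple(
        tuple(int(x) for x in str(b).split("-")) for b in raw.get("age_bands", ["40-49", "50-74"])
    )
    band_labels = [f"{lo}-{hi}" for lo, hi in age_bands]
    rr_table: dict[tuple[str, str, str, str], float] = {}
    if "rr_table" in raw:
        for key, rr in raw["rr_table"].items():
            density, fdr, biopsy, band = (s.strip() for s in str(key).split("|"))
            rr_table[(density, fdr, biopsy, band)] = float(rr)
    else:
        comp = raw["rr_components"]
        dens_rr = comp["density"]
        for band in band_labels:
            dens_band = dens_rr.get(band, dens_rr) if isinstance(dens_rr, dict) else dens_rr
            for density, d_rr in dens_band.items():
                if isinstance(d_rr, dict):  # nested band structure
                    continue
                for fdr_key, f_rr in comp["fdr"].items():
                    for biopsy, b_rr in comp["biopsy"].items():
                        rr_table[(str(density), str(fdr_key), str(biopsy), band)] = (
                            float(d_rr) * float(f_rr) * float(b_rr)
                        )
    baseline = {g: _expand_age_keys(v) for g, v in raw["baseline_hazard"].items()}
    competing = {g: _expand_age_keys(v) for g, v in raw["competing_hazard"].items()}
    return BcscCoefficients(
        rr_table=rr_table,
        baseline_hazard=baseline,
        competing_hazard=competing,
        age_bands=age_bands,
    )


def load_thresholds(path: str | Path | None = None) -> ThresholdTable:
    """Load and validate a screening threshold table from YAML."""
    if path is None:
        path = default_thresholds_path()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    bands = []
    for band in raw["age_bands"]:
        lo, hi = (int(x) for x in band["ages"])
        rules = tuple(
            ThresholdRule(
                risk_lo=float(r["risk_lo"]),
                risk_hi=float(r["risk_hi"]),
                recommendation=ScreeningRecommendation(r["recommendation"]),
            )
            for r in band["rules"]
        )
        bands.append(AgeBand(age_lo=lo, age_hi=hi, rules=rules))
    overrides = {
        str(o["density"]): ScreeningRecommendation(o["recommendation"])
        for o in raw.get("density_overrides", [])
    }
    age_min = min(b.age_lo for b in bands)
    age_max = max(b.age_hi for b in bands)
    return ThresholdTable(
        bands=tuple(sorted(bands, key=lambda b: b.age_lo)),
        density_overrides=overrides,
        age_min=age_min,
        age_max=age_max,
    )


def load_freq_map(path: str | Path) -> dict[ScreeningRecommendation, float]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {ScreeningRecommendation(k): float(v) for k, v in raw.items()}


def load_reference_crosstabs(path: str | Path | None = None) -> dict[str, ReassignmentTable]:
    """Load the reconstructed year-1 cross-tabs for the two age strata.

    Cells documented as published in the source YAML are exact; the
    remaining cells are a synthetic reconstruction consistent with every
    published marginal and utilization figure.
    """
    if path is None:
        path = _data_path("year1_crosstabs_reconstructed.yaml")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for stratum, spec in raw["strata"].items():
        cells = {}
        for row in spec["cells"]:
            cells[(row["from"], row["to"])] = int(row["count"])
        out[str(stratum)] = ReassignmentTable.from_dict(str(stratum), cells)
    return out
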