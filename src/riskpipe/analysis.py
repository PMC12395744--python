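"""Reassignment and utilization analysis of screening recommendations.

Cross-tabulates year-1 recommendations under the clinical-only model
against the PRS-combined model, computes discordance percentages and
per-cell reassignment fractions, projects screening utilization
(screens per woman-year and its "1 screen per N women" reciprocal),
exports Sankey flow records, and provides the descriptive and rank
statistics used to compare PRS across subgroups (Wilcoxon rank-sum,
Kruskal-Wallis, a Jonckheere-Terpstra trend test, Pearson r^2).

PV carriers are excluded upstream from all of these analyses: the PRS is
not used to set their screening.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bcsc import Participant, absolute_5yr_risk, hazard_group, relative_risk
from .combine import combine_bcsc_prs
from .policy import (
    DEFAULT_FREQ_MAP,
    AssignmentRecord,
    ScreeningRecommendation,
    ThresholdTable,
    assign_screening,
)

__all__ = [
    "REC_ORDER",
    "ReassignmentTable",
    "GroupSummary",
    "assign_cohort",
    "cross_tabulate",
    "discordance_percentage",
    "cell_reassignment_fraction",
    "mean_screens_per_woman_year",
    "sankey_flows",
    "rank_group_compare",
    "trend_test",
    "pearson_r2",
    "summarize_prs_by_group",
    "round_half_up",
]

#: Fixed row/column order for cross-tabulations (risk-based ladder only).
REC_ORDER: tuple[ScreeningRecommendation, ...] = (
    ScreeningRecommendation.NONE_OR_STOP,
    ScreeningRecommendation.BIENNIAL,
    ScreeningRecommendation.ANNUAL_RISK,
    ScreeningRecommendation.ANNUAL_DENSITY,
    ScreeningRecommendation.Q6MO_ALTERNATING,
)


def round_half_up(x: float) -> int:
    """Round with ties away from zero, matching reported integer percents."""
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass
class ReassignmentTable:
    """Cross-tabulation of recommendations under two risk models."""

    age_stratum: str
    counts: pd.DataFrame  # index: rec under model A, columns: rec under model B

    @property
    def n_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @classmethod
    def from_dict(
        cls, age_stratum: str, cells: Mapping[tuple, int]
    ) -> "ReassignmentTable":
        idx = [r.value for r in REC_ORDER]
        counts = pd.DataFrame(0, index=idx, columns=idx, dtype=int)
        for (a, b), n in cells.items():
            a = ScreeningRecommendation(a).value
            b = ScreeningRecommendation(b).value
            counts.loc[a, b] += int(n)
        return cls(age_stratum=age_stratum, counts=counts)

    def row_marginal(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def col_marginal(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive PRS summary for one subgroup (Median (IQR) / Mean (SD))."""

    group: str
    n: int
    mean: float
    sd: float | None
    median: float
    q1: float
    q3: float


def assign_cohort(
    participants: Sequence[Participant],
    prs_values: Sequence[float],
    coeffs,
    thresholds: ThresholdTable,
    year: int = 1,
    attenuation: float = 1.0,
) -> tuple[list[AssignmentRecord], list]:
    """Run the full year-1 pipeline over a cohort.

    For each non-PV participant: clinical relative risk -> absolute 5-year
    risk -> Bayesian combination with the PRS -> threshold assignment
    under both the clinical-only and combined risks.  PV carriers get
    PV_GUIDELINE in every slot.  Returns (records, risk estimates) where
    risk estimates are (bcsc, prs, combined) triplets aligned to records.
    """
    if len(participants) != len(prs_values):
        raise ValueError("participants and prs_values must align")
    records: list[AssignmentRecord] = []
    estimates = []
    for part, prs in zip(participants, prs_values):
        aged = part.aged(year - 1)
        if aged.pv_carrier:
            records.append(
                AssignmentRecord(
                    participant_id=aged.id,
                    year=year,
                    rec_bcsc=ScreeningRecommendation.PV_GUIDELINE,
                    rec_combined=ScreeningRecommendation.PV_GUIDELINE,
                    rec_final=ScreeningRecommendation.PV_GUIDELINE,
                )
            )
            estimates.append(None)
            continue
        rr = relative_risk(aged, coeffs)
        bcsc = absolute_5yr_risk(rr, aged.age, hazard_group(aged), coeffs)
        combined = combine_bcsc_prs(bcsc, prs, attenuation=attenuation)
        records.append(
            AssignmentRecord(
                participant_id=aged.id,
                year=year,
                rec_bcsc=assign_screening(aged, bcsc, thresholds),
                rec_combined=assign_screening(aged, combined, thresholds),
            )
        )
        estimates.append((bcsc, prs, combined))
    return records, estimates


def cross_tabulate(
    records: Iterable[AssignmentRecord], age_stratum: str = "all"
) -> ReassignmentTable:
    """Count (rec under clinical model, rec under combined model) pairs.

    Input records must already be restricted to non-PV, scoreable,
    single-year participants; PV_GUIDELINE rows are rejected.
    """
    idx = [r.value for r in REC_ORDER]
    counts = pd.DataFrame(0, index=idx, columns=idx, dtype=int)
    for rec in records:
        if (
            rec.rec_bcsc is ScreeningRecommendation.PV_GUIDELINE
            or rec.rec_combined is ScreeningRecommendation.PV_GUIDELINE
        ):
            raise ValueError("PV carriers must be excluded before cross-tabulation")
        counts.loc[rec.rec_bcsc.value, rec.rec_combined.value] += 1
    return ReassignmentTable(age_stratum=age_stratum, counts=counts)


def discordance_percentage(table: ReassignmentTable) -> float:
    """Percent of participants whose recommendation changed (off-diagonal)."""
    n = table.n_total
    if n == 0:
        raise ValueError("cannot compute discordance of an empty table")
    off_diag = n - int(np.trace(table.counts.to_numpy()))
    return 100.0 * off_diag / n


def cell_reassignment_fraction(
    table: ReassignmentTable, from_rec, to_rec
) -> float:
    """Percent of a from-row reassigned to a given recommendation."""
    a = ScreeningRecommendation(from_rec).value
    b = ScreeningRecommendation(to_rec).value
    row_total = int(table.counts.loc[a].sum())
    if row_total == 0:
        raise ValueError(f"row {a} is empty")
    return 100.0 * int(table.counts.loc[a, b]) / row_total


def mean_screens_per_woman_year(
    recommendations,
    freq_map: Mapping[ScreeningRecommendation, float] | None = None,
) -> tuple[float, int | None]:
    """Projected screens per woman-year and rounded women-per-screen.

    ``recommendations`` may be an iterable of recommendations or a mapping
    recommendation -> count (e.g. a cross-tab marginal).  Returns
    ``(mean, women_per_screen)`` with the reciprocal rounded half-up to an
    integer, or None when no screening at all is recommended.
    """
    fm = DEFAULT_FREQ_MAP if freq_map is None else freq_map
    if isinstance(recommendations, (Mapping, pd.Series)):
        items = [(ScreeningRecommendation(r), int(n)) for r, n in recommendations.items()]
    else:
        items = [(ScreeningRecommendation(r), 1) for r in recommendations]
    n = sum(cnt for _, cnt in items)
    if n == 0:
        raise ValueError("cannot average screens over an empty cohort")
    try:
        total = sum(fm[rec] * cnt for rec, cnt in items)
    except KeyError as exc:
        raise KeyError(f"no screens-per-year frequency for {exc}") from None
    mean = total / n
    return mean, (round_half_up(1.0 / mean) if mean > 0 else None)


def sankey_flows(records: Sequence[AssignmentRecord]) -> list[dict]:
    """Flow records for a three-column Sankey (clinical -> combined -> final).

    One flow per nonzero (source, target) pair; totals at every node
    conserve the number of input records.  The final stage is included
    only when every record carries a final recommendation.
    """
    records = list(records)
    flows: list[dict] = []
    have_final = all(r.rec_final is not None for r in records)
    stages = [("bcsc", "combined", lambda r: (r.rec_bcsc, r.rec_combined))]
    if have_final:
        stages.append(("combined", "final", lambda r: (r.rec_combined, r.rec_final)))
    for src_stage, dst_stage, key in stages:
        counts: dict[tuple, int] = {}
        for r in records:
            a, b = key(r)
            counts[(a, b)] = counts.get((a, b), 0) + 1
        for (a, b), n in sorted(counts.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)):
            flows.append(
                {
                    "source": f"{src_stage}:{a.value}",
                    "target": f"{dst_stage}:{b.value}",
                    "count": n,
                }
            )
    return flows


def _grouped(values, labels) -> dict:
    groups: dict = {}
    for v, lab in zip(values, labels, strict=True):
        groups.setdefault(lab, []).append(float(v))
    return groups


def rank_group_compare(values, labels) -> tuple[str, float, float]:
    """Two groups -> two-sided Wilcoxon rank-sum; >=3 -> Kruskal-Wallis.

    The Wilcoxon test is exact when both groups are small (<= 25) and
    tie-free, otherwise the normal approximation with tie correction is
    used.  Returns (test name, statistic, p value).
    """
    groups = _grouped(values, labels)
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    samples = list(groups.values())
    if len(samples) == 2:
        x, y = samples
        pooled = x + y
        exact = max(len(x), len(y)) <= 25 and len(set(pooled)) == len(pooled)
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
        return "wilcoxon_rank_sum", float(res.statistic), float(res.pvalue)
    res = stats.kruskal(*samples)
    return "kruskal_wallis", float(res.statistic), float(res.pvalue)


def _jt_statistic(samples: Sequence[Sequence[float]]) -> float:
    """Sum of pairwise Mann-Whitney counts over ordered group pairs."""
    stat = 0.0
    for i, j in itertools.combinations(range(len(samples)), 2):
        for a in samples[i]:
            for b in samples[j]:
                if b > a:
                    stat += 1.0
                elif b == a:
                    stat += 0.5
    return stat


def trend_test(values, labels, ordered_labels: Sequence) -> tuple[float, float]:
    """Jonckheere-Terpstra test for an increasing trend across ordered groups.

    One-sided against the alternative that values increase along
    ``ordered_labels``.  Small tie-free layouts (total n <= 8) are tested
    exactly by permutation enumeration; otherwise the normal approximation
    with tie-corrected variance and continuity correction is used.
    Returns (statistic, one-sided p value).
    """
    groups = _grouped(values, labels)
    if list(ordered_labels) != sorted(set(ordered_labels), key=list(ordered_labels).index):
        raise ValueError("ordered_labels contains duplicates")
    missing = set(groups) - set(ordered_labels)
    if missing:
        raise ValueError(f"labels {sorted(missing)!r} not in ordered_labels")
    if len([g for g in ordered_labels if g in groups]) < 3:
        raise ValueError("trend test requires at least three ordered categories")
    samples = [groups[g] for g in ordered_labels if g in groups]
    sizes = [len(s) for s in samples]
    N = sum(sizes)
    obs = _jt_statistic(samples)

    if N <= 8:
        pooled = [v for s in samples for v in s]
        ge = 0
        total = 0
        for perm in itertools.permutations(pooled):
            arranged, k = [], 0
            for n_i in sizes:
                arranged.append(perm[k : k + n_i])
                k += n_i
            total += 1
            if _jt_statistic(arranged) >= obs - 1e-12:
                ge += 1
        return obs, ge / total

    mean = (N * N - sum(n * n for n in sizes)) / 4.0
    # tie-corrected null variance (standard three-term formula)
    pooled = [v for s in samples for v in s]
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(float)
    n_arr = np.array(sizes, dtype=float)
    A = (
        N * (N - 1) * (2 * N + 5)
        - np.sum(n_arr * (n_arr - 1) * (2 * n_arr + 5))
        - np.sum(t * (t - 1) * (2 * t + 5))
    )
    B = np.sum(n_arr * (n_arr - 1) * (n_arr - 2)) * np.sum(t * (t - 1) * (t - 2))
    C = np.sum(n_arr * (n_arr - 1)) * np.sum(t * (t - 1))
    var = A / 72.0 + B / (36.0 * N * (N - 1) * (N - 2)) + C / (8.0 * N * (N - 1))
    if var <= 0:
        return obs, 0.5 if math.isclose(obs, mean) else (0.0 if obs > mean else 1.0)
    z = (obs - 0.5 - mean) / math.sqrt(var) if obs > mean else (obs + 0.5 - mean) / math.sqrt(var)
    return obs, float(stats.norm.sf(z))


def pearson_r2(x, y) -> tuple[float, float]:
    """Squared Pearson correlation and two-sided p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in one of the variables")
    res = stats.pearsonr(x, y)
    return float(res.statistic**2), float(res.pvalue)


def summarize_prs_by_group(values, labels) -> list[GroupSummary]:
    """Per-group n, mean, sample SD, median and quartiles of the PRS.

    Quartiles use the same linear-interpolation percentile convention as
    the quintile cutpoints.  Empty groups are omitted with a warning;
    singleton groups report SD as None.
    """
    groups = _grouped(values, labels)
    out = []
    for lab, vals in groups.items():
        if not vals:
            warnings.warn(f"group {lab!r} is empty; omitted from summary")
            continue
        arr = np.asarray(vals, dtype=float)
        q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
        out.append(
            GroupSummary(
                group=str(lab),
                n=arr.size,
                mean=float(arr.mean()),
                sd=float(arr.std(ddof=1)) if arr.size > 1 else None,
                median=float(med),
                q1=float(q1),
                q3=float(q3),
            )
        )
    return out
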