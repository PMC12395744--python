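# Methods

## PRS construction

The score is multiplicative over panel SNPs: each SNP contributes
OR^g / μ, with g the risk-allele dosage, OR the per-allele odds ratio for
the participant's self-reported race/ethnicity group, and μ the
Hardy–Weinberg mean of OR^g at that group's risk-allele frequency. This is
the standard log-additive (per-allele multiplicative) model; the division
by μ makes the expectation of each factor exactly 1 in a cancer-free
Hardy–Weinberg population, so the cohort mean PRS is ~1 by construction —
a property we assert both in closed form (exhaustive genotype enumeration
for ≤3-SNP panels) and by large-scale simulation. Internally scores are
accumulated as sums of logs and exponentiated once; products and
sums-of-logs agree to 1e-10 relative tolerance and the representation is
invariant to SNP order.

Group routing: Hispanic ethnicity dominates race; Asian, Native Hawaiian
and Pacific Islander route to the NH Asian parameters; Black to NH Black;
White, Native American, other, mixed and unreported race to NH White
(groups without sufficient GWAS data are scored with NH White parameters).
An unrecognized race label with non-Hispanic ethnicity is an error, not a
silent default.

Missing genotypes contribute a neutral factor 1.0 and are counted; a
result whose missing fraction exceeds `max_missing_fraction` (default 0)
is flagged non-scoreable rather than silently returned, mirroring a trial
design that excludes rather than imputes. Strand-ambiguous (A/T, C/G)
panel SNPs are flagged on VCF import but scored by default.

Quintile cutpoints use linear interpolation between order statistics
(`numpy.percentile`, `method="linear"`); the same convention is used for
all reported quartiles.

## Clinical absolute risk

The relative-risk table is cross-classified on BI-RADS density, binary
first-degree family history, worst prior biopsy pathology and age band
(40–49 / 50–74). Family history is deliberately binary — the number of
affected first-degree relatives and all second-degree history are ignored
by this model generation. Unknown density and biopsy map to dedicated
table rows, set to the reference multiplier in the bundled fixture. The
reference pattern (density b, no first-degree history, no biopsy) has
relative risk exactly 1.

Absolute risk uses an annual-interval cause-specific competing-risk
projection over a 5-year window [age, age+5): within each year the total
hazard is rr·h₁ + h₂; the breast cancer share of events that year is
rr·h₁/(rr·h₁+h₂); and survival to the start of each year discounts its
contribution. The projection is strictly increasing in rr whenever h₁ is
positive somewhere in the window, bounded by 1 − exp(−Σ rr·h₁), and
matches a piecewise-exponential competing-risk simulation of 10⁶ subjects
within Monte-Carlo error. Race/ethnicity enters only through the hazard
vectors (white / black / asian_pi / hispanic / other), which is a separate
mapping from the PRS group routing.

The bundled coefficient file is synthetic: plausible smooth incidence and
mortality rates and invented covariate multipliers with the correct
structure. The loader accepts the real published tables (integer-age or
age-band keys) without code changes; reproducing the published calculator
is a matter of dropping those tables in.

## Bayesian combination

posterior odds = prior odds × PRS^α with α = 1. The centered PRS is
treated as a likelihood ratio on the clinical prior; PRS = 1 is the
identity, the update is strictly monotone in both arguments, invertible
(multiplying by 1/PRS restores the prior to 1e-10), and order-preserving
across participants at fixed PRS. No PRS × family-history or PRS × density
interaction attenuation is applied by default — α ≠ 1 exists as an
explicit opt-in for calibration experiments only.

## Screening policy

The threshold table is validated before use: age bands must partition
40–74 and each band's risk intervals must partition (0, 1) half-open and
lower-inclusive, so boundary risks resolve upward to the higher-intensity
rule. Recommendation intensity is ordered none < biennial < annual <
6-monthly; density overrides (extremely dense breasts → at least annual)
only ever escalate. Pathogenic-variant carriers receive guideline
screening regardless of risk and are excluded from all reassignment and
utilization analyses. The bundled table is an explicitly-labelled
placeholder with the structure above; its cutoffs (40–49: start at 0.009
5-year risk; 50–74: biennial band 0.0035–0.020, annual 0.020–0.040,
6-monthly ≥ 0.040) were chosen once so that, against the synthetic cohort
and the bundled hazards, the pipeline reproduces the qualitative published
pattern: discordance positive in both age strata, larger in 40–49 where
starting age is risk-determined, and utilization of about one screen per
6 women/year (clinical) vs 5 (combined) in 40–49 and one per 2 in 50–74.

Utilization uses the frequency map none = 0, biennial = 0.5, annual = 1,
6-monthly alternating = 2 screens per woman-year. The "1 screen per N
women/year" reciprocal is rounded half-up; the unrounded mean is always
retained alongside it.

## Reassignment analysis

Cross-tabs count (clinical-model, combined-model) recommendation pairs on
non-carrier year-1 records; discordance is the off-diagonal percentage and
per-cell reassignment fractions are row-relative. Sankey export emits one
flow per nonzero cell for the clinical→combined and combined→final stages
and conserves counts at every node. Reported percentages are rounded
half-up to integers, with unrounded values retained.

Rank statistics: two groups are compared with a two-sided Wilcoxon
rank-sum test (exact when both groups are ≤ 25 and tie-free, which we
verify against full enumeration of rank splits; asymptotic with tie
correction otherwise); three or more with Kruskal–Wallis. The ordered
trend across family-history or density categories uses a
Jonckheere–Terpstra test — the trend statistic was left unnamed by the
analyses this package emulates, so the choice is fixed here: sum of
pairwise Mann–Whitney counts over ordered category pairs, exact by
permutation enumeration for total n ≤ 8 and otherwise normal with
tie-corrected variance and continuity correction, one-sided for an
increasing trend. Correlations use the two-sided Pearson coefficient,
reported as r². No multiple-testing correction is applied anywhere.

The reference year-1 cross-tabs shipped in
`riskpipe/data/year1_crosstabs_reconstructed.yaml` embed the published
cells and marginals exactly (strata totals 5752 and 7724; 794 and 801
discordant; the 4466-women none-row with 491 starters; the 675-women
annual-row with 436→biennial and 140→6-monthly); the unpublished cells are
a reconstruction consistent with the published utilization reciprocals,
and the file says so.

## Synthetic cohort generator

The generator emulates the composition of the reference 21,631-participant
cohort using its exact category counts as default mixture weights:
race/ethnicity (Hispanic 8.9%, NH AI/AN 0.2%, NH Asian/PI 4.8%, NH Black
4.5%, NH other/mixed/unknown 4.0%, NH White 77.6%), family history (none
48.2%, second-degree only 24.5%, first-degree only 15.6%, both 11.7%),
BI-RADS density (a 4.7%, b 35.0%, c 39.7%, d 8.7%, unknown 12.0%) and a
3.09% pathogenic-variant rate. Ages are drawn as 40 + ⌊35·Beta(1.2, 1.7)⌋,
matching the published median ~53 and IQR ≈ 45–62; the exact trial age
distribution is not public. The prior-biopsy mix is not published at all;
the default (80% none, 8% nonproliferative, 6% proliferative, 2% atypia,
0.5% LCIS, 3.5% unknown) is an invented plausible screening-population
mix.

Genotypes are independent Hardy–Weinberg draws Binomial(2, p) per SNP with
group-specific frequencies — the exact regime under which the PRS
normalization centers at 1, which the generator asserts rather than
assumes. Family-history extent and density are then drawn *conditional on
the realized log-PRS* through proportional-odds (ordinal-logistic) links
with slopes `fh_prs_link = 0.35` and `density_prs_link = 0.25`, chosen
once to reproduce the direction and rough magnitude of the observed PRS
gradients (mean PRS rising from ~1.00 with no family history to ~1.13
with both first- and second-degree history, and from ~0.98 in density a to
~1.08 in density d). Zero slopes give exact independence. This is the
minimal mechanism that reproduces the reported associations; it does not
simulate relatives, pedigrees, linkage disequilibrium, genotyping error or
breast cancer outcomes.

What passing tests therefore show: the arithmetic, normalization,
projection, combination, policy and analysis layers are correct and
internally consistent, and the qualitative reassignment structure emerges
under realistic composition. What they cannot show: agreement with the
trial's absolute discordance percentages or PRS distribution moments,
which depend on unreleased individual-level data and the unpublished real
panel, coefficient and threshold tables.

## Numerical and design choices

* PRS computed as sum of logs, stored in natural scale; dosage matrices
  are int8 with −1 as the missing sentinel.
* Percentile convention everywhere: linear interpolation.
* Reported integer percentages and reciprocals: round half-up.
* Tie-breaks at threshold boundaries: upward (lower-inclusive intervals).
* Degenerate inputs are errors, not defaults: empty tables, empty rows,
  zero-variance correlations, probabilities at 0 or 1, unrecognized
  category labels.
* Simulation sizes in the test suite (200,000 per group for centering,
  10⁶ subjects for the competing-risk oracle, 20,000-participant pipeline
  cohorts) were chosen as the smallest scales at which the Monte-Carlo
  bounds being asserted are meaningfully tight.

## Known limitations

* The bundled coefficient, threshold and panel files are synthetic
  stand-ins; absolute risk levels and assignment proportions under them
  are not calibrated to any real population.
* Genetic ancestry is self-reported group routing only; no ancestry
  inference, no imputation, no LD modeling, no multi-ancestry PRS.
* The Screening Review Board is modeled only as an id→recommendation
  override pass-through.
* Yearly recalculation updates age only; risk-factor changes over time
  (new biopsies, density changes) are not simulated.
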