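# Year-1 screening recommendation cross-tabs, RECONSTRUCTED.
#
# Rows ("from") are recommendations under the clinical model alone; columns
# ("to") under the PRS-combined model.  The published report prints only a
# subset of cells and marginals; those published values are embedded here
# exactly:
#   40-49 stratum: n = 5752 non-carrier participants, 794 discordant;
#                  none-row total 4466 with 491 reassigned to screening.
#   50-74 stratum: n = 7724, 801 discordant; annual-row total 675 with
#                  436 reassigned to biennial and 140 to twice-yearly
#                  (yearly MRI plus mammogram).
# Every other cell is a SYNTHETIC reconstruction chosen to be consistent
# with the published screens-per-woman-year reciprocals (1 screen per 6
# women/year clinical vs 1 per 5 combined in 40-49; 1 per 2 under both
# models in 50-74).  The published flow diagram merges annual-by-risk and
# annual-by-density into one "annual" node; that merged node is encoded as
# ANNUAL_RISK here.
#
# start_deferral records the published follow-up of the 491 women aged
# 40-49 who started screening only under the combined model: 34 would have
# been recommended to start within study years 2-3 by the clinical model
# alone.

strata:
  "40-49":
    cells:
      - {from: NONE_OR_STOP,     to: NONE_OR_STOP,     count: 3975}
      - {from: NONE_OR_STOP,     to: BIENNIAL,         count: 400}
      - {from: NONE_OR_STOP,     to: ANNUAL_RISK,      count: 80}
      - {from: NONE_OR_STOP,     to: Q6MO_ALTERNATING, count: 11}
      - {from: BIENNIAL,         to: NONE_OR_STOP,     count: 30}
      - {from: BIENNIAL,         to: BIENNIAL,         count: 755}
      - {from: BIENNIAL,         to: ANNUAL_RISK,      count: 60}
      - {from: BIENNIAL,         to: Q6MO_ALTERNATING, count: 5}
      - {from: ANNUAL_RISK,      to: BIENNIAL,         count: 120}
      - {from: ANNUAL_RISK,      to: ANNUAL_RISK,      count: 170}
      - {from: ANNUAL_RISK,      to: Q6MO_ALTERNATING, count: 60}
      - {from: Q6MO_ALTERNATING, to: ANNUAL_RISK,      count: 28}
      - {from: Q6MO_ALTERNATING, to: Q6MO_ALTERNATING, count: 58}
  "50-74":
    cells:
      - {from: NONE_OR_STOP,     to: NONE_OR_STOP,     count: 250}
      - {from: NONE_OR_STOP,     to: BIENNIAL,         count: 50}
      - {from: BIENNIAL,         to: NONE_OR_STOP,     count: 80}
      - {from: BIENNIAL,         to: BIENNIAL,         count: 6360}
      - {from: BIENNIAL,         to: ANNUAL_RISK,      count: 40}
      - {from: BIENNIAL,         to: Q6MO_ALTERNATING, count: 20}
      - {from: ANNUAL_RISK,      to: BIENNIAL,         count: 436}
      - {from: ANNUAL_RISK,      to: ANNUAL_RISK,      count: 99}
      - {from: ANNUAL_RISK,      to: Q6MO_ALTERNATING, count: 140}
      - {from: Q6MO_ALTERNATING, to: ANNUAL_RISK,      count: 35}
      - {from: Q6MO_ALTERNATING, to: Q6MO_ALTERNATING, count: 214}

start_deferral:
  started_under_combined: 491
  would_start_by_clinical_years_2_3: 34
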