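# PLACEHOLDER screening threshold table.
#
# The trial's actual 5-year-risk cutoffs are in its (external) supplement;
# this file is a documented synthetic stand-in with the same structure:
# age bands partitioning 40-74, half-open lower-inclusive risk intervals
# partitioning (0, 1), ascending screening intensity, and a density
# override escalating extremely dense breasts to at least annual
# mammography.  Drop the real table in verbatim to reproduce the trial
# policy.

age_bands:
  - ages: [40, 49]
    rules:
      - {risk_lo: 0.0,    risk_hi: 0.009, recommendation: NONE_OR_STOP}
      - {risk_lo: 0.009,  risk_hi: 0.015, recommendation: BIENNIAL}
      - {risk_lo: 0.015,  risk_hi: 0.030, recommendation: ANNUAL_RISK}
      - {risk_lo: 0.030,  risk_hi: 1.0,   recommendation: Q6MO_ALTERNATING}
  - ages: [50, 74]
    rules:
      - {risk_lo: 0.0,    risk_hi: 0.0035, recommendation: NONE_OR_STOP}
      - {risk_lo: 0.0035, risk_hi: 0.020, recommendation: BIENNIAL}
      - {risk_lo: 0.020,  risk_hi: 0.040, recommendation: ANNUAL_RISK}
      - {risk_lo: 0.040,  risk_hi: 1.0,   recommendation: Q6MO_ALTERNATING}

density_overrides:
  - {density: d, recommendation: ANNUAL_DENSITY}
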