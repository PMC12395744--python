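# SYNTHETIC clinical-risk coefficient tables.
#
# Structurally faithful stand-in for the published BCSC v2 coefficient and
# hazard tables (which are distributed with the published calculator, not
# bundled here).  Relative risks are plausible invented multipliers; the
# reference covariate pattern (density b, no first-degree family history,
# no prior biopsy) has relative risk exactly 1.  Hazards are plausible
# smooth annual rates: baseline breast cancer incidence among
# covariate-reference women and competing (non-breast-cancer) mortality,
# by race/ethnicity hazard group and age.  Replace this file with the real
# published tables to reproduce the published calculator; the loader
# accepts integer-age keys or "lo-hi" band keys.

age_bands: ["40-49", "50-74"]

rr_components:
  density:
    a: 0.6
    b: 1.0
    c: 1.4
    d: 2.1
    unknown: 1.0
  fdr:
    "0": 1.0
    "1": 1.6
  biopsy:
    none: 1.0
    nonproliferative: 1.2
    proliferative_no_atypia: 1.5
    atypia: 2.0
    lcis: 2.5
    unknown: 1.0

baseline_hazard:
  white:
    "40-44": 0.00085
    "45-49": 0.00095
    "50-54": 0.00110
    "55-59": 0.00125
    "60-64": 0.00140
    "65-69": 0.00155
    "70-74": 0.00165
    "75-84": 0.00170
  black:
    "40-44": 0.00081
    "45-49": 0.00090
    "50-54": 0.00105
    "55-59": 0.00119
    "60-64": 0.00133
    "65-69": 0.00147
    "70-74": 0.00157
    "75-84": 0.00162
  asian_pi:
    "40-44": 0.00064
    "45-49": 0.00071
    "50-54": 0.00083
    "55-59": 0.00094
    "60-64": 0.00105
    "65-69": 0.00116
    "70-74": 0.00124
    "75-84": 0.00128
  hispanic:
    "40-44": 0.00068
    "45-49": 0.00076
    "50-54": 0.00088
    "55-59": 0.00100
    "60-64": 0.00112
    "65-69": 0.00124
    "70-74": 0.00132
    "75-84": 0.00136
  other:
    "40-44": 0.00077
    "45-49": 0.00086
    "50-54": 0.00099
    "55-59": 0.00113
    "60-64": 0.00126
    "65-69": 0.00140
    "70-74": 0.00149
    "75-84": 0.00153

competing_hazard:
  white:
    "40-44": 0.0016
    "45-49": 0.0024
    "50-54": 0.0035
    "55-59": 0.0052
    "60-64": 0.0078
    "65-69": 0.0118
    "70-74": 0.0180
    "75-84": 0.0270
  black:
    "40-44": 0.0021
    "45-49": 0.0031
    "50-54": 0.0046
    "55-59": 0.0068
    "60-64": 0.0101
    "65-69": 0.0153
    "70-74": 0.0234
    "75-84": 0.0351
  asian_pi:
    "40-44": 0.0011
    "45-49": 0.0017
    "50-54": 0.0025
    "55-59": 0.0036
    "60-64": 0.0055
    "65-69": 0.0083
    "70-74": 0.0126
    "75-84": 0.0189
  hispanic:
    "40-44": 0.0014
    "45-49": 0.0020
    "50-54": 0.0030
    "55-59": 0.0044
    "60-64": 0.0066
    "65-69": 0.0100
    "70-74": 0.0153
    "75-84": 0.0230
  other:
    "40-44": 0.0016
    "45-49": 0.0024
    "50-54": 0.0035
    "55-59": 0.0052
    "60-64": 0.0078
    "65-69": 0.0118
    "70-74": 0.0180
    "75-84": 0.0270
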