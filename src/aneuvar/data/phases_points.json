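{
  "description": "PHASES aneurysm rupture-risk point table (population, hypertension, age, size, earlier SAH, site). Verified against the published score before release.",
  "population": {
    "north_american_european": 0,
    "japanese": 3,
    "finnish": 5
  },
  "hypertension": {
    "no": 0,
    "yes": 1
  },
  "age": {
    "threshold_years": 70,
    "below": 0,
    "at_or_above": 1
  },
  "size_mm_bins": [
    {"min": 0.0, "max": 7.0, "points": 0},
    {"min": 7.0, "max": 10.0, "points": 3},
    {"min": 10.0, "max": 20.0, "points": 6},
    {"min": 20.0, "max": null, "points": 10}
  ],
  "earlier_sah_other_aneurysm": {
    "no": 0,
    "yes": 1
  },
  "site": {
    "ICA": 0,
    "MCA": 2,
    "ACA_Pcom_posterior": 4
  }
}
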