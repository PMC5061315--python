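{
  "equation": "pce",
  "version": "2013-caucasian",
  "source_citation": "Goff DC Jr et al., 2013 ACC/AHA Guideline on the Assessment of Cardiovascular Risk (white strata)",
  "strata": [
    {
      "sex": "female",
      "race": "white",
      "terms": {
        "ln_age": -29.799,
        "ln_age_sq": 4.884,
        "ln_tc": 13.540,
        "ln_age_ln_tc": -3.114,
        "ln_hdl": -13.578,
        "ln_age_ln_hdl": 3.149,
        "ln_sbp_treated": 2.019,
        "ln_sbp_untreated": 1.957,
        "smoker": 7.574,
        "ln_age_smoker": -1.665,
        "diabetes": 0.661
      },
      "mean_lp": -29.18,
      "s0_10": 0.9665
    },
    {
      "sex": "male",
      "race": "white",
      "terms": {
        "ln_age": 12.344,
        "ln_tc": 11.853,
        "ln_age_ln_tc": -2.664,
        "ln_hdl": -7.990,
        "ln_age_ln_hdl": 1.769,
        "ln_sbp_treated": 1.797,
        "ln_sbp_untreated": 1.764,
        "smoker": 7.837,
        "ln_age_smoker": -1.795,
        "diabetes": 0.658
      },
      "mean_lp": 61.18,
      "s0_10": 0.9144
    }
  ]
}
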