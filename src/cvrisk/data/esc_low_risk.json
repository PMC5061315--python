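{
  "equation": "esc_score",
  "version": "2003-low-risk",
  "source_citation": "Conroy RM et al., SCORE project: ten-year risk of fatal cardiovascular disease in Europe (low-risk region)",
  "reference_chol_mmoll": 6.0,
  "reference_sbp_mmhg": 120.0,
  "strata": [
    {
      "sex": "male",
      "causes": {
        "chd": {
          "alpha": -22.1,
          "p": 4.71,
          "beta_smoker": 0.71,
          "beta_chol": 0.24,
          "beta_sbp": 0.018
        },
        "non_chd_cvd": {
          "alpha": -26.7,
          "p": 5.64,
          "beta_smoker": 0.63,
          "beta_chol": 0.02,
          "beta_sbp": 0.022
        }
      }
    },
    {
      "sex": "female",
      "causes": {
        "chd": {
          "alpha": -29.8,
          "p": 6.36,
          "beta_smoker": 0.71,
          "beta_chol": 0.24,
          "beta_sbp": 0.018
        },
        "non_chd_cvd": {
          "alpha": -31.0,
          "p": 6.62,
          "beta_smoker": 0.63,
          "beta_chol": 0.02,
          "beta_sbp": 0.022
        }
      }
    }
  ]
}
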