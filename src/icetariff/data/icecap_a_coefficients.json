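{
  "instrument": "ICECAP-A",
  "n": 1373,
  "note": "Published regression coefficients of composite SWB on ICECAP-A level dummies (reference = level 1) and SES controls. Each entry is [coefficient, standard error].",
  "models": {
    "reduced": {
      "intercept": [0.817, 0.010],
      "r_squared": 0.630,
      "levels": {
        "stability":   {"2": [-0.066, 0.012], "3": [-0.178, 0.015], "4": [-0.251, 0.021]},
        "attachment":  {"2": [-0.020, 0.009], "3": [-0.033, 0.013], "4": [-0.079, 0.028]},
        "autonomy":    {"2": [-0.008, 0.008], "3": [-0.014, 0.012], "4": [-0.029, 0.031]},
        "achievement": {"2": [-0.021, 0.011], "3": [-0.080, 0.014], "4": [-0.171, 0.024]},
        "enjoyment":   {"2": [-0.053, 0.010], "3": [-0.144, 0.015], "4": [-0.170, 0.032]}
      },
      "ses": {},
      "constraints": []
    },
    "full": {
      "intercept": [0.710, 0.041],
      "r_squared": 0.656,
      "levels": {
        "stability":   {"2": [-0.059, 0.012], "3": [-0.158, 0.015], "4": [-0.219, 0.022]},
        "attachment":  {"2": [-0.014, 0.009], "3": [-0.024, 0.013], "4": [-0.059, 0.026]},
        "autonomy":    {"2": [-0.008, 0.007], "3": [-0.013, 0.012], "4": [-0.025, 0.030]},
        "achievement": {"2": [-0.017, 0.011], "3": [-0.071, 0.014], "4": [-0.159, 0.024]},
        "enjoyment":   {"2": [-0.055, 0.010], "3": [-0.140, 0.014], "4": [-0.162, 0.031]}
      },
      "ses": {
        "male": [-0.016, 0.007],
        "age": [0.000, 0.002],
        "age_sq": [0.000, 0.000],
        "tertiary": [0.003, 0.007],
        "married": [0.030, 0.008],
        "fin_some_difficulty": [0.033, 0.016],
        "fin_fairly_easy": [0.077, 0.016],
        "fin_easy": [0.094, 0.019],
        "income_month": [0.000, 0.000]
      },
      "constraints": []
    }
  }
}
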