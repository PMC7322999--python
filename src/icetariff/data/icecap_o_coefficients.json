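{
  "instrument": "ICECAP-O",
  "n": 516,
  "note": "Published regression coefficients of composite SWB on ICECAP-O level dummies (reference = level 1) and SES controls. Each entry is [coefficient, standard error].",
  "models": {
    "reduced": {
      "intercept": [0.868, 0.011],
      "r_squared": 0.628,
      "levels": {
        "attachment": {"2": [-0.042, 0.014], "3": [-0.096, 0.019], "4": [-0.188, 0.045]},
        "security":   {"2": [-0.018, 0.014], "3": [-0.083, 0.019], "4": [-0.140, 0.029]},
        "role":       {"2": [0.001, 0.016],  "3": [-0.040, 0.026], "4": [-0.096, 0.061]},
        "enjoyment":  {"2": [-0.062, 0.016], "3": [-0.130, 0.023], "4": [-0.155, 0.052]},
        "control":    {"2": [-0.043, 0.014], "3": [-0.151, 0.024], "4": [-0.146, 0.042]}
      },
      "ses": {},
      "constraints": []
    },
    "full": {
      "intercept": [0.327, 1.251],
      "r_squared": 0.647,
      "levels": {
        "attachment": {"2": [-0.041, 0.014], "3": [-0.090, 0.020], "4": [-0.164, 0.046]},
        "security":   {"2": [-0.016, 0.014], "3": [-0.081, 0.019], "4": [-0.131, 0.029]},
        "role":       {"2": [0.004, 0.016],  "3": [-0.036, 0.025], "4": [-0.097, 0.062]},
        "enjoyment":  {"2": [-0.058, 0.015], "3": [-0.127, 0.023], "4": [-0.134, 0.054]},
        "control":    {"2": [-0.042, 0.014], "3": [-0.143, 0.023], "4": [-0.154, 0.043]}
      },
      "ses": {
        "male": [-0.016, 0.011],
        "age": [0.010, 0.032],
        "age_sq": [-0.000, 0.000],
        "tertiary": [-0.002, 0.011],
        "married": [0.029, 0.012],
        "fin_some_difficulty": [0.062, 0.030],
        "fin_fairly_easy": [0.063, 0.030],
        "fin_easy": [0.097, 0.031],
        "wealth_millions": [0.0002, 0.000]
      },
      "constraints": []
    },
    "constrained": {
      "intercept": [0.321, 1.252],
      "r_squared": null,
      "levels": {
        "attachment": {"2": [-0.040, 0.014], "3": [-0.090, 0.020], "4": [-0.164, 0.046]},
        "security":   {"2": [-0.016, 0.014], "3": [-0.081, 0.019], "4": [-0.131, 0.029]},
        "role":       {"2": [0.000, 0.0],    "3": [-0.039, 0.019], "4": [-0.099, 0.059]},
        "enjoyment":  {"2": [-0.057, 0.013], "3": [-0.126, 0.021], "4": [-0.133, 0.054]},
        "control":    {"2": [-0.041, 0.013], "3": [-0.142, 0.023], "4": [-0.153, 0.043]}
      },
      "ses": {
        "male": [-0.016, 0.011],
        "age": [0.010, 0.032],
        "age_sq": [-0.000, 0.000],
        "tertiary": [-0.002, 0.011],
        "married": [0.029, 0.012],
        "fin_some_difficulty": [0.062, 0.030],
        "fin_fairly_easy": [0.064, 0.030],
        "fin_easy": [0.097, 0.031],
        "wealth_millions": [0.000, 0.000]
      },
      "constraints": [["role", 2, 0.0]]
    }
  }
}
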