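{
  "note": "Published rescaled disutilities on the 0-1 scale (reference = level 1, which carries 0). 'eu' = experienced-utility values; 'du' = decision-utility values with the reference category reversed to level 1. Per dimension: levels 2..4.",
  "ICECAP-O": {
    "eu": {
      "attachment": [-0.059, -0.132, -0.241],
      "security":   [-0.024, -0.119, -0.193],
      "role":       [0.000, -0.057, -0.146],
      "enjoyment":  [-0.083, -0.185, -0.195],
      "control":    [-0.060, -0.209, -0.225]
    },
    "du": {
      "attachment": [-0.021, -0.120, -0.266],
      "security":   [-0.072, -0.113, -0.147],
      "role":       [-0.013, -0.063, -0.177],
      "enjoyment":  [-0.002, -0.048, -0.149],
      "control":    [-0.025, -0.102, -0.261]
    }
  },
  "ICECAP-A": {
    "eu": {
      "stability":   [-0.094, -0.253, -0.351],
      "attachment":  [-0.023, -0.038, -0.095],
      "autonomy":    [-0.013, -0.020, -0.041],
      "achievement": [-0.027, -0.113, -0.255],
      "enjoyment":   [-0.089, -0.224, -0.259]
    },
    "du": {
      "stability":   [-0.031, -0.121, -0.223],
      "attachment":  [-0.039, -0.131, -0.252],
      "autonomy":    [-0.032, -0.105, -0.182],
      "achievement": [-0.022, -0.090, -0.160],
      "enjoyment":   [-0.027, -0.112, -0.184]
    }
  }
}
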