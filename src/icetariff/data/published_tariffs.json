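{
  "note": "Published value sets. 'eu' = experienced-utility tariff (derived from SWB regressions), 'du' = decision-utility tariff (best-worst scaling). Per dimension: utilities of levels 1..4; level 4 anchors at 0 for the EU tariff by construction.",
  "ICECAP-O": {
    "eu": {
      "attachment": [0.241, 0.182, 0.109, 0.0],
      "security":   [0.193, 0.169, 0.074, 0.0],
      "role":       [0.146, 0.146, 0.089, 0.0],
      "enjoyment":  [0.195, 0.112, 0.011, 0.0],
      "control":    [0.225, 0.165, 0.016, 0.0]
    },
    "du": {
      "attachment": [0.2535, 0.2325, 0.1340, -0.0128],
      "security":   [0.1788, 0.1071, 0.0661, 0.0321],
      "role":       [0.1923, 0.1793, 0.1296, 0.0151],
      "enjoyment":  [0.1660, 0.1643, 0.1185, 0.0168],
      "control":    [0.2094, 0.1848, 0.1076, -0.0512]
    }
  },
  "ICECAP-A": {
    "eu": {
      "stability":   [0.351, 0.257, 0.098, 0.0],
      "attachment":  [0.095, 0.072, 0.056, 0.0],
      "autonomy":    [0.041, 0.028, 0.021, 0.0],
      "achievement": [0.255, 0.228, 0.142, 0.0],
      "enjoyment":   [0.259, 0.170, 0.035, 0.0]
    },
    "du": {
      "stability":   [0.2221, 0.1915, 0.1013, -0.0008],
      "attachment":  [0.2276, 0.1890, 0.0964, -0.0239],
      "autonomy":    [0.1881, 0.1560, 0.0836, 0.0063],
      "achievement": [0.1811, 0.1588, 0.0909, 0.0210],
      "enjoyment":   [0.1811, 0.1540, 0.0693, -0.0026]
    }
  }
}
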