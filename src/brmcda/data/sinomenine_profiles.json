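{
  "alone": {
    "effective": {"point": 2.44, "ci_low": 1.87, "ci_high": 3.19, "k": 11},
    "morning_stiffness": {"point": -3.83, "ci_low": -4.87, "ci_high": -2.8, "k": 13},
    "tjc": {"point": -0.95, "ci_low": -1.39, "ci_high": -0.51, "k": 13},
    "sjc": {"point": -1.65, "ci_low": -2.1, "ci_high": -1.19, "k": 13},
    "esr": {"point": -5.15, "ci_low": -7.98, "ci_high": -2.23, "k": 11},
    "rf": {"point": -2.36, "ci_low": -3.25, "ci_high": -1.48, "k": 9},
    "crp": {"point": -2.63, "ci_low": -5.49, "ci_high": -0.24, "k": 8},
    "adverse_rate": {"point": 0.39, "ci_low": 0.21, "ci_high": 0.72, "k": 6},
    "gastrointestinal": {"point": 0.46, "ci_low": 0.19, "ci_high": 1.12, "k": 12},
    "liver": {"point": 0.23, "ci_low": 0.07, "ci_high": 0.73, "k": 6},
    "leucopenia": {"point": 0.51, "ci_low": 0.18, "ci_high": 1.44, "k": 8},
    "skin": {"point": 1.54, "ci_low": 0.61, "ci_high": 3.89, "k": 9},
    "others": {"point": 0.13, "ci_low": 0.04, "ci_high": 0.38, "k": 7}
  },
  "combined": {
    "effective": {"point": 3.7, "ci_low": 2.72, "ci_high": 5.02, "k": 20},
    "morning_stiffness": {"point": -10.51, "ci_low": -12.72, "ci_high": -8.31, "k": 20},
    "tjc": {"point": -0.82, "ci_low": -1.6, "ci_high": -0.03, "k": 17},
    "sjc": {"point": -1.25, "ci_low": -1.98, "ci_high": -0.52, "k": 17},
    "esr": {"point": -6.96, "ci_low": -9.65, "ci_high": -4.27, "k": 26},
    "rf": {"point": -10.18, "ci_low": -16.4, "ci_high": -3.97, "k": 22},
    "crp": {"point": -5.14, "ci_low": -6.63, "ci_high": -3.66, "k": 19},
    "adverse_rate": {"point": 0.62, "ci_low": 0.43, "ci_high": 0.89, "k": 20},
    "gastrointestinal": {"point": 0.61, "ci_low": 0.43, "ci_high": 0.85, "k": 19},
    "liver": {"point": 0.45, "ci_low": 0.26, "ci_high": 0.78, "k": 15},
    "leucopenia": {"point": 0.48, "ci_low": 0.29, "ci_high": 0.78, "k": 17},
    "skin": {"point": 1.4, "ci_low": 0.88, "ci_high": 2.23, "k": 20},
    "others": {"point": 0.47, "ci_low": 0.25, "ci_high": 0.88, "k": 8}
  }
}
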