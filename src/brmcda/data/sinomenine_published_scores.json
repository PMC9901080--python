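{
  "weight_precision": 3,
  "weight_scores": {
    "alone": {
      "effective": 3.456,
      "morning_stiffness": 2.784,
      "tjc": 5.76,
      "sjc": 6.36,
      "esr": 2.496,
      "rf": 1.008,
      "crp": 1.824,
      "adverse_rate": 5.124,
      "gastrointestinal": 2.268,
      "liver": 8.085,
      "leucopenia": 5.145,
      "skin": 0.0,
      "others": 1.827
    },
    "combined": {
      "effective": 6.528,
      "morning_stiffness": 7.776,
      "tjc": 4.92,
      "sjc": 5.04,
      "esr": 3.36,
      "rf": 4.32,
      "crp": 3.504,
      "adverse_rate": 3.192,
      "gastrointestinal": 1.638,
      "liver": 7.035,
      "leucopenia": 5.775,
      "skin": 0.0,
      "others": 1.113
    }
  },
  "totals": {
    "alone": {"benefit_total": 23.4, "risk_total": 22.4, "benefit_value": 39, "risk_value": 56, "overall": 46},
    "combined": {"benefit_total": 35.4, "risk_total": 17.2, "benefit_value": 59, "risk_value": 43, "overall": 53}
  },
  "errata": {
    "alone": {"sjc": 53},
    "combined": {}
  }
}
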