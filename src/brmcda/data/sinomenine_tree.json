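{
  "categories": {"benefit": 0.6, "risk": 0.4},
  "criteria": [
    {"id": "effective", "label": "Total effective rate (%)", "category": "benefit", "measure": "OR", "raw_weight": 80, "best": 5, "worst": 1},
    {"id": "morning_stiffness", "label": "Morning stiffness (min)", "category": "benefit", "measure": "MD", "raw_weight": 80, "best": -13, "worst": 0},
    {"id": "tjc", "label": "Tender joint count", "category": "benefit", "measure": "MD", "raw_weight": 100, "best": -2, "worst": 0},
    {"id": "sjc", "label": "Swollen joint count", "category": "benefit", "measure": "MD", "raw_weight": 100, "best": -3, "worst": 0},
    {"id": "esr", "label": "Erythrocyte sedimentation rate (mm/h)", "category": "benefit", "measure": "MD", "raw_weight": 40, "best": -10, "worst": 0},
    {"id": "rf", "label": "Rheumatoid factor (IU/ml)", "category": "benefit", "measure": "MD", "raw_weight": 60, "best": -17, "worst": 0},
    {"id": "crp", "label": "C-reactive protein (mg/L)", "category": "benefit", "measure": "MD", "raw_weight": 40, "best": -7, "worst": 0},
    {"id": "adverse_rate", "label": "Overall adverse-effect rate (%)", "category": "risk", "measure": "OR", "raw_weight": 80, "best": 0, "worst": 1},
    {"id": "gastrointestinal", "label": "Gastrointestinal reactions (%)", "category": "risk", "measure": "OR", "raw_weight": 40, "best": 0, "worst": 1},
    {"id": "liver", "label": "Liver function impairment (%)", "category": "risk", "measure": "OR", "raw_weight": 100, "best": 0, "worst": 1},
    {"id": "leucopenia", "label": "Leucopenia (%)", "category": "risk", "measure": "OR", "raw_weight": 100, "best": 0, "worst": 1},
    {"id": "skin", "label": "Skin lesions (%)", "category": "risk", "measure": "OR", "raw_weight": 40, "best": 0, "worst": 1},
    {"id": "others", "label": "Other adverse reactions (%)", "category": "risk", "measure": "OR", "raw_weight": 20, "best": 0, "worst": 1}
  ]
}
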