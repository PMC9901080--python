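# Full-pipeline config: the shipped sinomenine assessment end to end.
tree: sinomenine
regimens:
  - id: alone
    builtin: alone
  - id: combined
    builtin: combined
# reproduce the published table arithmetic: 0.1-percentage-point
# relative weights and the documented errata overrides
weight_precision: 3
preference_overrides: builtin
mc:
  iterations: 30000
  seed: 1
  ci_level: 0.95
sensitivity:
  fraction: 0.2
  grid_step: 0.01
out_dir: brmcda_out
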