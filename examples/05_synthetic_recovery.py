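"""End-to-end pipeline check on synthetic trials with known truth.

Generates trial-level data whose true effects equal the combination
regimen's pooled points (no between-trial heterogeneity), pools them
per indicator, scores the recovered profile, and compares the category
values with those implied by the generating truth.
"""

import math

from brmcda.datasets import sinomenine_example
from brmcda.pipeline import pool_profile
from brmcda.synth import SyntheticSpec, gen_regimen_scenario
from brmcda.value import score_profile

ex = sinomenine_example()
control_rates = {"effective": 0.65, "adverse_rate": 0.15, "gastrointestinal": 0.10,
                 "liver": 0.06, "leucopenia": 0.06, "skin": 0.05, "others": 0.05}
sd_within = {"morning_stiffness": 25.0, "tjc": 3.0, "sjc": 3.0,
             "esr": 10.0, "rf": 15.0, "crp": 8.0}

specs = {}
for c in ex.tree.criteria:
    point = ex.combined.measurement(c.id).point
    if c.measure == "OR":
        specs[c.id] = SyntheticSpec(indicator_id=c.id, measure="OR",
                                    true_effect=math.log(point), k_trials=20,
                                    n_per_arm=(200, 400),
                                    control_rate=control_rates[c.id])
    else:
        specs[c.id] = SyntheticSpec(indicator_id=c.id, measure="MD",
                                    true_effect=point, k_trials=20,
                                    n_per_arm=(200, 400), sd_within=sd_within[c.id])

scenario = gen_regimen_scenario(ex.tree, specs, seed=42)
trials = [t for ts in scenario.values() for t in ts]
profile, effects = pool_profile("synthetic_combined", trials, ex.tree)

print(f"generated {len(trials)} trials across {len(effects)} indicators")
truth = score_profile(ex.combined, ex.tree).reported()
recovered = score_profile(profile, ex.tree).reported()
print(f"{'':<16}{'truth':>8}{'recovered':>11}")
for key in ("benefit_value", "risk_value", "overall"):
    print(f"{key:<16}{truth[key]:>8}{recovered[key]:>11}")

print("""
With 20 trials of 200-400 patients per arm and no heterogeneity, the
pooled-and-scored category values land on (or within a point or two
of) the values implied by the generating truth.""")
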