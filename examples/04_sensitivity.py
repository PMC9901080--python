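"""How robust is the ranking to the benefit/risk weight split?

Solves the crossover benefit weight in closed form from the reported
category values, checks stability under a 20% relative perturbation of
the 60/40 split, and sweeps each criterion's raw SWING weight for
single-criterion flip thresholds.
"""

from brmcda.datasets import sinomenine_example
from brmcda.sensitivity import sensitivity_report

ex = sinomenine_example()
rep = sensitivity_report(
    ex.tree, ex.alone, ex.combined,
    fraction=0.20, grid_step=0.01,
    overrides=(ex.errata.get("alone"), ex.errata.get("combined")),
    weight_precision=ex.weight_precision,
)

print(f"ranking at 60/40 split : {' > '.join(rep.ranking_at_default)}")
print(f"crossover benefit weight: {rep.crossover_weight:.4f} ({rep.crossover_reason})")
print(f"stable under +/-20%     : {rep.stable_under_20pct}")
print("\nsingle-criterion weight multipliers at which the ranking flips:")
for cid, flip in rep.one_way.items():
    print(f"  {cid:<20} {'never (within 0-5x)' if flip is None else f'{flip:.2f}x'}")

print("""
The combination leads as long as the benefit weight stays above ~0.39;
the default 0.60 sits well clear of the crossover, so a 20% relative
perturbation (0.48-0.72) cannot change the ranking.""")
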