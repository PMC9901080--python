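"""Propagate pooled-effect uncertainty into score-difference intervals.

Each criterion's pooled effect is sampled (log-normal for odds ratios,
normal for mean differences) with the SE back-derived from its 95% CI;
both regimens are rescored each iteration with continuous partial
values.  Prints percentile intervals of the combined-minus-alone
differences and the exceedance probability.
"""

from brmcda.datasets import sinomenine_example
from brmcda.montecarlo import MCConfig, mc_compare

ex = sinomenine_example()
res = mc_compare(ex.alone, ex.combined, ex.tree, MCConfig(iterations=30_000, seed=1))

for name, diff in (
    ("benefit value", res.benefit_diff),
    ("risk value", res.risk_diff),
    ("overall score", res.overall_diff),
):
    print(f"{name:<14} difference {diff.point:6.2f}  "
          f"95% CI ({diff.ci_low:6.2f}, {diff.ci_high:6.2f})")
print(f"\nP(combined overall > alone overall) = {res.p_superior:.3f}")

print("""
Positive differences favour the combination regimen.  The benefit gain
is clearly positive, the risk difference is uncertain in sign, and the
combination's overall score is higher in ~88% of iterations.""")
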