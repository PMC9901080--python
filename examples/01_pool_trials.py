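"""Pool a handful of two-arm trial summaries into effect estimates.

Builds three small dichotomous trials and two continuous ones, pools
them with the Mantel-Haenszel and inverse-variance methods, and prints
the pooled effects with their 95% CIs and heterogeneity statistics.
"""

from brmcda import TrialSummary, pool_md_iv, pool_or_mh

dichotomous = [
    TrialSummary("zhang1999", "effective", "dichotomous",
                 events_trt=28, n_trt=40, events_ctl=18, n_ctl=38),
    TrialSummary("li2004", "effective", "dichotomous",
                 events_trt=45, n_trt=60, events_ctl=30, n_ctl=55),
    TrialSummary("wang2011", "effective", "dichotomous",
                 events_trt=33, n_trt=45, events_ctl=25, n_ctl=47),
]

continuous = [
    TrialSummary("zhang1999", "esr", "continuous", n_trt=40, n_ctl=38,
                 mean_trt=22.1, sd_trt=9.5, mean_ctl=28.4, sd_ctl=10.2),
    TrialSummary("li2004", "esr", "continuous", n_trt=60, n_ctl=55,
                 mean_trt=20.6, sd_trt=8.1, mean_ctl=26.0, sd_ctl=9.0),
]

e = pool_or_mh(dichotomous)
print(f"effective rate, {e.k_studies} trials (Mantel-Haenszel, {e.model}):")
print(f"  OR = {e.point:.2f}  95% CI ({e.ci_low:.2f}, {e.ci_high:.2f})"
      f"  I2 = {e.i2:.0f}%  tau2 = {e.tau2:.3f}")

m = pool_md_iv(continuous)
print(f"ESR, {m.k_studies} trials (inverse variance, {m.model}):")
print(f"  MD = {m.point:.2f} mm/h  95% CI ({m.ci_low:.2f}, {m.ci_high:.2f})")

print()
print("An OR above 1 favours the treated arm for a desirable event;")
print("a negative MD means a larger reduction than the control arm.")
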