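# Methods

## The decision model

The package implements a weighted additive multicriteria decision
analysis (MCDA) for comparing two drug regimens on a two-level value
tree. The shipped tree is the sinomenine-for-rheumatoid-arthritis
assessment: 7 benefit criteria (total effective rate as an odds ratio;
morning stiffness, tender and swollen joint counts, ESR, RF and CRP as
mean differences) and 6 risk criteria (overall adverse-effect rate,
gastrointestinal reactions, liver impairment, leucopenia, skin lesions
and other adverse reactions, all odds ratios), with the benefit
category weighted 0.60 and risk 0.40.

**Partial values.** Each criterion carries a best anchor (preference
100) and a worst anchor (preference 0); a measurement `x` maps to
`v = 100·(x − worst)/(best − worst)`, clamped to [0, 100]. Direction is
implicit in the anchors: for harms the best anchor (OR 0) lies below
the worst (OR 1), so smaller odds ratios score higher. Odds ratios
enter on the natural scale with the null value 1 serving as the worst
anchor of the benefit OR; mean differences enter signed, in native
units. These are the only anchor conventions under which the shipped
tree reproduces its published scoring table.

**Swing weights.** Raw SWING scores (most important swing = 100) are
normalized within each category: `relative_weight = raw/Σraw ×
category weight`, so relative weights sum to the category weight and to
1 overall. A profile at all best anchors therefore scores exactly 100
and at all worst anchors exactly 0.

**Scoring and rounding.** The deterministic reporting path rounds each
preference half-away-from-zero to an integer before weighting (47.5 →
48, 67.5 → 68); weight scores are `preference × relative_weight`;
category totals are rescaled by the category weights onto 0–100
category values; the overall score is the sum of the two category
totals. Category values and the overall score are rounded to integers
at presentation only — internal arithmetic is full precision, so
`0.6·BV + 0.4·RV = overall` holds exactly pre-rounding.

## Reproducing the published scoring table

Two reproduction details are surfaced as explicit, documented options
rather than baked in:

- **Weight precision.** The published table carries relative weights at
  0.1-percentage-point precision (8.40%, 10.50%, …; within the risk
  category they sum to 39.9%, not 40%). `score_profile(...,
  weight_precision=3)` mirrors that truncation and is required to
  reproduce the published cells bit-exactly. The default
  (`weight_precision=None`) uses exact normalized weights; the reported
  integer category values (39/59, 56/43, 46/53) are identical under
  both, so the knob only matters at cell level.
- **Errata overrides.** Three published cells are inconsistent with
  their own pooled effects under the stated rules: the monotherapy
  swollen-joint-count cell (printed 6.36 ⇒ preference 53, but the
  pooled MD −1.65 gives 55 ⇒ 6.60), and the combination liver /
  leucopenia cells (printed 7.035 / 5.775, but the pooled ORs 0.45 /
  0.48 give 5.775 / 5.460 — the printed leucopenia cell equals the
  recomputed liver cell, suggesting a shift). The published *totals*
  side with the recomputation for the combination risk column, so those
  two cells are left recomputed; for the swollen-joint cell the
  published preference is carried as an override
  (`preference_overrides`) because the published benefit total and
  headline benefit value 39 are only reproducible with it. The
  published monotherapy benefit total row (23.4) is additionally
  inconsistent with the sum of its own printed cells (23.688); the
  package always reports the sum of its cells.

## Meta-analysis

Dichotomous outcomes are pooled as Mantel-Haenszel odds ratios with the
Robins-Breslow-Greenland variance of the log pooled OR. Trials with a
zero cell get 0.5 added to all four cells; trials with zero (or all)
events in both arms are non-informative for the OR and are excluded.
Continuous outcomes are pooled as inverse-variance mean differences
with per-trial variance `sd_t²/n_t + sd_c²/n_c`. Heterogeneity is
summarized by Cochran's Q, `I² = max(0, (Q − df)/Q)·100` and the
DerSimonian-Laird moment estimate `τ² = max(0, (Q − (k−1))/C)`,
`C = Σw − Σw²/Σw`. The model choice is per indicator: fixed effect by
default, explicit `random`, or `auto` (switch to DL random effects when
I² > 50%). Odds ratios are pooled and sampled on the log scale and
reported on the natural scale. All CIs use the frozen quantile
z = 1.959964 for bit-stable output. The pooling routines agree with
r-metafor (`rma.mh`, `rma`) to 1e-9 on the fixtures frozen in the test
suite.

Confidence intervals are the only uncertainty carrier in published
pooled tables, so SEs are back-derived: `SE = (ln hi − ln lo)/(2z)` for
OR (log scale), `(hi − lo)/(2z)` for MD.

## Monte Carlo uncertainty propagation

Each iteration draws every criterion's measurement independently —
log-normal about the pooled log OR, normal about the pooled MD, with
the CI-derived SE — and rescores both regimens with *continuous*
partial values: integer preference rounding is disabled inside the loop
to avoid lattice artifacts in the difference distributions (the
deterministic reporting path keeps it). Summaries are percentile
intervals at the configured level and the exceedance probability
`P(overall_B > overall_A)` (strict; a profile compared against itself
is the same uncertain quantity on both sides and yields identically
zero differences). Criteria are sampled independently; no correlation
structure is modelled because none is available from pooled summaries —
a limitation, since correlated benefits would widen the difference
intervals. Defaults: 30,000 iterations, 95% percentile intervals,
seeded `numpy` Generator (bit-identical results per seed).

The `point` fields of a Monte Carlo result are the *continuous*
deterministic differences (all SEs collapsed to zero), so the interval
invariants survive the zero-variance collapse; the integer headline
differences (+20 benefit, −13 risk, +7 overall for the shipped data)
come from the deterministic reporting path and differ slightly (19.1 /
−13.2 / 6.2) because of preference rounding and clamping. Reproduction
of published simulation intervals is best-effort only — the original
tool's assumption cells are not documented — and the package treats the
exceedance probability as the robust simulated quantity (~0.878 at
30,000 iterations across seeds).

## Weight sensitivity

With additive scoring the overall score at benefit weight `w` is
`w·BV + (1−w)·RV`, so the crossover weight solves
`w·BV_A + (1−w)·RV_A = w·BV_B + (1−w)·RV_B` in closed form; grids are
used only for one-way single-criterion sweeps (default step 0.001,
multiplier range (0, 5]). Exchanging regimens leaves the crossover
invariant; "identical" and "dominance" are distinguished reason codes.
For the shipped data (benefit 39 vs 59, risk 56 vs 43) the crossover is
13/33 ≈ 0.394, comfortably below the default 0.60.

The headline stability rule — "the ranking must survive a 20% change of
the benefit weight" — is interpreted as a *relative* change (0.60 →
0.48 / 0.72) with risk absorbing the complement; an absolute
percentage-point reading (0.60 → 0.40) would be a 33% relative change
and is obtainable by passing `fraction=1/3`. The crossover-implied
critical fraction for the shipped data is (0.60 − 0.394)/0.60 ≈ 0.343,
so the 20% perturbation cannot flip the ranking; the bracketing
property (stable just below the critical fraction, unstable just above)
is checked programmatically.

## Synthetic trial generator

The generator emulates what a systematic review extracts from two-arm
RCTs. Per trial: a true effect `θᵢ ~ Normal(true_effect, τ²)` on the
log-OR or MD scale (additive normal random effect, matching the DL
model being tested); arm sizes uniform on a configurable range;
dichotomous arms draw binomial event counts with
`p_trt = expit(logit(p_ctl) + θᵢ)`; continuous arms simulate individual
normal responses and report the sample mean and sample SD (summary
statistics therefore carry realistic noise rather than plugging in
population values). All generation is driven by a single seeded
Generator.

Study conditions used in the recovery tests mirror the shipped
assessment's scale where it states one and otherwise use values typical
of the underlying trial literature: true effects set to the pooled
points (e.g. OR 2.44, MD −10.51), τ² = 0, k = 30 trials, 200–500
patients per arm, control-arm response rate 0.65 for efficacy and
0.05–0.15 for adverse events, within-arm SDs of 3–25 in the indicators'
native units. Recovery is asserted within 3 Monte-Carlo standard errors
over 200 replicates, and a full synthetic end-to-end run must land the
reported category values within ±2 of those implied by the truth.
What these tests show is internal consistency (generator → pooling →
scoring is unbiased at realistic sizes); they do not validate the
generator against real trial heterogeneity, publication bias, or
correlated outcomes, none of which are simulated.

## Numerical conventions and degenerate inputs

- z-quantile frozen at 1.959964; preference rounding half-away-from-
  zero after snapping to 9 decimals (so binary noise cannot flip an
  exact .5 tie); floating output serialized at 6 significant digits.
- Pooling a single study returns that study's effect and CI exactly
  (the RBG variance collapses to the Woolf variance).
- Degenerate CIs (lo = hi) give SE 0; SE 0 measurements are sampled as
  constants; an all-zero-margin set of 2×2 tables raises as
  inestimable; τ² estimation requires k ≥ 2 and truncates negative
  moments to 0.
- Pipeline bundles are byte-identical across reruns with the same
  config and seed.

## Known limitations

- Percentile intervals only; no bias-corrected bootstrap variants.
- No correlation model between criteria in the Monte Carlo stage (hook
  reserved in the config schema).
- The value functions are linear-clamped; no nonlinear utility
  families.
- One-way sweeps renormalize siblings proportionally; joint
  multi-criterion weight perturbations (SMAA-style acceptability
  analysis) are deliberately out of scope.
- The shipped pooled effects are transcriptions of a published summary
  table; the underlying 44 RCTs' raw data are not publicly deposited,
  so trial-level reanalysis of the real data is not possible here.
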