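"""Synthetic two-arm RCT summary data with known ground truth.

Emulates the summary statistics a systematic review extracts from
randomized trials: per trial, a true effect is drawn about the
indicator's true log odds ratio or mean difference (with optional
between-trial heterogeneity tau^2 on that scale), arm sizes are drawn
uniformly from a range, and arm-level outcomes are simulated —
binomial event counts for dichotomous indicators, individual normal
responses reduced to mean/SD/n for continuous indicators (so reported
SDs carry realistic sampling noise).  Everything is seeded, so the
full pipeline (pooling, scoring, Monte Carlo) is testable end to end
against the generating truth without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.special import expit, logit

from .meta import TrialSummary

__all__ = [
    "SyntheticSpec",
    "gen_dichotomous_trials",
    "gen_continuous_trials",
    "gen_regimen_scenario",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generating truth for one indicator's batch of trials.

    ``true_effect`` is the log odds ratio for dichotomous indicators
    and the mean difference (in the indicator's units) for continuous
    ones; ``tau2`` is the between-trial variance on that same scale.
    ``n_per_arm`` bounds the uniform draw of each arm's size.
    """

    indicator_id: str
    measure: str  # "OR" | "MD"
    true_effect: float
    k_trials: int
    n_per_arm: tuple[int, int]
    tau2: float = 0.0
    control_rate: float | None = None  # dichotomous only
    sd_within: float | None = None  # continuous only
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.measure not in ("OR", "MD"):
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.k_trials < 1:
            raise ValueError("k_trials must be >= 1")
        lo, hi = self.n_per_arm
        if lo < 2 or hi < lo:
            raise ValueError("n_per_arm bounds must satisfy 2 <= lo <= hi")
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")


def _rng(spec: SyntheticSpec, rng=None):
    if rng is not None:
        return rng
    return np.random.default_rng(spec.seed)


def gen_dichotomous_trials(spec: SyntheticSpec, rng=None) -> list[TrialSummary]:
    """Simulate dichotomous trial summaries for one indicator.

    Control events are Binomial(n, control_rate); treatment events are
    Binomial(n, expit(logit(control_rate) + theta_i)) with the trial
    effect theta_i ~ Normal(true_effect, tau2) on the log-odds scale.
    """
    if spec.measure != "OR":
        raise ValueError("gen_dichotomous_trials needs a dichotomous (OR) spec")
    if spec.control_rate is None or not 0.0 < spec.control_rate < 1.0:
        raise ValueError("control_rate must lie in (0, 1)")
    rng = _rng(spec, rng)
    lo, hi = spec.n_per_arm
    trials = []
    for i in range(spec.k_trials):
        theta = rng.normal(spec.true_effect, np.sqrt(spec.tau2))
        n_trt = int(rng.integers(lo, hi + 1))
        n_ctl = int(rng.integers(lo, hi + 1))
        p_ctl = spec.control_rate
        p_trt = float(expit(logit(p_ctl) + theta))
        trials.append(
            TrialSummary(
                trial_id=f"{spec.indicator_id}_{i + 1:03d}",
                indicator_id=spec.indicator_id,
                design="dichotomous",
                events_trt=int(rng.binomial(n_trt, p_trt)),
                n_trt=n_trt,
                events_ctl=int(rng.binomial(n_ctl, p_ctl)),
                n_ctl=n_ctl,
            )
        )
    return trials


def gen_continuous_trials(spec: SyntheticSpec, rng=None) -> list[TrialSummary]:
    """Simulate continuous trial summaries for one indicator.

    Individual responses are Normal(0, sd_within) in the control arm
    and Normal(theta_i, sd_within) in the treatment arm; summaries
    report the sample mean and sample SD per arm.
    """
    if spec.measure != "MD":
        raise ValueError("gen_continuous_trials needs a continuous (MD) spec")
    if spec.sd_within is None or spec.sd_within <= 0:
        raise ValueError("sd_within must be > 0")
    rng = _rng(spec, rng)
    lo, hi = spec.n_per_arm
    trials = []
    for i in range(spec.k_trials):
        theta = rng.normal(spec.true_effect, np.sqrt(spec.tau2))
        n_trt = int(rng.integers(lo, hi + 1))
        n_ctl = int(rng.integers(lo, hi + 1))
        y_trt = rng.normal(theta, spec.sd_within, size=n_trt)
        y_ctl = rng.normal(0.0, spec.sd_within, size=n_ctl)
        trials.append(
            TrialSummary(
                trial_id=f"{spec.indicator_id}_{i + 1:03d}",
                indicator_id=spec.indicator_id,
                design="continuous",
                n_trt=n_trt,
                n_ctl=n_ctl,
                mean_trt=float(y_trt.mean()),
                sd_trt=float(y_trt.std(ddof=1)),
                mean_ctl=float(y_ctl.mean()),
                sd_ctl=float(y_ctl.std(ddof=1)),
            )
        )
    return trials


def gen_trials(spec: SyntheticSpec, rng=None) -> list[TrialSummary]:
    """Dispatch on the spec's measure."""
    if spec.measure == "OR":
        return gen_dichotomous_trials(spec, rng)
    return gen_continuous_trials(spec, rng)


def gen_regimen_scenario(
    tree, effects: Mapping[str, SyntheticSpec], seed: int | None = None
) -> dict[str, list[TrialSummary]]:
    """Generate trials for every criterion of a value tree.

    ``effects`` maps criterion id -> SyntheticSpec; exactly one spec
    per tree criterion is required.  A single seeded generator drives
    all indicators, so the whole scenario is reproducible from one
    seed (per-spec seeds are ignored when ``seed`` is given).
    """
    tree_ids = {c.id for c in tree.criteria}
    if set(effects) != tree_ids:
        missing = sorted(tree_ids - set(effects))
        extra = sorted(set(effects) - tree_ids)
        raise ValueError(f"scenario specs must cover the tree: missing={missing} extra={extra}")
    rng = np.random.default_rng(seed) if seed is not None else None
    out: dict[str, list[TrialSummary]] = {}
    for c in tree.criteria:
        spec = effects[c.id]
        if spec.measure != c.measure:
            raise ValueError(
                f"criterion {c.id!r} is {c.measure} but spec is {spec.measure}"
            )
        out[c.id] = gen_trials(spec, rng)
    return out
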