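"""Monte Carlo propagation of pooled-effect uncertainty through the value model.

Each iteration draws every criterion's measurement independently —
normal on the mean-difference scale, log-normal on the odds-ratio
scale, parameterized by the pooled point and the standard error
back-derived from its 95% CI — scores both regimens with *continuous*
partial values (integer preference rounding is disabled inside the
loop to avoid lattice artifacts), and records the benefit-value,
risk-value and overall score differences.  Summaries are percentile
confidence intervals and the exceedance probability
P(regimen B's overall score > regimen A's).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .value import PerformanceProfile, ValueTree, normalize_swing_weights, score_profile

__all__ = ["MCConfig", "DiffSummary", "MCResult", "sample_measurement", "mc_compare"]


@dataclass(frozen=True)
class MCConfig:
    """Simulation settings: iteration count, RNG seed, CI level."""

    iterations: int = 30_000
    seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")


@dataclass(frozen=True)
class DiffSummary:
    """One score-difference distribution (B minus A).

    ``point`` is the deterministic difference (all SEs collapsed to 0,
    continuous preferences); ``ci_low``/``ci_high`` are percentile
    bounds of the sampled distribution.
    """

    point: float
    ci_low: float
    ci_high: float
    samples: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {"point": self.point, "ci_low": self.ci_low, "ci_high": self.ci_high}


@dataclass(frozen=True)
class MCResult:
    benefit_diff: DiffSummary
    risk_diff: DiffSummary
    overall_diff: DiffSummary
    p_superior: float
    config: MCConfig

    def to_dict(self) -> dict:
        return {
            "benefit_diff": self.benefit_diff.to_dict(),
            "risk_diff": self.risk_diff.to_dict(),
            "overall_diff": self.overall_diff.to_dict(),
            "p_superior": self.p_superior,
            "iterations": self.config.iterations,
            "seed": self.config.seed,
            "ci_level": self.config.ci_level,
        }


def sample_measurement(point: float, se: float, measure: str, rng, size=None):
    """Draw measurement(s): Normal for MD, log-normal for OR.

    ``se`` is on the sampling scale (log scale for OR); ``se=0``
    returns the point exactly.
    """
    if se < 0:
        raise ValueError("standard error must be >= 0")
    if measure not in ("OR", "MD"):
        raise ValueError(f"unknown measure {measure!r}")
    if measure == "OR" and point <= 0:
        raise ValueError("odds-ratio point must be > 0")
    if se == 0:
        return point if size is None else np.full(size, float(point))
    if measure == "MD":
        return rng.normal(point, se, size=size)
    return np.exp(rng.normal(np.log(point), se, size=size))


def _sampled_values(
    profile: PerformanceProfile, tree: ValueTree, rng, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """(benefit_value, risk_value) arrays of length n for one profile."""
    benefit = np.zeros(n)
    risk = np.zeros(n)
    for c in tree.criteria:
        m = profile.measurement(c.id)
        x = sample_measurement(m.point, m.se, c.measure, rng, size=n)
        pref = np.clip(100.0 * (x - c.worst) / (c.best - c.worst), 0.0, 100.0)
        if c.category == "benefit":
            benefit += c.relative_weight * pref
        else:
            risk += c.relative_weight * pref
    w_b = tree.category_weights["benefit"]
    w_r = tree.category_weights["risk"]
    return benefit / w_b, risk / w_r


def mc_compare(
    profile_a: PerformanceProfile,
    profile_b: PerformanceProfile,
    tree: ValueTree,
    cfg: MCConfig,
) -> MCResult:
    """Compare two regimens under sampled measurement uncertainty.

    Draws all measurements of both profiles independently each
    iteration, scores both through the tree with continuous partial
    values, and summarizes the B−A differences of benefit value, risk
    value and overall score.  ``p_superior`` is the fraction of
    iterations in which B's overall score strictly exceeds A's.
    Bit-identical results for identical configs (seeded RNG).
    """
    if not tree.is_normalized:
        tree = normalize_swing_weights(tree)
    profile_a.require_complete(tree)
    profile_b.require_complete(tree)
    w_b = tree.category_weights["benefit"]
    w_r = tree.category_weights["risk"]

    rng = np.random.default_rng(cfg.seed)
    bv_a, rv_a = _sampled_values(profile_a, tree, rng, cfg.iterations)
    if profile_b is profile_a:
        # a profile compared against itself is the same uncertain
        # quantity on both sides: the difference is identically zero
        bv_b, rv_b = bv_a, rv_a
    else:
        bv_b, rv_b = _sampled_values(profile_b, tree, rng, cfg.iterations)
    ov_a = w_b * bv_a + w_r * rv_a
    ov_b = w_b * bv_b + w_r * rv_b

    # deterministic reference point: continuous preferences, no sampling
    det_a = score_profile(profile_a, tree, integer_preferences=False)
    det_b = score_profile(profile_b, tree, integer_preferences=False)

    alpha = (1.0 - cfg.ci_level) / 2.0

    def summarize(samples: np.ndarray, point: float) -> DiffSummary:
        lo, hi = np.quantile(samples, [alpha, 1.0 - alpha])
        return DiffSummary(point=point, ci_low=float(lo), ci_high=float(hi), samples=samples)

    return MCResult(
        benefit_diff=summarize(bv_b - bv_a, det_b.benefit_value - det_a.benefit_value),
        risk_diff=summarize(rv_b - rv_a, det_b.risk_value - det_a.risk_value),
        overall_diff=summarize(ov_b - ov_a, det_b.overall - det_a.overall),
        p_superior=float(np.mean(ov_b > ov_a)),
        config=cfg,
    )
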