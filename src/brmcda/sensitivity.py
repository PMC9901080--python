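"""Weight-sensitivity analysis for the two-regimen comparison.

With linear additive scoring, the overall score at benefit weight w is
w*bv + (1-w)*rv, so the benefit/risk split at which two regimens'
overall scores coincide — the crossover weight — has a closed form.
On one side of the crossover the ranking flips; a ranking robust to a
stated relative perturbation of the default split is called stable.
One-way sweeps perturb a single criterion's raw SWING weight instead,
renormalizing its siblings so category weights are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .value import (
    PerformanceProfile,
    ValueTree,
    normalize_swing_weights,
    partial_value,
    score_profile,
)

__all__ = [
    "CrossoverResult",
    "SensitivityReport",
    "crossover_weight",
    "perturb_stability",
    "one_way_weight_sweep",
    "sensitivity_report",
]


@dataclass(frozen=True)
class CrossoverResult:
    """Crossover benefit weight, or the reason none exists.

    ``reason`` is "crossover" (weight in [0, 1]), "identical" (the two
    regimens have equal category values everywhere, every weight ties),
    or "dominance" (one regimen wins at every admissible weight).
    """

    weight: float | None
    reason: str


def crossover_weight(
    bv_a: float, rv_a: float, bv_b: float, rv_b: float
) -> CrossoverResult:
    """Solve w*bv_a + (1-w)*rv_a = w*bv_b + (1-w)*rv_b for w in [0, 1].

    Category values are on the 0-100 scale.  Exchanging the two
    regimens leaves the solution unchanged.
    """
    d_b = bv_a - bv_b
    d_r = rv_a - rv_b
    if d_b == 0 and d_r == 0:
        return CrossoverResult(weight=None, reason="identical")
    if d_b == d_r:
        # parallel lines: same gap at every weight, never crosses
        return CrossoverResult(weight=None, reason="dominance")
    w = d_r / (d_r - d_b)
    if 0.0 <= w <= 1.0:
        return CrossoverResult(weight=float(w), reason="crossover")
    return CrossoverResult(weight=None, reason="dominance")


def _pair_overrides(
    overrides: Sequence[Mapping[str, float] | None] | None,
) -> tuple[Mapping[str, float] | None, Mapping[str, float] | None]:
    if overrides is None:
        return None, None
    if len(overrides) != 2:
        raise ValueError("preference_overrides must align with the two profiles")
    return overrides[0], overrides[1]


def _category_values(
    tree: ValueTree,
    profiles: Sequence[PerformanceProfile],
    overrides: Sequence[Mapping[str, float] | None] | None = None,
    **score_kwargs,
) -> list[tuple[float, float]]:
    ov = _pair_overrides(overrides)
    out = []
    for p, o in zip(profiles, ov):
        s = score_profile(p, tree, preference_overrides=o, **score_kwargs)
        out.append((s.benefit_value, s.risk_value))
    return out


def perturb_stability(
    tree: ValueTree,
    profiles: Sequence[PerformanceProfile],
    fraction: float,
    overrides: Sequence[Mapping[str, float] | None] | None = None,
    **score_kwargs,
) -> bool:
    """Is the regimen ranking unchanged under a +/-``fraction`` relative
    change of the benefit category weight (risk absorbing the complement)?

    Rescoring is deterministic; the ranking at both extremes is
    compared with the ranking at the default split.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    if len(profiles) != 2:
        raise ValueError("perturb_stability compares exactly two profiles")
    if not tree.is_normalized:
        tree = normalize_swing_weights(tree)
    (bv_a, rv_a), (bv_b, rv_b) = _category_values(
        tree, profiles, overrides, **score_kwargs
    )
    w0 = tree.category_weights["benefit"]

    def sign_at(w: float) -> int:
        w = min(1.0, max(0.0, w))
        gap = (w * bv_b + (1 - w) * rv_b) - (w * bv_a + (1 - w) * rv_a)
        return (gap > 0) - (gap < 0)

    base = sign_at(w0)
    return sign_at(w0 * (1 - fraction)) == base and sign_at(w0 * (1 + fraction)) == base


def one_way_weight_sweep(
    tree: ValueTree,
    profiles: Sequence[PerformanceProfile],
    criterion_id: str,
    grid_step: float = 0.001,
    max_multiplier: float = 5.0,
    overrides: Sequence[Mapping[str, float] | None] | None = None,
    integer_preferences: bool = True,
    weight_precision: int | None = None,
) -> float | None:
    """Sweep one criterion's raw weight over a multiplicative grid.

    Siblings within the category are renormalized proportionally so the
    category weight is preserved.  Returns the grid multiplier closest
    to 1 at which the overall ranking flips relative to the unperturbed
    tree, or None if the ranking never flips on (0, max_multiplier].
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    if len(profiles) != 2:
        raise ValueError("one_way_weight_sweep compares exactly two profiles")
    if not tree.is_normalized:
        tree = normalize_swing_weights(tree)
    target = tree.criterion(criterion_id)  # KeyError for unknown ids
    cat = target.category
    members = tree.in_category(cat)
    w_cat = tree.category_weights[cat]
    other_cat = "risk" if cat == "benefit" else "benefit"
    ov = _pair_overrides(overrides)

    prefs = []  # per profile: preference of every category member
    fixed = []  # per profile: contribution of the untouched category
    for p, o in zip(profiles, ov):
        p.require_complete(tree)
        o = o or {}
        pv = {
            c.id: float(o[c.id])
            if c.id in o
            else partial_value(
                p.measurement(c.id).point, c, integer=integer_preferences
            )
            for c in members
        }
        prefs.append(pv)
        s = score_profile(
            p,
            tree,
            integer_preferences=integer_preferences,
            weight_precision=weight_precision,
            preference_overrides=o or None,
        )
        fixed.append(s.benefit_total if other_cat == "benefit" else s.risk_total)

    sib_raw = np.array([c.raw_weight for c in members if c.id != criterion_id])
    r_j = target.raw_weight
    m = np.arange(grid_step, max_multiplier + grid_step / 2, grid_step)

    def overall(i: int) -> np.ndarray:
        pv = prefs[i]
        sib_prefs = np.array([pv[c.id] for c in members if c.id != criterion_id])
        num = sib_raw @ sib_prefs + m * r_j * pv[criterion_id]
        den = sib_raw.sum() + m * r_j
        return fixed[i] + w_cat * num / den

    gap = overall(1) - overall(0)
    base_idx = int(np.argmin(np.abs(m - 1.0)))
    base_sign = np.sign(gap[base_idx])
    flipped = np.sign(gap) != base_sign
    if not flipped.any():
        return None
    idx = np.nonzero(flipped)[0]
    return float(m[idx[np.argmin(np.abs(m[idx] - 1.0))]])


@dataclass(frozen=True)
class SensitivityReport:
    """Crossover, default ranking, perturbation verdict, one-way flips."""

    crossover_weight: float | None
    crossover_reason: str
    ranking_at_default: tuple[str, ...]
    stable_under_20pct: bool
    fraction: float
    one_way: Mapping[str, float | None]

    def to_dict(self) -> dict:
        return {
            "crossover_weight": self.crossover_weight,
            "crossover_reason": self.crossover_reason,
            "ranking_at_default": list(self.ranking_at_default),
            "stable_under_20pct": self.stable_under_20pct,
            "fraction": self.fraction,
            "one_way": dict(self.one_way),
        }


def sensitivity_report(
    tree: ValueTree,
    profile_a: PerformanceProfile,
    profile_b: PerformanceProfile,
    *,
    fraction: float = 0.20,
    grid_step: float | None = 0.001,
    use_reported_values: bool = True,
    overrides: Sequence[Mapping[str, float] | None] | None = None,
    **score_kwargs,
) -> SensitivityReport:
    """Assemble the full weight-sensitivity report for two regimens.

    With ``use_reported_values`` the crossover is solved from the
    integer category values a decision summary reports (the form the
    headline stability claim is stated in); otherwise from the
    full-precision values.  ``overrides`` carries per-profile
    preference overrides aligned with (profile_a, profile_b);
    ``grid_step=None`` skips one-way sweeps.
    """
    if not tree.is_normalized:
        tree = normalize_swing_weights(tree)
    ov = _pair_overrides(overrides)
    s_a = score_profile(profile_a, tree, preference_overrides=ov[0], **score_kwargs)
    s_b = score_profile(profile_b, tree, preference_overrides=ov[1], **score_kwargs)
    if use_reported_values:
        ra, rb = s_a.reported(), s_b.reported()
        cross = crossover_weight(
            ra["benefit_value"], ra["risk_value"], rb["benefit_value"], rb["risk_value"]
        )
    else:
        cross = crossover_weight(
            s_a.benefit_value, s_a.risk_value, s_b.benefit_value, s_b.risk_value
        )
    ranked = sorted(((s.overall, s.regimen_id) for s in (s_a, s_b)), reverse=True)
    one_way: dict[str, float | None] = {}
    if grid_step is not None:
        for c in tree.criteria:
            one_way[c.id] = one_way_weight_sweep(
                tree,
                (profile_a, profile_b),
                c.id,
                grid_step=grid_step,
                overrides=overrides,
                integer_preferences=score_kwargs.get("integer_preferences", True),
                weight_precision=score_kwargs.get("weight_precision"),
            )
    return SensitivityReport(
        crossover_weight=cross.weight,
        crossover_reason=cross.reason,
        ranking_at_default=tuple(rid for _, rid in ranked),
        stable_under_20pct=perturb_stability(
            tree, (profile_a, profile_b), fraction, overrides=overrides, **score_kwargs
        ),
        fraction=fraction,
        one_way=one_way,
    )
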