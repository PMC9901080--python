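"""Swing-weighted multicriteria value model.

A two-level value tree splits outcome indicators into a benefit and a
risk category.  Within a category each criterion carries a raw SWING
weight (the most important swing scored 100, the rest rated against
it); normalization turns raw weights into relative weights that sum to
the category's top-level weight.  Each criterion maps a measurement
(a pooled odds ratio or mean difference) onto a 0-100 preference scale
through a linear partial value function anchored at a best and a worst
value, clamped outside the anchors.

Scoring a regimen multiplies preferences by relative weights, sums
them into category totals, rescales the totals by the category weights
onto a 0-100 category value, and adds the totals into an overall
benefit-risk score.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "Criterion",
    "ValueTree",
    "Measurement",
    "PerformanceProfile",
    "CriterionScore",
    "ScoreBreakdown",
    "normalize_swing_weights",
    "partial_value",
    "score_profile",
    "round_half_away",
    "load_value_tree",
    "dump_value_tree",
]

CATEGORIES = ("benefit", "risk")


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero.

    Values are snapped to 9 decimals first so that binary representation
    noise (e.g. 47.499999999999996 for an exact 47.5) cannot flip a tie.
    """
    x = round(x, 9)
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class Criterion:
    """One outcome indicator in the value tree.

    ``best`` is the measurement mapped to preference 100 and ``worst``
    the one mapped to 0; direction is implicit in the anchor ordering
    (for harms, best is numerically below worst).  ``raw_weight`` is
    the SWING score; ``relative_weight`` is filled by
    :func:`normalize_swing_weights`.
    """

    id: str
    label: str
    category: str  # "benefit" | "risk"
    measure: str  # "OR" | "MD"
    raw_weight: float
    best: float
    worst: float
    relative_weight: float | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"criterion {self.id!r}: unknown category {self.category!r}")
        if self.measure not in ("OR", "MD"):
            raise ValueError(f"criterion {self.id!r}: unknown measure {self.measure!r}")
        if self.raw_weight <= 0:
            raise ValueError(f"criterion {self.id!r}: raw weight must be > 0")
        if self.best == self.worst:
            raise ValueError(f"criterion {self.id!r}: best and worst anchors coincide")


@dataclass(frozen=True)
class ValueTree:
    """Two-level value tree: category weights plus weighted criteria."""

    category_weights: Mapping[str, float]
    criteria: Sequence[Criterion]

    def __post_init__(self) -> None:
        if set(self.category_weights) != set(CATEGORIES):
            raise ValueError("category weights must cover exactly 'benefit' and 'risk'")
        total = sum(self.category_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category weights must sum to 1 (got {total})")
        ids = [c.id for c in self.criteria]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate criterion ids in tree")

    def criterion(self, criterion_id: str) -> Criterion:
        for c in self.criteria:
            if c.id == criterion_id:
                return c
        raise KeyError(f"unknown criterion {criterion_id!r}")

    def in_category(self, category: str) -> list[Criterion]:
        return [c for c in self.criteria if c.category == category]

    @property
    def is_normalized(self) -> bool:
        return all(c.relative_weight is not None for c in self.criteria)


def normalize_swing_weights(tree: ValueTree) -> ValueTree:
    """Fill each criterion's relative weight from the raw SWING scores.

    relative_weight = (raw_weight / sum of raw weights in the category)
    * category weight, so relative weights sum to the category weight
    and to 1 over the whole tree.  Idempotent.
    """
    new = []
    for cat in CATEGORIES:
        members = tree.in_category(cat)
        if not members:
            raise ValueError(f"category {cat!r} has no criteria")
        raw_sum = sum(c.raw_weight for c in members)
        w_cat = tree.category_weights[cat]
        for c in members:
            new.append(replace(c, relative_weight=c.raw_weight / raw_sum * w_cat))
    order = {c.id: i for i, c in enumerate(tree.criteria)}
    new.sort(key=lambda c: order[c.id])
    return ValueTree(category_weights=dict(tree.category_weights), criteria=tuple(new))


def partial_value(x: float, criterion: Criterion, *, integer: bool = True) -> float:
    """Linear-clamped partial value of measurement ``x`` on 0-100.

    v = 100 * (x - worst) / (best - worst), clamped to [0, 100]; with
    ``integer=True`` (the deterministic reporting convention) the
    preference is rounded half-away-from-zero to an integer.
    """
    if not math.isfinite(x):
        raise ValueError("measurement must be finite")
    if criterion.measure == "OR" and x <= 0:
        raise ValueError(f"criterion {criterion.id!r}: odds-ratio measurement must be > 0")
    v = 100.0 * (x - criterion.worst) / (criterion.best - criterion.worst)
    v = min(100.0, max(0.0, v))
    return float(round_half_away(v)) if integer else v


@dataclass(frozen=True)
class Measurement:
    """A point estimate on the criterion's measure scale, with optional SE.

    For odds ratios the SE lives on the log scale (the scale the
    Monte Carlo stage samples on); ``se=0`` marks a value treated as
    known exactly.
    """

    point: float
    se: float = 0.0

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be >= 0")


@dataclass(frozen=True)
class PerformanceProfile:
    """One regimen's measurement for every criterion of a tree."""

    regimen_id: str
    measurements: Mapping[str, Measurement]

    def measurement(self, criterion_id: str) -> Measurement:
        try:
            return self.measurements[criterion_id]
        except KeyError:
            raise KeyError(
                f"profile {self.regimen_id!r} has no measurement for "
                f"criterion {criterion_id!r}"
            ) from None

    def require_complete(self, tree: ValueTree) -> None:
        missing = [c.id for c in tree.criteria if c.id not in self.measurements]
        if missing:
            raise ValueError(
                f"profile {self.regimen_id!r} is missing measurements for: {missing}"
            )


def profile_from_pooled(regimen_id: str, effects) -> PerformanceProfile:
    """Build a profile from pooled effects, SEs back-derived from CIs."""
    return PerformanceProfile(
        regimen_id=regimen_id,
        measurements={e.indicator_id: Measurement(point=e.point, se=e.se) for e in effects},
    )


@dataclass(frozen=True)
class CriterionScore:
    criterion_id: str
    category: str
    measurement: float
    preference: float
    relative_weight: float
    weight_score: float


@dataclass(frozen=True)
class ScoreBreakdown:
    """Full-precision scores for one regimen under one tree.

    ``benefit_value`` and ``risk_value`` are the category totals
    rescaled onto 0-100 by the category weights; ``overall`` is the sum
    of the two category totals.  ``reported()`` applies the
    integer presentation rounding used in decision summaries.
    """

    regimen_id: str
    rows: Sequence[CriterionScore]
    benefit_total: float
    risk_total: float
    benefit_value: float
    risk_value: float
    overall: float

    def reported(self) -> dict[str, int]:
        return {
            "benefit_value": round_half_away(self.benefit_value),
            "risk_value": round_half_away(self.risk_value),
            "overall": round_half_away(self.overall),
        }

    def weight_scores(self) -> dict[str, float]:
        return {r.criterion_id: r.weight_score for r in self.rows}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in self.rows])
        df.insert(0, "regimen_id", self.regimen_id)
        return df

    def to_dict(self) -> dict:
        return {
            "regimen_id": self.regimen_id,
            "criteria": [vars(r) for r in self.rows],
            "benefit_total": self.benefit_total,
            "risk_total": self.risk_total,
            "benefit_value": self.benefit_value,
            "risk_value": self.risk_value,
            "overall": self.overall,
            "reported": self.reported(),
        }


def score_profile(
    profile: PerformanceProfile,
    tree: ValueTree,
    *,
    integer_preferences: bool = True,
    weight_precision: int | None = None,
    preference_overrides: Mapping[str, float] | None = None,
) -> ScoreBreakdown:
    """Score a regimen's profile through a normalized value tree.

    ``weight_precision`` optionally rounds relative weights to that
    many decimals before weighting — published benefit-risk tables
    often carry weights at 0.1-percentage-point precision
    (``weight_precision=3``), and reproducing their cells bit-exactly
    requires the same truncation.  ``preference_overrides`` substitutes
    fixed preferences for named criteria (used to carry documented
    errata of a published scoring table); overridden criteria skip the
    partial value function entirely.
    """
    if not tree.is_normalized:
        tree = normalize_swing_weights(tree)
    profile.require_complete(tree)
    overrides = dict(preference_overrides or {})
    unknown = set(overrides) - {c.id for c in tree.criteria}
    if unknown:
        raise KeyError(f"preference overrides for unknown criteria: {sorted(unknown)}")

    rows = []
    totals = {"benefit": 0.0, "risk": 0.0}
    for c in tree.criteria:
        x = profile.measurement(c.id).point
        if c.id in overrides:
            pref = float(overrides[c.id])
        else:
            pref = partial_value(x, c, integer=integer_preferences)
        w = c.relative_weight
        if weight_precision is not None:
            w = round(w, weight_precision)
        ws = w * pref
        totals[c.category] += ws
        rows.append(
            CriterionScore(
                criterion_id=c.id,
                category=c.category,
                measurement=x,
                preference=pref,
                relative_weight=w,
                weight_score=ws,
            )
        )
    w_benefit = tree.category_weights["benefit"]
    w_risk = tree.category_weights["risk"]
    return ScoreBreakdown(
        regimen_id=profile.regimen_id,
        rows=tuple(rows),
        benefit_total=totals["benefit"],
        risk_total=totals["risk"],
        benefit_value=totals["benefit"] / w_benefit,
        risk_value=totals["risk"] / w_risk,
        overall=totals["benefit"] + totals["risk"],
    )


# --- tree configuration files --------------------------------------------


def _tree_from_dict(cfg: Mapping) -> ValueTree:
    try:
        cats = {k: float(v) for k, v in cfg["categories"].items()}
        criteria = tuple(
            Criterion(
                id=str(c["id"]),
                label=str(c.get("label", c["id"])),
                category=str(c["category"]),
                measure=str(c["measure"]),
                raw_weight=float(c["raw_weight"]),
                best=float(c["best"]),
                worst=float(c["worst"]),
            )
            for c in cfg["criteria"]
        )
    except KeyError as exc:
        raise ValueError(f"value-tree config missing key {exc}") from exc
    return normalize_swing_weights(ValueTree(category_weights=cats, criteria=criteria))


def load_value_tree(path) -> ValueTree:
    """Load and normalize a value tree from a JSON or YAML config file."""
    path = Path(path)
    text = path.read_text()
    cfg = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    return _tree_from_dict(cfg)


def dump_value_tree(tree: ValueTree, path) -> None:
    cfg = {
        "categories": dict(tree.category_weights),
        "criteria": [
            {
                "id": c.id,
                "label": c.label,
                "category": c.category,
                "measure": c.measure,
                "raw_weight": c.raw_weight,
                "best": c.best,
                "worst": c.worst,
            }
            for c in tree.criteria
        ],
    }
    Path(path).write_text(json.dumps(cfg, indent=2) + "\n")
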