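"""The shipped sinomenine benefit-risk dataset.

The package ships the inputs of the published benefit-risk assessment
of sinomenine preparations for rheumatoid arthritis: the two-level
value tree (7 benefit + 6 risk indicators with SWING weights and
best/worst anchors, benefit weighted 60% and risk 40%), and the
pooled effects — odds ratios for dichotomous indicators, mean
differences for continuous ones, each with its 95% CI and the number
of contributing RCTs — for the two regimens compared: sinomenine
alone versus sinomenine combined with conventional drugs (NSAIDs /
DMARDs).  The raw data of the 44 underlying RCTs are not publicly
deposited, so the pooled effects are the authoritative regimen inputs.

The published per-criterion scoring table is also shipped, together
with its documented internal inconsistencies (``errata``): three cells
disagree with what their own pooled effects imply under the stated
scoring rules.  For the swollen-joint-count cell of the monotherapy
regimen the published preference (53) is carried as an override
because the published category totals and headline values are only
reproducible with it; the two deviating combination-regimen cells
(liver impairment, leucopenia) are *not* overridden because there the
published totals side with the recomputation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

from .meta import ci_to_se
from .value import (
    Measurement,
    PerformanceProfile,
    ScoreBreakdown,
    ValueTree,
    _tree_from_dict,
    score_profile,
)

__all__ = [
    "load_sinomenine_tree",
    "load_sinomenine_profiles",
    "load_published_scores",
    "sinomenine_example",
    "SinomenineExample",
]

#: the published table carries relative weights at 0.1-percentage-point
#: precision; reproducing its cells requires the same truncation
PUBLISHED_WEIGHT_PRECISION = 3


def _read_json(name: str) -> dict:
    with resources.files("brmcda.data").joinpath(name).open("r") as fh:
        return json.load(fh)


def load_sinomenine_tree() -> ValueTree:
    """The normalized sinomenine benefit-risk value tree (13 criteria)."""
    return _tree_from_dict(_read_json("sinomenine_tree.json"))


def load_sinomenine_profiles(
    with_uncertainty: bool = True,
) -> tuple[PerformanceProfile, PerformanceProfile]:
    """(alone, combined) performance profiles from the pooled effects.

    With ``with_uncertainty`` each measurement carries the standard
    error back-derived from its 95% CI (log scale for odds ratios);
    otherwise all SEs are zero and scoring is fully deterministic.
    """
    raw = _read_json("sinomenine_profiles.json")
    tree = load_sinomenine_tree()
    measures = {c.id: c.measure for c in tree.criteria}
    profiles = []
    for regimen in ("alone", "combined"):
        meas = {}
        for cid, rec in raw[regimen].items():
            se = ci_to_se(rec["ci_low"], rec["ci_high"], measures[cid]) if with_uncertainty else 0.0
            meas[cid] = Measurement(point=rec["point"], se=se)
        profiles.append(PerformanceProfile(regimen_id=regimen, measurements=meas))
    return tuple(profiles)


def load_pooled_table() -> dict:
    """Raw pooled-effect records (point, ci_low, ci_high, k) per regimen."""
    return _read_json("sinomenine_profiles.json")


def load_published_scores() -> dict:
    """The published per-criterion weight scores, totals and errata."""
    return _read_json("sinomenine_published_scores.json")


@dataclass(frozen=True)
class SinomenineExample:
    """Everything needed to reproduce the published assessment."""

    tree: ValueTree
    alone: PerformanceProfile
    combined: PerformanceProfile
    errata: Mapping[str, Mapping[str, float]]
    weight_precision: int

    def breakdowns(self) -> tuple[ScoreBreakdown, ScoreBreakdown]:
        """Deterministic score breakdowns with the published conventions.

        Integer preferences, 0.1-pp weight precision, and the
        documented errata overrides — the settings under which the
        published headline values (benefit 39/59, risk 56/43, overall
        46/53) are reproduced exactly.
        """
        out = []
        for p in (self.alone, self.combined):
            out.append(
                score_profile(
                    p,
                    self.tree,
                    weight_precision=self.weight_precision,
                    preference_overrides=self.errata.get(p.regimen_id) or None,
                )
            )
        return tuple(out)


def sinomenine_example(with_uncertainty: bool = True) -> SinomenineExample:
    """Load tree, profiles and reproduction conventions in one bundle."""
    alone, combined = load_sinomenine_profiles(with_uncertainty=with_uncertainty)
    published = load_published_scores()
    return SinomenineExample(
        tree=load_sinomenine_tree(),
        alone=alone,
        combined=combined,
        errata=published["errata"],
        weight_precision=published["weight_precision"],
    )
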