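"""Full-pipeline orchestration: pool -> score -> simulate -> sensitivity.

A pipeline config (YAML or JSON) names the value tree, exactly two
regimens (each backed by a trial-summary CSV, a pooled-effects CSV, or
the shipped sinomenine dataset), the Monte Carlo block and the
sensitivity block.  ``run_pipeline`` executes the stages in order and
writes a deterministic report bundle: pooled-effects CSVs (when
pooling ran), per-regimen score tables (CSV + JSON), the Monte Carlo
result (JSON), the sensitivity report (JSON) and a human-readable
summary whose every number is taken from the machine-readable files.

Floating-point output is serialized at 6 significant digits (integer
preferences excepted) so repeated runs with identical configs and
seeds produce byte-identical bundles.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import datasets, meta
from .montecarlo import MCConfig, MCResult, mc_compare
from .sensitivity import SensitivityReport, sensitivity_report
from .value import (
    PerformanceProfile,
    ScoreBreakdown,
    ValueTree,
    load_value_tree,
    profile_from_pooled,
    score_profile,
)

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "pool_profile"]


def _sig6(x: Any) -> Any:
    """Round floats (recursively) to 6 significant digits for output."""
    if isinstance(x, bool):
        return x
    if isinstance(x, float):
        return float(f"{x:.6g}")
    if isinstance(x, dict):
        return {k: _sig6(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_sig6(v) for v in x]
    return x


def _write_json(obj: Mapping, path: Path) -> None:
    path.write_text(json.dumps(_sig6(obj), indent=2, sort_keys=True) + "\n")


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline configuration.

    ``regimens`` holds exactly two entries; each names its input as
    exactly one of ``trials_csv``, ``pooled_csv`` or ``builtin``
    ("alone"/"combined" from the shipped sinomenine dataset).
    """

    tree: str
    regimens: tuple[Mapping[str, str], Mapping[str, str]]
    model: str = "fixed"
    model_overrides: Mapping[str, str] | None = None
    weight_precision: int | None = None
    preference_overrides: Mapping[str, Mapping[str, float]] | None = None
    mc: Mapping[str, Any] | None = None
    sensitivity: Mapping[str, Any] | None = None
    out_dir: str = "brmcda_out"

    @classmethod
    def from_dict(cls, cfg: Mapping[str, Any], base: Path | None = None) -> "PipelineConfig":
        regimens = cfg.get("regimens")
        if not regimens or len(regimens) != 2:
            raise ValueError("pipeline config must list exactly two regimens")
        for r in regimens:
            keys = {"trials_csv", "pooled_csv", "builtin"} & set(r)
            if "id" not in r:
                raise ValueError("every regimen needs an 'id'")
            if len(keys) != 1:
                raise ValueError(
                    f"regimen {r.get('id')!r}: supply exactly one of "
                    "trials_csv / pooled_csv / builtin"
                )

        def resolve(p):
            if base is not None and p is not None and not Path(p).is_absolute():
                return str(base / p)
            return p

        regimens = tuple(
            {k: (resolve(v) if k.endswith("_csv") else v) for k, v in r.items()}
            for r in regimens
        )
        return cls(
            tree=resolve(cfg.get("tree", "sinomenine"))
            if cfg.get("tree", "sinomenine") != "sinomenine"
            else "sinomenine",
            regimens=regimens,
            model=cfg.get("model", "fixed"),
            model_overrides=cfg.get("model_overrides"),
            weight_precision=cfg.get("weight_precision"),
            preference_overrides=cfg.get("preference_overrides"),
            mc=cfg.get("mc"),
            sensitivity=cfg.get("sensitivity"),
            out_dir=resolve(cfg.get("out_dir", "brmcda_out")),
        )

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        cfg = yaml.safe_load(path.read_text())
        if not isinstance(cfg, dict):
            raise ValueError(f"pipeline config {path} is not a mapping")
        return cls.from_dict(cfg, base=path.parent)


def pool_profile(
    regimen_id: str,
    trials: Sequence[meta.TrialSummary],
    tree: ValueTree,
    model: str = "fixed",
    model_overrides: Mapping[str, str] | None = None,
) -> tuple[PerformanceProfile, list[meta.PooledEffect]]:
    """Pool trials per indicator and assemble a performance profile.

    The model choice applies per indicator; ``model_overrides`` maps
    indicator ids to "fixed"/"random"/"auto".  Every tree criterion
    must be covered by at least one trial.
    """
    by_indicator: dict[str, list[meta.TrialSummary]] = defaultdict(list)
    for t in trials:
        by_indicator[t.indicator_id].append(t)
    missing = [c.id for c in tree.criteria if c.id not in by_indicator]
    if missing:
        raise ValueError(f"regimen {regimen_id!r}: no trials for criteria {missing}")
    overrides = dict(model_overrides or {})
    effects = []
    for c in tree.criteria:
        effects.append(
            meta.pool_trials(by_indicator[c.id], model=overrides.get(c.id, model))
        )
    return profile_from_pooled(regimen_id, effects), effects


@dataclass(frozen=True)
class ReportBundle:
    """In-memory results plus the paths of everything written."""

    tree: ValueTree
    profiles: tuple[PerformanceProfile, PerformanceProfile]
    breakdowns: tuple[ScoreBreakdown, ScoreBreakdown]
    mc_result: MCResult
    sensitivity: SensitivityReport
    paths: Mapping[str, str]


def _load_regimen(
    spec: Mapping[str, str], cfg: PipelineConfig, tree: ValueTree, out: Path
) -> tuple[PerformanceProfile, str | None]:
    rid = spec["id"]
    if "builtin" in spec:
        which = spec["builtin"]
        alone, combined = datasets.load_sinomenine_profiles()
        prof = {"alone": alone, "combined": combined}.get(which)
        if prof is None:
            raise ValueError(f"unknown builtin profile {which!r}")
        return PerformanceProfile(regimen_id=rid, measurements=prof.measurements), None
    if "pooled_csv" in spec:
        effects = meta.read_pooled_csv(spec["pooled_csv"])
        return profile_from_pooled(rid, effects), None
    trials = meta.read_trials_csv(spec["trials_csv"])
    prof, effects = pool_profile(
        rid, trials, tree, model=cfg.model, model_overrides=cfg.model_overrides
    )
    pooled_path = out / f"pooled_{rid}.csv"
    meta.pooled_to_frame(effects).to_csv(pooled_path, index=False, float_format="%.6g")
    return prof, str(pooled_path)


def run_pipeline(cfg: PipelineConfig | Mapping[str, Any], seed: int | None = None) -> ReportBundle:
    """Execute pool -> score -> simulate -> sensitivity and write the bundle.

    ``seed`` overrides the Monte Carlo seed from the config.  The
    bundle is deterministic given config and seed.
    """
    if not isinstance(cfg, PipelineConfig):
        cfg = PipelineConfig.from_dict(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    tree = (
        datasets.load_sinomenine_tree()
        if cfg.tree == "sinomenine"
        else load_value_tree(cfg.tree)
    )

    profiles = []
    for spec in cfg.regimens:
        prof, pooled_path = _load_regimen(spec, cfg, tree, out)
        if pooled_path:
            paths[f"pooled_{prof.regimen_id}"] = pooled_path
        profiles.append(prof)
    profile_a, profile_b = profiles

    pref_overrides = cfg.preference_overrides
    if pref_overrides == "builtin":
        pref_overrides = datasets.load_published_scores()["errata"]
    pref_overrides = pref_overrides or {}

    breakdowns = []
    for prof in profiles:
        s = score_profile(
            prof,
            tree,
            weight_precision=cfg.weight_precision,
            preference_overrides=pref_overrides.get(prof.regimen_id) or None,
        )
        sp_json = out / f"scores_{prof.regimen_id}.json"
        _write_json(s.to_dict(), sp_json)
        sp_csv = out / f"scores_{prof.regimen_id}.csv"
        s.to_frame().to_csv(sp_csv, index=False, float_format="%.6g")
        paths[f"scores_{prof.regimen_id}_json"] = str(sp_json)
        paths[f"scores_{prof.regimen_id}_csv"] = str(sp_csv)
        breakdowns.append(s)
    s_a, s_b = breakdowns

    mc_block = dict(cfg.mc or {})
    if seed is not None:
        mc_block["seed"] = seed
    mc_cfg = MCConfig(
        iterations=int(mc_block.get("iterations", 30_000)),
        seed=int(mc_block.get("seed", 0)),
        ci_level=float(mc_block.get("ci_level", 0.95)),
    )
    mc_result = mc_compare(profile_a, profile_b, tree, mc_cfg)
    mc_path = out / "mc.json"
    _write_json(mc_result.to_dict(), mc_path)
    paths["mc_json"] = str(mc_path)

    sens_block = dict(cfg.sensitivity or {})
    sens = sensitivity_report(
        tree,
        profile_a,
        profile_b,
        fraction=float(sens_block.get("fraction", 0.20)),
        grid_step=sens_block.get("grid_step", 0.001),
        overrides=(
            pref_overrides.get(profile_a.regimen_id) or None,
            pref_overrides.get(profile_b.regimen_id) or None,
        ),
        weight_precision=cfg.weight_precision,
    )
    sens_path = out / "sensitivity.json"
    _write_json(sens.to_dict(), sens_path)
    paths["sensitivity_json"] = str(sens_path)

    summary_path = out / "summary.txt"
    summary_path.write_text(_render_summary(tree, (s_a, s_b), mc_result, sens))
    paths["summary"] = str(summary_path)

    return ReportBundle(
        tree=tree,
        profiles=(profile_a, profile_b),
        breakdowns=(s_a, s_b),
        mc_result=mc_result,
        sensitivity=sens,
        paths=paths,
    )


def _render_summary(
    tree: ValueTree,
    breakdowns: tuple[ScoreBreakdown, ScoreBreakdown],
    mc: MCResult,
    sens: SensitivityReport,
) -> str:
    s_a, s_b = breakdowns
    ra, rb = s_a.reported(), s_b.reported()
    w_b = tree.category_weights["benefit"]
    lines = [
        "Benefit-risk assessment summary",
        "===============================",
        "",
        f"Regimens: A = {s_a.regimen_id}, B = {s_b.regimen_id}",
        f"Category weights: benefit {w_b:.6g}, risk {tree.category_weights['risk']:.6g}",
        "",
        "Reported category values (0-100, integer presentation):",
        f"  benefit value : A {ra['benefit_value']:>3d}   B {rb['benefit_value']:>3d}"
        f"   (difference {rb['benefit_value'] - ra['benefit_value']:+d})",
        f"  risk value    : A {ra['risk_value']:>3d}   B {rb['risk_value']:>3d}"
        f"   (difference {rb['risk_value'] - ra['risk_value']:+d})",
        f"  overall score : A {ra['overall']:>3d}   B {rb['overall']:>3d}"
        f"   (difference {rb['overall'] - ra['overall']:+d})",
        "",
        f"Monte Carlo ({mc.config.iterations} iterations, seed {mc.config.seed}),",
        f"{mc.config.ci_level:.0%} percentile intervals of the B - A differences:",
        f"  benefit value : {mc.benefit_diff.point:.6g}"
        f"  CI ({mc.benefit_diff.ci_low:.6g}, {mc.benefit_diff.ci_high:.6g})",
        f"  risk value    : {mc.risk_diff.point:.6g}"
        f"  CI ({mc.risk_diff.ci_low:.6g}, {mc.risk_diff.ci_high:.6g})",
        f"  overall score : {mc.overall_diff.point:.6g}"
        f"  CI ({mc.overall_diff.ci_low:.6g}, {mc.overall_diff.ci_high:.6g})",
        f"  P(B overall > A overall) = {mc.p_superior:.6g}",
        "",
        "Sensitivity:",
        f"  ranking at default split : {' > '.join(sens.ranking_at_default)}",
        f"  benefit-weight crossover : "
        + (
            f"{sens.crossover_weight:.6g}"
            if sens.crossover_weight is not None
            else f"none ({sens.crossover_reason})"
        ),
        f"  stable under +/-{sens.fraction:.0%} benefit-weight change : "
        + ("yes" if sens.stable_under_20pct else "no"),
        "",
    ]
    return "\n".join(lines)
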