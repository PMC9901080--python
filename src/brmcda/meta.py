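"""Pairwise meta-analysis of two-arm trial summaries.

Pools per-indicator trial summaries into effect estimates with 95%
confidence intervals: Mantel-Haenszel odds ratios for dichotomous
outcomes (with the Robins-Breslow-Greenland variance), inverse-variance
mean differences for continuous outcomes, and DerSimonian-Laird
random-effects variants driven by the between-trial variance tau^2.

Odds ratios are pooled on the log scale and reported on the natural
scale.  All intervals use the fixed normal quantile Z95 so confidence
limits are bit-stable across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Z95",
    "TrialSummary",
    "PooledEffect",
    "ci_to_se",
    "dl_tau2",
    "pool_or_mh",
    "pool_md_iv",
    "pool_trials",
    "read_trials_csv",
    "write_pooled_csv",
]

#: two-sided 95% normal quantile, frozen for reproducible intervals
Z95 = 1.959964

_DICH_FIELDS = ("events_trt", "n_trt", "events_ctl", "n_ctl")
_CONT_FIELDS = ("mean_trt", "sd_trt", "n_trt", "mean_ctl", "sd_ctl", "n_ctl")


@dataclass(frozen=True)
class TrialSummary:
    """Summary statistics of one two-arm trial for one outcome indicator.

    Either the dichotomous fields (events and arm sizes) or the
    continuous fields (mean, SD and arm size per arm) are populated,
    according to ``design``.
    """

    trial_id: str
    indicator_id: str
    design: str  # "dichotomous" | "continuous"
    events_trt: int | None = None
    n_trt: int | None = None
    events_ctl: int | None = None
    n_ctl: int | None = None
    mean_trt: float | None = None
    sd_trt: float | None = None
    mean_ctl: float | None = None
    sd_ctl: float | None = None

    def __post_init__(self) -> None:
        if self.design not in ("dichotomous", "continuous"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.n_trt is None or self.n_ctl is None:
            raise ValueError("both arm sizes are required")
        if self.n_trt < 1 or self.n_ctl < 1:
            raise ValueError("arm sizes must be >= 1")
        if self.design == "dichotomous":
            for ev, n in ((self.events_trt, self.n_trt), (self.events_ctl, self.n_ctl)):
                if ev is None:
                    raise ValueError("dichotomous trials need event counts in both arms")
                if not 0 <= ev <= n:
                    raise ValueError(f"events {ev} outside [0, {n}]")
        else:
            for name in ("mean_trt", "sd_trt", "mean_ctl", "sd_ctl"):
                if getattr(self, name) is None:
                    raise ValueError(f"continuous trials need {name}")
            if self.sd_trt < 0 or self.sd_ctl < 0:
                raise ValueError("standard deviations must be >= 0")


@dataclass(frozen=True)
class PooledEffect:
    """A pooled effect with its 95% CI on the reporting scale.

    ``measure`` is "OR" (reported on the natural scale, pooled on the
    log scale) or "MD".  ``tau2``, ``q_stat`` and ``i2`` describe
    between-trial heterogeneity; ``model`` records whether fixed- or
    random-effects weighting produced the estimate.
    """

    indicator_id: str
    measure: str
    point: float
    ci_low: float
    ci_high: float
    k_studies: int
    tau2: float
    q_stat: float
    i2: float
    model: str

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")
        if self.measure == "OR" and min(self.point, self.ci_low, self.ci_high) <= 0:
            raise ValueError("odds ratios and their limits must be positive")

    @property
    def se(self) -> float:
        """Standard error back-derived from the CI (log scale for OR)."""
        return ci_to_se(self.ci_low, self.ci_high, self.measure)


def ci_to_se(ci_low: float, ci_high: float, measure: str) -> float:
    """Back-derive a standard error from a 95% confidence interval.

    For an odds ratio the interval is assumed symmetric on the log
    scale and the SE of the *log* effect is returned; for a mean
    difference the interval is symmetric on the natural scale.
    """
    if ci_low > ci_high:
        raise ValueError("ci_low must not exceed ci_high")
    if measure == "OR":
        if ci_low <= 0 or ci_high <= 0:
            raise ValueError("odds-ratio confidence limits must be positive")
        return (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z95)
    if measure == "MD":
        return (ci_high - ci_low) / (2.0 * Z95)
    raise ValueError(f"unknown measure {measure!r}")


def dl_tau2(effects: Sequence[float], variances: Sequence[float]) -> float:
    """DerSimonian-Laird moment estimate of the between-trial variance.

    tau^2 = max(0, (Q - (k-1)) / C) with Q the fixed-effect
    heterogeneity statistic and C = sum(w) - sum(w^2)/sum(w), where the
    w are the fixed-effect (inverse-variance) weights.
    """
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    if y.shape != v.shape:
        raise ValueError("effects and variances must have equal length")
    k = y.size
    if k < 2:
        raise ValueError("tau^2 estimation needs at least 2 trials")
    if np.any(v <= 0):
        raise ValueError("variances must be positive")
    w = 1.0 / v
    sw = w.sum()
    ybar = float((w * y).sum() / sw)
    q = float((w * (y - ybar) ** 2).sum())
    c = float(sw - (w**2).sum() / sw)
    return max(0.0, (q - (k - 1)) / c)


def _check_same_indicator(trials: Sequence[TrialSummary], design: str) -> str:
    if not trials:
        raise ValueError("cannot pool an empty list of trials")
    indicators = {t.indicator_id for t in trials}
    if len(indicators) > 1:
        raise ValueError(f"mixed indicators in one pool: {sorted(indicators)}")
    for t in trials:
        if t.design != design:
            raise ValueError(f"trial {t.trial_id!r} is not {design}")
    return trials[0].indicator_id


def _or_tables(trials: Sequence[TrialSummary]) -> np.ndarray:
    """2x2 cells (a, b, c, d) per informative trial, zero-cell corrected.

    Trials with zero events in both arms, or events in every subject of
    both arms, carry no information about the odds ratio and are
    dropped; any remaining trial with a zero cell gets 0.5 added to all
    four cells (the continuity convention of standard meta-analysis
    software).
    """
    rows = []
    for t in trials:
        a = float(t.events_trt)
        b = float(t.n_trt - t.events_trt)
        c = float(t.events_ctl)
        d = float(t.n_ctl - t.events_ctl)
        if (a == 0 and c == 0) or (b == 0 and d == 0):
            continue  # double-zero margin: inestimable, excluded
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        rows.append((a, b, c, d))
    if not rows:
        raise ValueError("no informative trials: every 2x2 table has an all-zero margin")
    return np.array(rows, dtype=float)


def pool_or_mh(trials: Sequence[TrialSummary], model: str = "fixed") -> PooledEffect:
    """Pool dichotomous trials into an odds ratio.

    ``model="fixed"`` gives the Mantel-Haenszel pooled OR with the
    Robins-Breslow-Greenland variance for its log.  ``model="random"``
    pools study-level log ORs by DerSimonian-Laird inverse-variance
    weighting.  ``model="auto"`` starts fixed and switches to random
    effects when I^2 > 50%.

    Heterogeneity (Q, I^2, DL tau^2) is always computed from the
    study-level log ORs and reported with either model.
    """
    if model not in ("fixed", "random", "auto"):
        raise ValueError(f"unknown model {model!r}")
    indicator = _check_same_indicator(trials, "dichotomous")
    cells = _or_tables(trials)
    a, b, c, d = cells.T
    n = cells.sum(axis=1)
    k = len(cells)

    r = a * d / n
    s = b * c / n
    or_mh = float(r.sum() / s.sum())
    log_mh = math.log(or_mh)

    # Robins-Breslow-Greenland variance of log(OR_MH)
    p = (a + d) / n
    q = (b + c) / n
    sr, ss = r.sum(), s.sum()
    var_mh = float(
        (p * r).sum() / (2 * sr**2)
        + (p * s + q * r).sum() / (2 * sr * ss)
        + (q * s).sum() / (2 * ss**2)
    )
    se_mh = math.sqrt(var_mh)

    # study-level log ORs with Woolf variances drive Q / I^2 / tau^2
    y = np.log(a * d / (b * c))
    v = 1 / a + 1 / b + 1 / c + 1 / d
    w = 1.0 / v
    q_stat = float((w * (y - log_mh) ** 2).sum())
    df = k - 1
    i2 = max(0.0, (q_stat - df) / q_stat) * 100.0 if q_stat > 0 else 0.0
    tau2 = dl_tau2(y, v) if k >= 2 else 0.0

    use_random = model == "random" or (model == "auto" and i2 > 50.0)
    if use_random and k >= 2:
        w_star = 1.0 / (v + tau2)
        log_re = float((w_star * y).sum() / w_star.sum())
        se_re = float(1.0 / math.sqrt(w_star.sum()))
        point, se, fitted = log_re, se_re, "random"
    else:
        point, se, fitted = log_mh, se_mh, "fixed"

    return PooledEffect(
        indicator_id=indicator,
        measure="OR",
        point=math.exp(point),
        ci_low=math.exp(point - Z95 * se),
        ci_high=math.exp(point + Z95 * se),
        k_studies=k,
        tau2=tau2,
        q_stat=q_stat,
        i2=i2,
        model=fitted,
    )


def pool_md_iv(trials: Sequence[TrialSummary], model: str = "fixed") -> PooledEffect:
    """Pool continuous trials into a mean difference by inverse variance.

    Per-trial variance is sd_trt^2/n_trt + sd_ctl^2/n_ctl.  Under
    ``model="random"`` the DerSimonian-Laird tau^2 is added to every
    trial variance before weighting; ``model="auto"`` switches to
    random effects when I^2 > 50%.
    """
    if model not in ("fixed", "random", "auto"):
        raise ValueError(f"unknown model {model!r}")
    indicator = _check_same_indicator(trials, "continuous")
    for t in trials:
        if (t.n_trt < 2 or t.n_ctl < 2) and (t.sd_trt > 0 or t.sd_ctl > 0):
            raise ValueError(f"trial {t.trial_id!r}: arms of size < 2 cannot carry an SD")
    y = np.array([t.mean_trt - t.mean_ctl for t in trials])
    v = np.array([t.sd_trt**2 / t.n_trt + t.sd_ctl**2 / t.n_ctl for t in trials])
    if np.all(v == 0):
        raise ValueError("all trials have zero variance; mean difference CI undefined")
    if np.any(v == 0):
        raise ValueError("a trial with zero variance cannot be inverse-variance weighted")
    k = len(trials)

    w = 1.0 / v
    md_fe = float((w * y).sum() / w.sum())
    q_stat = float((w * (y - md_fe) ** 2).sum())
    df = k - 1
    i2 = max(0.0, (q_stat - df) / q_stat) * 100.0 if q_stat > 0 else 0.0
    tau2 = dl_tau2(y, v) if k >= 2 else 0.0

    use_random = model == "random" or (model == "auto" and i2 > 50.0)
    if use_random and k >= 2:
        w_star = 1.0 / (v + tau2)
        point = float((w_star * y).sum() / w_star.sum())
        se = float(1.0 / math.sqrt(w_star.sum()))
        fitted = "random"
    else:
        point = md_fe
        se = float(1.0 / math.sqrt(w.sum()))
        fitted = "fixed"

    return PooledEffect(
        indicator_id=indicator,
        measure="MD",
        point=point,
        ci_low=point - Z95 * se,
        ci_high=point + Z95 * se,
        k_studies=k,
        tau2=tau2,
        q_stat=q_stat,
        i2=i2,
        model=fitted,
    )


def pool_trials(trials: Sequence[TrialSummary], model: str = "fixed") -> PooledEffect:
    """Pool a homogeneous list of trials, dispatching on their design."""
    if not trials:
        raise ValueError("cannot pool an empty list of trials")
    if trials[0].design == "dichotomous":
        return pool_or_mh(trials, model=model)
    return pool_md_iv(trials, model=model)


# --- CSV interfaces -------------------------------------------------------

_CSV_COLUMNS = [
    "trial_id",
    "indicator_id",
    "design",
    "events_trt",
    "n_trt",
    "events_ctl",
    "n_ctl",
    "mean_trt",
    "sd_trt",
    "mean_ctl",
    "sd_ctl",
]


def read_trials_csv(path) -> list[TrialSummary]:
    """Read trial summaries from CSV (one row per trial and indicator)."""
    df = pd.read_csv(path)
    missing = {"trial_id", "indicator_id", "design", "n_trt", "n_ctl"} - set(df.columns)
    if missing:
        raise ValueError(f"trial CSV missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError(f"trial CSV {path} contains no rows")
    trials = []
    for idx, row in df.iterrows():
        design = str(row["design"]).strip()
        kwargs: dict = dict(
            trial_id=str(row["trial_id"]),
            indicator_id=str(row["indicator_id"]),
            design=design,
            n_trt=int(row["n_trt"]),
            n_ctl=int(row["n_ctl"]),
        )
        try:
            if design == "dichotomous":
                kwargs["events_trt"] = int(row["events_trt"])
                kwargs["events_ctl"] = int(row["events_ctl"])
            else:
                for name in ("mean_trt", "sd_trt", "mean_ctl", "sd_ctl"):
                    kwargs[name] = float(row[name])
            trials.append(TrialSummary(**kwargs))
        except (ValueError, KeyError, TypeError) as exc:
            raise ValueError(f"trial CSV line {idx + 2}: {exc}") from exc
    return trials


def trials_to_frame(trials: Iterable[TrialSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(t) for t in trials], columns=_CSV_COLUMNS)


def write_trials_csv(trials: Iterable[TrialSummary], path) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


def pooled_to_frame(effects: Iterable[PooledEffect]) -> pd.DataFrame:
    rows = [
        {
            "indicator_id": e.indicator_id,
            "measure": e.measure,
            "k": e.k_studies,
            "point": e.point,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "model": e.model,
            "tau2": e.tau2,
            "q_stat": e.q_stat,
            "i2": e.i2,
        }
        for e in effects
    ]
    return pd.DataFrame(rows)


def write_pooled_csv(effects: Iterable[PooledEffect], path) -> None:
    pooled_to_frame(effects).to_csv(path, index=False)


def read_pooled_csv(path) -> list[PooledEffect]:
    df = pd.read_csv(path)
    effects = []
    for _, row in df.iterrows():
        effects.append(
            PooledEffect(
                indicator_id=str(row["indicator_id"]),
                measure=str(row["measure"]),
                point=float(row["point"]),
                ci_low=float(row["ci_low"]),
                ci_high=float(row["ci_high"]),
                k_studies=int(row["k"]),
                tau2=float(row.get("tau2", 0.0)),
                q_stat=float(row.get("q_stat", 0.0)),
                i2=float(row.get("i2", 0.0)),
                model=str(row.get("model", "fixed")),
            )
        )
    return effects
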