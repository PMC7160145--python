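"""Survival stratification: Kaplan-Meier, log-rank and Cox regression.

The product-limit estimate and its Greenwood standard error are derived
from the lifelines event table; the two-group log-rank test and the
multivariate Cox proportional-hazards fit (Efron tie handling) delegate
to lifelines.  Times are in years throughout.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _lifelines_logrank
from lifelines.utils import survival_table_from_events

from .core_io import ClinicalRecord, UNKNOWN

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier product-limit curve with Greenwood standard errors.

    Arrays are aligned on the distinct event times; ``survival[i]`` is
    the step value just after ``event_times[i]``.
    """

    event_times: np.ndarray
    survival: np.ndarray
    greenwood_se: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    last_observed_time: float


@dataclass(frozen=True)
class SurvivalPoint:
    estimate: float
    se: float
    extrapolated: bool = False


def kaplan_meier(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Product-limit estimator with tied event times grouped.

    The Greenwood variance is ``S(t)^2 * sum d_i / (n_i (n_i - d_i))``
    over event times up to ``t``; once the curve reaches zero its
    standard error is reported as zero.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if times.shape != events.shape:
        raise ValueError("times and events differ in length")
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("event flags must be 0/1")

    table = survival_table_from_events(times, events)
    observed = table["observed"].to_numpy()
    at_risk = table["at_risk"].to_numpy()
    mask = observed > 0
    d = observed[mask].astype(float)
    n = at_risk[mask].astype(float)
    event_times = table.index.to_numpy()[mask].astype(float)

    survival = np.cumprod(1.0 - d / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > d, d / (n * (n - d)), np.inf)
        var = survival**2 * np.cumsum(terms)
    se = np.sqrt(np.where(survival > 0, var, 0.0))
    return KMCurve(
        event_times=event_times,
        survival=survival,
        greenwood_se=se,
        n_at_risk=n,
        n_events=d,
        last_observed_time=float(times.max()),
    )


def survival_at(curve: KMCurve, t: float) -> SurvivalPoint:
    """Right-continuous step-function value (and Greenwood SE) at ``t``."""
    if t < 0:
        raise ValueError("t must be non-negative")
    idx = int(np.searchsorted(curve.event_times, t, side="right")) - 1
    extrapolated = t > curve.last_observed_time
    if idx < 0:
        return SurvivalPoint(1.0, 0.0, extrapolated)
    return SurvivalPoint(
        float(curve.survival[idx]), float(curve.greenwood_se[idx]), extrapolated
    )


def logrank(
    times_a: Sequence[float], events_a: Sequence[int],
    times_b: Sequence[float], events_b: Sequence[int],
) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic on 1 df, p-value)."""
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    events_a, events_b = np.asarray(events_a, int), np.asarray(events_b, int)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if events_a.sum() + events_b.sum() == 0:
        return 0.0, 1.0
    result = _lifelines_logrank(times_a, times_b, events_a, events_b)
    return float(result.test_statistic), float(result.p_value)


@dataclass(frozen=True)
class CovariateEffect:
    name: str
    coef: float
    hazard_ratio: float
    se: float
    p: float
    ci_low: float
    ci_high: float


@dataclass
class CoxFit:
    effects: list[CovariateEffect]
    n_samples: int
    n_events: int
    converged: bool
    dropped_covariates: list[str] = field(default_factory=list)

    def effect(self, name: str) -> CovariateEffect:
        for eff in self.effects:
            if eff.name == name:
                return eff
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_events": self.n_events,
            "converged": self.converged,
            "dropped_covariates": self.dropped_covariates,
            "effects": [vars(e) for e in self.effects],
        }


def cox_ph(
    frame: pd.DataFrame,
    duration_col: str = "time",
    event_col: str = "event",
    covariates: Optional[Sequence[str]] = None,
) -> CoxFit:
    """Cox proportional-hazards fit (Efron ties, Newton-Raphson).

    Constant covariates are dropped with a warning; a fit that fails to
    converge (including complete separation) is returned flagged rather
    than raising.
    """
    covariates = list(covariates) if covariates is not None else [
        c for c in frame.columns if c not in (duration_col, event_col)
    ]
    n_events = int(frame[event_col].sum())
    if n_events < 1:
        raise ValueError("at least one event is required")
    kept, dropped = [], []
    for cov in covariates:
        if frame[cov].nunique() < 2:
            dropped.append(cov)
            warnings.warn(f"dropping constant covariate {cov!r}", stacklevel=2)
        else:
            kept.append(cov)
    if not kept:
        raise ValueError("no non-constant covariates to fit")
    data = frame[[duration_col, event_col] + kept]

    fitter = CoxPHFitter()
    converged = True
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fitter.fit(data, duration_col=duration_col, event_col=event_col)
        converged = not any("onvergence" in str(w.message) for w in caught)
    except ConvergenceError:
        return CoxFit(
            effects=[], n_samples=len(data), n_events=n_events,
            converged=False, dropped_covariates=dropped,
        )

    summary = fitter.summary
    with np.errstate(over="ignore"):
        effects = [
            CovariateEffect(
                name=str(name),
                coef=float(row["coef"]),
                hazard_ratio=float(row["exp(coef)"]),
                se=float(row["se(coef)"]),
                p=float(row["p"]),
                ci_low=float(np.exp(row["coef lower 95%"])),
                ci_high=float(np.exp(row["coef upper 95%"])),
            )
            for name, row in summary.iterrows()
        ]
    return CoxFit(
        effects=effects, n_samples=len(data), n_events=n_events,
        converged=converged, dropped_covariates=dropped,
    )


def prepare_survival_frame(
    clinical: Sequence[ClinicalRecord],
    loss_flags: dict[str, bool],
    endpoint: str = "os",
) -> tuple[pd.DataFrame, int]:
    """Assemble the modelling frame for one endpoint (``os`` or ``efs``).

    Covariates: ``sca_loss`` (1 = target loss present), ``mycn``
    (1 = amplified), ``stage4`` (1 = INSS stage 4 vs 1/2/3/4S).
    Samples with unknown stage or MYCN status, or missing endpoint data,
    are dropped; the dropped count is returned alongside the frame.
    """
    if endpoint not in ("os", "efs"):
        raise ValueError("endpoint must be 'os' or 'efs'")
    rows, n_dropped = [], 0
    for rec in clinical:
        time = rec.os_time if endpoint == "os" else rec.efs_time
        event = rec.os_event if endpoint == "os" else rec.efs_event
        if (
            time is None or event is None or time <= 0
            or rec.inss_stage == UNKNOWN or rec.mycn_amplified == UNKNOWN
            or rec.sample_id not in loss_flags
        ):
            n_dropped += 1
            continue
        rows.append({
            "sample_id": rec.sample_id,
            "time": time,
            "event": event,
            "sca_loss": int(loss_flags[rec.sample_id]),
            "mycn": int(rec.mycn_amplified == "amplified"),
            "stage4": int(rec.inss_stage == "4"),
        })
    if n_dropped:
        logger.info("dropped %d samples with missing clinical data", n_dropped)
    return pd.DataFrame(rows), n_dropped


@dataclass
class GroupSurvival:
    label: str
    n: int
    n_events: int
    curve: KMCurve
    survival_5y: SurvivalPoint


def stratified_survival(
    frame: pd.DataFrame,
    group_col: str = "sca_loss",
    eval_time: float = 5.0,
) -> tuple[list[GroupSurvival], float, float]:
    """KM curves per group plus the two-group log-rank test.

    Returns ([group summaries], log-rank chi-square, p); groups are the
    two levels of ``group_col`` (absent first).
    """
    levels = sorted(frame[group_col].unique())
    if len(levels) != 2:
        raise ValueError(f"{group_col} must have exactly two levels, got {levels}")
    groups = []
    for level in levels:
        sub = frame[frame[group_col] == level]
        curve = kaplan_meier(sub["time"], sub["event"])
        groups.append(GroupSurvival(
            label=f"{group_col}={level}",
            n=len(sub),
            n_events=int(sub["event"].sum()),
            curve=curve,
            survival_5y=survival_at(curve, eval_time),
        ))
    sub0 = frame[frame[group_col] == levels[0]]
    sub1 = frame[frame[group_col] == levels[1]]
    chi2, p = logrank(sub0["time"], sub0["event"], sub1["time"], sub1["event"])
    return groups, chi2, p


def write_survival_report(
    groups: Sequence[GroupSurvival],
    logrank_chi2: float,
    logrank_p: float,
    cox: Optional[CoxFit],
    path: str | Path,
    eval_time: float = 5.0,
) -> None:
    payload = {
        "eval_time_years": eval_time,
        "groups": [
            {
                "label": g.label, "n": g.n, "events": g.n_events,
                "survival_at_eval": g.survival_5y.estimate,
                "greenwood_se": g.survival_5y.se,
                "extrapolated": g.survival_5y.extrapolated,
            }
            for g in groups
        ],
        "logrank_chi_square": logrank_chi2,
        "logrank_p": logrank_p,
        "cox": cox.to_dict() if cox is not None else None,
    }
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")


def plot_km(groups: Sequence[GroupSurvival], path: str | Path, title: str = "") -> None:
    """Step plot of the group KM curves (optional figure output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for group in groups:
        x = np.concatenate([[0.0], group.curve.event_times])
        y = np.concatenate([[1.0], group.curve.survival])
        ax.step(x, y, where="post", label=f"{group.label} (n={group.n})")
    ax.set_xlabel("years")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


__all__ = [
    "CovariateEffect", "CoxFit", "GroupSurvival", "KMCurve", "SurvivalPoint",
    "cox_ph", "kaplan_meier", "logrank", "plot_km", "prepare_survival_frame",
    "stratified_survival", "survival_at", "write_survival_report",
]
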