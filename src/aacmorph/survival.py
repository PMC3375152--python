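"""Cox-regression evaluation of the calcification markers.

The protocol mirrors how radiographic markers are typically benchmarked
against mortality in a prospective cohort:

* hazard ratios are reported per one-standard-deviation change of the raw
  marker (the marker is z-scored on the full analysis cohort before the
  fit, so the HR is invariant to affine rescaling of the raw values);
* deaths from causes outside the chosen endpoint are right-censored at the
  time of death, survivors at the administrative end of follow-up;
* "biological adjustment" first fits a Cox model on a set of biological
  covariates alone, combines them into a single composite via their
  beta-weights, and then fits the marker together with that composite;
* marker complementarity is probed by backwards stepwise deletion: all
  markers enter one model and the least significant is dropped until every
  remaining marker has Wald p below the significance level.

Event-time ties use the Efron approximation; p-values are Wald tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

DURATION_COL = "followup_years"
EVENT_COL = "event"

#: death-cause labels counted as events for each endpoint
ENDPOINTS = {
    "cvd": {"cvd"},
    "cvd_cancer": {"cvd", "cancer"},
    "all": {"cvd", "cancer", "other"},
}


@dataclass(frozen=True)
class CoxResult:
    """One marker's effect in one Cox model, per SD of the raw marker."""

    marker: str
    beta: float
    hr: float
    ci95: tuple[float, float]
    p_value: float
    n_events: int
    adjustment: str = "none"


@dataclass
class EliminationResult:
    """Outcome of backwards stepwise deletion."""

    retained: dict[str, CoxResult]
    deletion_order: list[tuple[str, float]]   # (marker, p at deletion)


def event_indicator(cohort: pd.DataFrame, endpoint: str) -> pd.Series:
    """1 for deaths whose cause belongs to the endpoint, else censored."""
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}; choose from {sorted(ENDPOINTS)}")
    causes = ENDPOINTS[endpoint]
    ev = cohort[EVENT_COL].astype(str).str.lower()
    return ev.isin(causes).astype(int)


def standardize(x: pd.Series) -> pd.Series:
    """z-score with the n-1 SD of the full analysis cohort."""
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd <= 0:
        raise ValueError(f"column {x.name!r} has zero variance; cannot standardize")
    return (x - x.mean()) / sd


def _fit(df: pd.DataFrame, covariates: list[str],
         penalizer: float = 0.0) -> CoxPHFitter:
    cph = CoxPHFitter(penalizer=penalizer)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df[[DURATION_COL, "_event"] + covariates],
                duration_col=DURATION_COL, event_col="_event")
    return cph


def _result_for(cph: CoxPHFitter, name: str, n_events: int,
                adjustment: str, report_as: str | None = None) -> CoxResult:
    beta = float(cph.params_[name])
    se = float(cph.standard_errors_[name])
    lo, hi = np.exp(beta - 1.959963984540054 * se), np.exp(beta + 1.959963984540054 * se)
    p = float(cph.summary.loc[name, "p"])
    return CoxResult(marker=report_as or name, beta=beta, hr=float(np.exp(beta)),
                     ci95=(float(lo), float(hi)), p_value=p,
                     n_events=n_events, adjustment=adjustment)


def _prepare(cohort: pd.DataFrame, endpoint: str) -> pd.DataFrame:
    df = cohort.copy()
    if (df[DURATION_COL] <= 0).any():
        raise ValueError("followup_years must be positive for every subject")
    df["_event"] = event_indicator(df, endpoint)
    n_events = int(df["_event"].sum())
    if n_events < 2:
        raise ValueError(f"endpoint {endpoint!r} has {n_events} event(s); need >= 2")
    return df


def fit_marker_cox(cohort: pd.DataFrame, marker: str,
                   endpoint: str = "all") -> CoxResult:
    """Unadjusted Cox fit of one marker, HR per SD."""
    df = _prepare(cohort, endpoint)
    zname = f"_z_{marker}"
    df[zname] = standardize(df[marker])
    cph = _fit(df, [zname])
    return _result_for(cph, zname, int(df["_event"].sum()), "none", report_as=marker)


def composite_adjusted_hr(cohort: pd.DataFrame, marker: str,
                          bio_set: list[str],
                          endpoint: str = "all") -> CoxResult:
    """Marker HR per SD after composite biological adjustment.

    The biological covariates are first fitted alone; their beta-weighted
    linear combination forms one composite variable, which then enters a
    second Cox model alongside the standardized marker.
    """
    df = _prepare(cohort, endpoint)
    for cov in bio_set:
        if cov not in df.columns:
            raise ValueError(f"missing biological covariate {cov!r}")
        if df[cov].std(ddof=1) <= 0:
            raise ValueError(f"biological covariate {cov!r} is degenerate")
    step1 = _fit(df, list(bio_set))
    weights = step1.params_[list(bio_set)]
    df["_composite"] = df[list(bio_set)].to_numpy() @ weights.to_numpy()
    zname = f"_z_{marker}"
    df[zname] = standardize(df[marker])
    corr = abs(np.corrcoef(df["_composite"], df[zname])[0, 1])
    penalizer = 0.0
    if corr > 0.999:
        warnings.warn(f"marker {marker!r} is collinear with the composite "
                      f"(|corr| = {corr:.4f}); adjusted effect is degenerate "
                      f"and fitted with a small ridge penalty")
        # a singular partial likelihood cannot be maximized; the ridge
        # splits the shared effect between the collinear columns
        penalizer = 1e-2
    cph = _fit(df, ["_composite", zname], penalizer=penalizer)
    return _result_for(cph, zname, int(df["_event"].sum()),
                       "+".join(bio_set), report_as=marker)


def backward_eliminate(cohort: pd.DataFrame, markers: list[str],
                       alpha: float = 0.05,
                       endpoint: str = "all") -> EliminationResult:
    """Backwards stepwise deletion over a set of standardized markers.

    All markers enter one Cox model; the marker with the largest Wald p is
    deleted (one per iteration, no re-entry) until every remaining marker
    has p < ``alpha`` or none remain.  Perfectly collinear duplicates are
    dropped (later-listed one) before iterating.
    """
    if not markers:
        raise ValueError("need at least one marker")
    df = _prepare(cohort, endpoint)
    znames: dict[str, str] = {}
    for m in markers:
        zn = f"_z_{m}"
        df[zn] = standardize(df[m])
        znames[m] = zn

    active = list(markers)
    corr = df[[znames[m] for m in active]].corr().to_numpy()
    drop_first = set()
    for i in range(len(active)):
        for j in range(i + 1, len(active)):
            if abs(corr[i, j]) > 0.999 and active[j] not in drop_first:
                warnings.warn(f"marker {active[j]!r} perfectly collinear with "
                              f"{active[i]!r}; dropped before elimination")
                drop_first.add(active[j])
    active = [m for m in active if m not in drop_first]

    deletion_order: list[tuple[str, float]] = [(m, float("nan")) for m in drop_first]
    cph = None
    while active:
        cph = _fit(df, [znames[m] for m in active])
        pvals = {m: float(cph.summary.loc[znames[m], "p"]) for m in active}
        worst = max(active, key=lambda m: pvals[m])
        if pvals[worst] < alpha:
            break
        deletion_order.append((worst, pvals[worst]))
        active.remove(worst)
        cph = None

    retained: dict[str, CoxResult] = {}
    if active:
        if cph is None:
            cph = _fit(df, [znames[m] for m in active])
        n_events = int(df["_event"].sum())
        for m in active:
            retained[m] = _result_for(cph, znames[m], n_events,
                                      "combined-model", report_as=m)
    return EliminationResult(retained=retained, deletion_order=deletion_order)


def marker_evaluation_table(cohort: pd.DataFrame, markers: list[str],
                            endpoints: list[str] = ("cvd", "cvd_cancer"),
                            bio_sets: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Unadjusted and composite-adjusted HR per SD for each marker and
    endpoint; one row per (marker, endpoint, adjustment)."""
    rows = []
    bio_sets = bio_sets or {}
    for marker in markers:
        for ep in endpoints:
            res = fit_marker_cox(cohort, marker, ep)
            rows.append((marker, ep, "none", res.hr, *res.ci95, res.p_value))
            for label, bset in bio_sets.items():
                res = composite_adjusted_hr(cohort, marker, bset, ep)
                rows.append((marker, ep, label, res.hr, *res.ci95, res.p_value))
    return pd.DataFrame(rows, columns=["marker", "endpoint", "adjustment",
                                       "hr_per_sd", "ci_low", "ci_high", "p"])
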