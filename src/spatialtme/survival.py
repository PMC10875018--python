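"""Median-split stratification, Kaplan-Meier / log-rank, and Cox modelling.

Patients are dichotomized at the cohort median of a spatial metric:
strictly above the median is "high", at or below is "low" (ties go to
low).  Group survival is compared by the Kaplan-Meier product-limit
estimator and the log-rank (Mantel-Cox) test.  Prognostic analysis is
univariate Cox proportional hazards per covariate (Wald test, Efron
handling of tied event times), followed by a multivariate model over
exactly the covariates with univariate p strictly below alpha (default
0.05).

Clinical covariates are encoded the conventional way for colon-cancer
cohorts: age continuous; male vs female; right- vs left-sided; adjuvant
yes vs no; AJCC stage III/IV vs I/II; MSI-H vs MSS; CMS2-4/Mixed dummies
against CMS1; ICR Medium/High vs Low; each spatial metric High vs Low.

Estimation is delegated to lifelines; Schoenfeld-residual proportional-
hazards diagnostics are reported alongside the fits but never alter them.
OS and PFS are analyzed independently; competing risks are not modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import logrank_test, proportional_hazard_test

__all__ = [
    "median_split",
    "km_estimate",
    "logrank",
    "cox_fit",
    "select_multivariate",
    "CoxResult",
    "encode_clinical_covariates",
    "run_survival_analysis",
]


def median_split(values: pd.Series) -> tuple[pd.Series, float]:
    """Dichotomize patients at the cohort median of a metric.

    Returns ``(groups, cutoff)`` where groups maps patient -> "high"
    (value > median) or "low" (value <= median); missing values are
    excluded.  Raises on fewer than 2 non-missing values or a degenerate
    (constant) metric.
    """
    v = pd.Series(values).astype(float).dropna()
    if len(v) < 2:
        raise ValueError("median split needs >= 2 non-missing values")
    cutoff = float(v.median())
    if v.nunique() == 1:
        raise ValueError("degenerate stratification: all metric values identical")
    groups = pd.Series(np.where(v > cutoff, "high", "low"), index=v.index, name="group")
    return groups, cutoff


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve.

    Returns one row per distinct observed time: ``time, survival,
    at_risk, n_events`` — steps occur only at event times; censored times
    reduce the risk set without a step.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if times.size == 0:
        raise ValueError("km_estimate: empty input")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table.iloc[1:] if 0.0 not in times else kmf.event_table
    # drop the automatically inserted t=0 row unless observed
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame({
        "time": table.index.to_numpy(dtype=float),
        "survival": surv.reindex(table.index).to_numpy(dtype=float),
        "at_risk": table["at_risk"].to_numpy(dtype=int),
        "n_events": table["observed"].to_numpy(dtype=int),
    }).reset_index(drop=True)
    return out


def logrank(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank (Mantel-Cox) test; returns (chi2, p), 1 df."""
    res = logrank_test(
        np.asarray(times_a, float), np.asarray(times_b, float),
        event_observed_A=np.asarray(events_a).astype(int),
        event_observed_B=np.asarray(events_b).astype(int),
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    """A fitted Cox proportional-hazards model.

    ``summary`` has one row per covariate: ``covariate, coef, se, hr,
    ci_low, ci_high, p`` (hazard ratios with 95% Wald intervals,
    ``exp(coef +- 1.96 se)``).  ``flags`` collects convergence /
    collinearity warnings; ``ph_test_p`` holds Schoenfeld-residual
    proportionality p-values (reported, never gating).
    """

    summary: pd.DataFrame
    n: int
    n_events: int
    converged: bool
    flags: list[str] = field(default_factory=list)
    ph_test_p: dict[str, float] = field(default_factory=dict)


def cox_fit(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str] | None = None,
) -> CoxResult:
    """Cox proportional-hazards fit with Efron tie handling and Wald tests.

    Non-convergence or separation/collinearity is reported via
    ``CoxResult.flags`` and ``converged``; a low-variance or duplicated
    covariate is flagged rather than silently dropped.
    """
    covariates = list(covariates) if covariates is not None else [
        c for c in data.columns if c not in (duration_col, event_col)
    ]
    df = data[[duration_col, event_col] + covariates].dropna()
    n, n_events = len(df), int(df[event_col].sum())
    if n_events < len(covariates) + 1:
        raise ValueError(
            f"too few events ({n_events}) for {len(covariates)} covariate(s)"
        )
    flags: list[str] = []
    X = df[covariates].astype(float)
    # exact collinearity (e.g. a duplicated covariate) makes the partial
    # likelihood unidentifiable; detect it up front
    if len(covariates) > 1 and np.linalg.matrix_rank(X.to_numpy()) < len(covariates):
        flags.append("collinear_covariates")
    cph = CoxPHFitter()  # lifelines default tie handling is Efron
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col=duration_col, event_col=event_col)
        except ConvergenceError as err:
            return CoxResult(
                summary=pd.DataFrame(
                    columns=["covariate", "coef", "se", "hr", "ci_low", "ci_high", "p"]
                ),
                n=n, n_events=n_events, converged=False,
                flags=flags + [f"convergence_error: {err}"],
            )
        for w in caught:
            if issubclass(w.category, ConvergenceWarning):
                flags.append(f"convergence_warning: {w.message}")
                converged = False

    s = cph.summary
    summary = pd.DataFrame({
        "covariate": s.index.to_numpy(),
        "coef": s["coef"].to_numpy(),
        "se": s["se(coef)"].to_numpy(),
        "hr": s["exp(coef)"].to_numpy(),
        "ci_low": s["exp(coef) lower 95%"].to_numpy(),
        "ci_high": s["exp(coef) upper 95%"].to_numpy(),
        "p": s["p"].to_numpy(),
    }).reset_index(drop=True)

    ph_p: dict[str, float] = {}
    if converged and n_events > len(covariates) + 1:
        try:
            pht = proportional_hazard_test(cph, df, time_transform="rank")
            ph_p = {str(k): float(v) for k, v in pht.summary["p"].items()}
        except Exception as err:  # diagnostics must never fail the fit
            flags.append(f"ph_test_failed: {err}")
    return CoxResult(summary=summary, n=n, n_events=n_events,
                     converged=converged, flags=flags, ph_test_p=ph_p)


def select_multivariate(univariate: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Covariates entering the multivariate model: univariate Wald p
    strictly below ``alpha`` (a boundary p == alpha is excluded)."""
    sig = univariate[univariate["p"] < alpha]
    return sig["covariate"].tolist()


def encode_clinical_covariates(clinical: pd.DataFrame) -> pd.DataFrame:
    """Numeric covariate design for Cox models (see module docstring)."""
    c = clinical.set_index("patient_id")
    out = pd.DataFrame(index=c.index)
    out["age"] = c["age"].astype(float)
    out["sex_male"] = (c["sex"] == "M").astype(float)
    out["side_right"] = (c["side"] == "right").astype(float)
    out["adjuvant_yes"] = c["adjuvant"].astype(float)
    out["ajcc_III_IV"] = c["ajcc"].isin(["III", "IV"]).astype(float)
    out["msi_high"] = (c["msi"] == "MSI-H").astype(float)
    for cms in ("CMS2", "CMS3", "CMS4", "Mixed"):
        out[f"cms_{cms}"] = (c["cms"] == cms).astype(float)
    out["icr_medium_high"] = c["icr"].isin(["Medium", "High"]).astype(float)
    return out


def run_survival_analysis(
    metric_wide: pd.DataFrame,
    clinical: pd.DataFrame,
    metrics: list[str],
    endpoint: str = "pfs",
    alpha: float = 0.05,
) -> dict:
    """Median-split each metric, then univariate -> multivariate Cox.

    ``endpoint`` is ``"os"`` or ``"pfs"``.  Returns a dict with:

    * ``km``: per metric, the two KM curves, group sizes and log-rank p;
    * ``univariate``: one-covariate Cox fits stacked into one table
      (clinical covariates plus each metric's high-vs-low indicator);
    * ``selected``: covariates with univariate p < alpha;
    * ``multivariate``: the joint fit over the selected covariates
      (None when nothing is selected).
    """
    if endpoint not in ("os", "pfs"):
        raise ValueError("endpoint must be 'os' or 'pfs'")
    dur, ev = f"{endpoint}_time", f"{endpoint}_event"
    surv = clinical.set_index("patient_id")[[dur, ev]].astype(
        {dur: float, ev: int}
    )
    design = encode_clinical_covariates(clinical)

    km_results: dict[str, dict] = {}
    cutoffs: dict[str, float] = {}
    for metric in metrics:
        if metric not in metric_wide.columns:
            raise KeyError(f"metric {metric!r} not in metric table")
        groups, cutoff = median_split(metric_wide[metric])
        cutoffs[metric] = cutoff
        aligned = groups.reindex(surv.index).dropna()
        hi = surv.loc[aligned[aligned == "high"].index]
        lo = surv.loc[aligned[aligned == "low"].index]
        chi2, p = logrank(hi[dur], hi[ev], lo[dur], lo[ev])
        km_results[metric] = {
            "cutoff": cutoff,
            "n_high": len(hi),
            "n_low": len(lo),
            "logrank_chi2": chi2,
            "logrank_p": p,
            "km_high": km_estimate(hi[dur], hi[ev]),
            "km_low": km_estimate(lo[dur], lo[ev]),
        }
        design[f"{metric}_high"] = (
            groups.reindex(design.index) == "high"
        ).astype(float).where(groups.reindex(design.index).notna())

    data = design.join(surv, how="inner")
    uni_rows = []
    for cov in design.columns:
        try:
            res = cox_fit(data.dropna(subset=[cov]), dur, ev, [cov])
        except ValueError as err:
            uni_rows.append({"covariate": cov, "coef": np.nan, "se": np.nan,
                             "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                             "p": np.nan, "flag": str(err)})
            continue
        row = res.summary.iloc[0].to_dict() if len(res.summary) else {
            "covariate": cov, "coef": np.nan, "se": np.nan, "hr": np.nan,
            "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
        }
        row["flag"] = ";".join(res.flags)
        uni_rows.append(row)
    univariate = pd.DataFrame(uni_rows)

    selected = select_multivariate(univariate.dropna(subset=["p"]), alpha=alpha)
    multivariate = None
    if selected:
        multivariate = cox_fit(data.dropna(subset=selected), dur, ev, selected)
    return {
        "endpoint": endpoint,
        "cutoffs": cutoffs,
        "km": km_results,
        "univariate": univariate,
        "selected": selected,
        "multivariate": multivariate,
    }
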