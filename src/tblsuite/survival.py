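"""Dichotomized survival analysis of a genomic-instability measure.

Samples are split into high and low at the threshold maximizing
Youden's J (sensitivity + specificity - 1) for predicting the
endpoint's event indicator, the convention being that a high measure
predicts the event. Prognosis is quantified per cancer type with
Kaplan-Meier curves and the log-rank test, and with a multivariate Cox
proportional-hazards model (Efron ties) adjusting for age, sex and
ordinal tumor stage. Disease-free-survival cohorts default to
localized (stage I-III), microsatellite-stable, untreated samples;
a treated-only mode reproduces the chemo/radiotherapy subset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test, multivariate_logrank_test

logger = logging.getLogger(__name__)

__all__ = [
    "NonEstimableError",
    "DichotomyThreshold",
    "SurvivalFit",
    "KMResult",
    "youden_threshold",
    "km_logrank",
    "cox_multivariate",
    "select_cohort",
    "survival_analysis",
]

STAGE_NUMERIC = {"I": 1, "II": 2, "III": 3, "IV": 4}


class NonEstimableError(RuntimeError):
    """The requested model cannot be estimated from the given data."""


@dataclass(frozen=True)
class DichotomyThreshold:
    measure: str
    threshold: float
    youden_j: float
    cancer_type: str | None = None


@dataclass
class SurvivalFit:
    endpoint: str
    hr: float
    ci_low: float
    ci_high: float
    wald_p: float
    logrank_p: float
    n: int
    n_events: int
    median_high: float
    median_low: float
    covariates: tuple
    estimable: bool = True
    note: str = ""


@dataclass
class KMResult:
    curves: dict           # group label -> DataFrame(time, survival)
    statistic: float
    p: float


def youden_threshold(values, events, measure: str = "measure",
                     cancer_type: str | None = None) -> DichotomyThreshold:
    """Threshold maximizing Youden's J for the event indicator.

    All midpoints between adjacent distinct values are candidate cuts;
    a value at or above the cut predicts an event. Ties in J are broken
    toward the lower threshold. Requires both event classes.
    """
    v = np.asarray(values, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(np.unique(e)) < 2:
        raise NonEstimableError("both event classes are required for a ROC threshold")
    uniq = np.unique(v)
    if len(uniq) < 2:
        raise NonEstimableError("measure is constant; no threshold exists")
    cand = (uniq[:-1] + uniq[1:]) / 2.0
    pos, neg = v[e == 1], v[e == 0]
    sens = (pos[None, :] >= cand[:, None]).mean(axis=1)
    spec = (neg[None, :] < cand[:, None]).mean(axis=1)
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # first max = lowest threshold
    return DichotomyThreshold(measure, float(cand[best]), float(j[best]), cancer_type)


def km_logrank(times, events, groups) -> KMResult:
    """Kaplan-Meier curves per group plus the log-rank test."""
    df = pd.DataFrame({"time": np.asarray(times, dtype=float),
                       "event": np.asarray(events, dtype=int),
                       "group": np.asarray(groups)})
    if df["event"].sum() == 0:
        raise NonEstimableError("no events observed; the log-rank test is undefined")
    labels = pd.unique(df["group"])
    if len(labels) < 2:
        raise NonEstimableError("need at least two groups")
    curves = {}
    for g in labels:
        sub = df[df["group"] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(g))
        curves[g] = pd.DataFrame({
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
        })
    if len(labels) == 2:
        a, b = labels
        res = logrank_test(df.loc[df["group"] == a, "time"],
                           df.loc[df["group"] == b, "time"],
                           df.loc[df["group"] == a, "event"],
                           df.loc[df["group"] == b, "event"])
    else:
        res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return KMResult(curves, float(res.test_statistic), float(res.p_value))


def _km_median(times, events) -> float:
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    return float(kmf.median_survival_time_)


def cox_multivariate(times, events, high, covariates: pd.DataFrame | None = None,
                     endpoint: str = "os") -> SurvivalFit:
    """Multivariate Cox PH fit of the high/low indicator with covariates.

    ``covariates`` may hold ``age`` (numeric), ``sex`` (male/female) and
    ``stage`` (I-IV, entered as ordinal numeric). The hazard ratio is
    ``exp(coef)`` of the high indicator with its Wald CI and p-value; a
    two-group log-rank p is reported alongside. A constant group
    indicator raises :class:`NonEstimableError`; non-convergence or a
    monotone likelihood is returned as a non-estimable fit (the "-"
    entries of a results table).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(high, dtype=bool)
    if g.all() or not g.any():
        raise NonEstimableError("group indicator is constant; HR non-estimable")
    if e.sum() == 0:
        raise NonEstimableError("no events observed")
    df = pd.DataFrame({"time": t, "event": e, "high": g.astype(float)})
    used = ["high"]
    if covariates is not None:
        cov = covariates.reset_index(drop=True)
        if "age" in cov:
            df["age"] = cov["age"].astype(float).to_numpy()
        if "sex" in cov:
            df["sex"] = (cov["sex"].astype(str).str.lower() == "male").astype(float).to_numpy()
        if "stage" in cov:
            df["stage"] = cov["stage"].map(STAGE_NUMERIC).astype(float).to_numpy()
        for c in ("age", "sex", "stage"):
            if c in df.columns:
                if df[c].isna().any() or df[c].nunique() < 2:
                    logger.info("covariate %s dropped (constant or missing)", c)
                    df = df.drop(columns=c)
                else:
                    used.append(c)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, ValueError, np.linalg.LinAlgError) as err:
        return SurvivalFit(endpoint, np.nan, np.nan, np.nan, np.nan, np.nan,
                           len(df), int(e.sum()), np.nan, np.nan, tuple(used),
                           estimable=False, note=f"non-estimable: {err}")
    coef = float(cph.params_["high"])
    se = float(cph.standard_errors_["high"])
    if not np.isfinite(se) or se > 50:
        return SurvivalFit(endpoint, np.nan, np.nan, np.nan, np.nan, np.nan,
                           len(df), int(e.sum()), np.nan, np.nan, tuple(used),
                           estimable=False, note="non-estimable: infinite confidence interval")
    lr = logrank_test(t[g], t[~g], e[g], e[~g])
    return SurvivalFit(
        endpoint=endpoint,
        hr=float(np.exp(coef)),
        ci_low=float(np.exp(coef - 1.959963984540054 * se)),
        ci_high=float(np.exp(coef + 1.959963984540054 * se)),
        wald_p=float(cph.summary.loc["high", "p"]),
        logrank_p=float(lr.p_value),
        n=len(df), n_events=int(e.sum()),
        median_high=_km_median(t[g], e[g]),
        median_low=_km_median(t[~g], e[~g]),
        covariates=tuple(used),
    )


def select_cohort(clinical: pd.DataFrame, endpoint: str = "dfs",
                  stage_max: str | None = "III", mss_only: bool = True,
                  treatment: str = "untreated") -> pd.DataFrame:
    """Cohort filter for survival analyses.

    The DFS defaults keep localized (stage I-III) MSS untreated
    samples; ``treatment='treated'`` selects the chemo/radiotherapy
    subset instead, ``'any'`` disables the filter. For OS pass
    ``stage_max=None, mss_only=False, treatment='any'``.
    """
    df = clinical.copy()
    if stage_max is not None:
        keep = [s for s, v in STAGE_NUMERIC.items() if v <= STAGE_NUMERIC[stage_max]]
        df = df[df["stage"].isin(keep)]
    if mss_only:
        df = df[df["msi_status"] == "MSS"]
    if treatment == "untreated":
        df = df[~df["treated"].astype(bool)]
    elif treatment == "treated":
        df = df[df["treated"].astype(bool)]
    elif treatment != "any":
        raise ValueError("treatment must be 'untreated', 'treated' or 'any'")
    df = df.dropna(subset=[f"{endpoint}_time", f"{endpoint}_event"])
    return df.reset_index(drop=True)


def survival_analysis(measures: pd.DataFrame, clinical: pd.DataFrame,
                      measure: str = "tbl", endpoint: str = "dfs",
                      stage_max: str | None = "III", mss_only: bool = True,
                      treatment: str = "untreated",
                      min_samples: int = 20) -> pd.DataFrame:
    """Per-cancer-type dichotomized survival table (HR, CI, p).

    The Youden threshold is computed per cancer type from the endpoint's
    event indicator within the filtered cohort.
    """
    cohort = select_cohort(clinical, endpoint, stage_max, mss_only, treatment)
    df = cohort.merge(measures[["sample_id", measure]], on="sample_id")
    rows = []
    for ct, grp in df.groupby("cancer_type"):
        if len(grp) < min_samples:
            logger.info("%s skipped: fewer than %d samples", ct, min_samples)
            continue
        t = grp[f"{endpoint}_time"].to_numpy()
        e = grp[f"{endpoint}_event"].to_numpy().astype(int)
        try:
            thr = youden_threshold(grp[measure], e, measure, ct)
            high = grp[measure].to_numpy() >= thr.threshold
            fit = cox_multivariate(t, e, high, grp[["age", "sex", "stage"]], endpoint)
        except NonEstimableError as err:
            logger.info("%s: %s", ct, err)
            continue
        rows.append({
            "cancer_type": ct, "measure": measure, "endpoint": endpoint,
            "n": fit.n, "n_events": fit.n_events,
            "threshold": thr.threshold, "youden_j": thr.youden_j,
            "hr": fit.hr, "ci_low": fit.ci_low, "ci_high": fit.ci_high,
            "wald_p": fit.wald_p, "logrank_p": fit.logrank_p,
            "median_high": fit.median_high, "median_low": fit.median_low,
            "estimable": fit.estimable,
        })
    return pd.DataFrame(rows)
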