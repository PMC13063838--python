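"""Survival evaluation of the radiomic risk model and the PRF analyses.

Covers the validation stage of the analysis: Kaplan-Meier curves and
log-rank tests per risk group, univariate and backward-eliminated
multivariate Cox proportional-hazards models, time-dependent AUC on a
6-month grid (cumulative/dynamic definition with inverse-probability-of-
censoring weighting), and the two analyses of the prognostic radiomic
feature (PRF, the directional SD of GLCM homogeneity at offset 3 on T2 in
the core VOI): the cross-cohort cutoff-range scan and the three-group
stratification with Bonferroni-corrected pairwise tests.

Standard estimators are delegated to lifelines (Kaplan-Meier, log-rank,
Cox) and scikit-survival (IPCW time-dependent AUC).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


DEFAULT_PRF_LOW_CUT = 0.0145
DEFAULT_PRF_HIGH_CUT = 0.018
DEFAULT_SCAN_STEP = 0.0005


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([r.__dict__ for r in records])


def kaplan_meier_by_group(records, group_labels) -> dict[str, dict]:
    """Product-limit survival curve and KM median per group.

    The median may be +inf when a group's curve never reaches 0.5.
    """
    df = _as_frame(records)
    groups = np.asarray(group_labels)
    if len(df) == 0 or len(groups) == 0:
        raise EvaluationError("no records to fit survival curves on")
    out: dict[str, dict] = {}
    for g in pd.unique(groups):
        sel = groups == g
        if not sel.any():
            raise EvaluationError(f"group '{g}' is empty")
        kmf = KaplanMeierFitter(label=str(g))
        kmf.fit(df.loc[sel, "os_months"], df.loc[sel, "event"])
        out[str(g)] = {
            "curve": kmf.survival_function_,
            "median": float(kmf.median_survival_time_),
            "n": int(sel.sum()),
            "fitter": kmf,
        }
    return out


def log_rank(records, group_labels) -> tuple[float, float]:
    """K-sample log-rank test; returns (chi-square statistic, p-value)."""
    df = _as_frame(records)
    groups = np.asarray(group_labels)
    if len(pd.unique(groups)) < 2:
        raise EvaluationError("log-rank needs at least two groups")
    if df["event"].sum() < 1:
        raise EvaluationError("log-rank needs at least one event")
    res = multivariate_logrank_test(df["os_months"], groups, df["event"])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    variable: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    coef: float
    n: int
    reference_level: str = "0"


def _fit_cox(df: pd.DataFrame, covariates: list[str]) -> tuple[CoxPHFitter, pd.DataFrame]:
    data = df[["os_months", "event", *covariates]].dropna()
    if data.empty:
        raise EvaluationError("no complete-case records for the Cox model")
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(data, duration_col="os_months", event_col="event")
    return cph, data


def _cox_results(cph: CoxPHFitter, n: int) -> list[CoxResult]:
    s = cph.summary
    return [
        CoxResult(
            variable=str(idx),
            hr=float(row["exp(coef)"]),
            ci_low=float(row["exp(coef) lower 95%"]),
            ci_high=float(row["exp(coef) upper 95%"]),
            p=float(row["p"]),
            coef=float(row["coef"]),
            n=n,
        )
        for idx, row in s.iterrows()
    ]


def cox_univariate(records, variable: str) -> CoxResult:
    """Univariate proportional-hazards fit; HR with Wald 95% CI and p.

    Records missing the covariate are dropped for this model only.
    """
    df = _as_frame(records)
    sub = df[["os_months", "event", variable]].dropna()
    if sub[variable].nunique() < 2:
        raise EvaluationError(f"variable '{variable}' is degenerate after dropping NAs")
    cph, data = _fit_cox(sub, [variable])
    return _cox_results(cph, len(data))[0]


@dataclass
class BackwardEliminationResult:
    final: list[CoxResult]
    trace: list[dict] = field(default_factory=list)

    @property
    def variables(self) -> list[str]:
        return [r.variable for r in self.final]


def cox_multivariate_backward(
    records,
    candidate_variables: list[str],
    removal_threshold: float = 0.05,
    criterion: str = "wald_p",
) -> BackwardEliminationResult:
    """Multivariate Cox with backward elimination.

    With ``criterion="wald_p"`` (default) the variable with the largest
    Wald p is removed while that p exceeds ``removal_threshold``, refitting
    after each removal; with ``criterion="aic"`` the removal that most
    improves the partial-likelihood AIC is taken while any removal improves
    it.  Complete-case records over the candidate set.  All variables
    eliminated gives an empty final model with the full trace.
    """
    df = _as_frame(records)
    if not candidate_variables:
        raise EvaluationError("need at least one candidate variable")
    data = df[["os_months", "event", *candidate_variables]].dropna()
    current = [v for v in candidate_variables if data[v].nunique() > 1]
    dropped_degenerate = sorted(set(candidate_variables) - set(current))
    trace: list[dict] = [
        {"step": 0, "removed": v, "p": float("nan"), "reason": "degenerate"}
        for v in dropped_degenerate
    ]
    if criterion not in ("wald_p", "aic"):
        raise EvaluationError(f"unknown elimination criterion '{criterion}'")
    step = 0
    while current:
        cph, fitted = _fit_cox(data, current)
        if criterion == "wald_p":
            pvals = cph.summary["p"]
            worst = str(pvals.idxmax())
            if pvals[worst] <= removal_threshold:
                return BackwardEliminationResult(
                    final=_cox_results(cph, len(fitted)), trace=trace
                )
            detail = float(pvals[worst])
            reason = "p>threshold"
        else:
            base_aic = float(cph.AIC_partial_)
            best_aic, worst = np.inf, None
            for v in current:
                reduced = [u for u in current if u != v]
                if not reduced:
                    # dropping the last variable: null model, AIC 2*0 - 2*ll0
                    continue
                sub, _ = _fit_cox(data, reduced)
                if float(sub.AIC_partial_) < best_aic:
                    best_aic, worst = float(sub.AIC_partial_), v
            if worst is None or best_aic >= base_aic:
                return BackwardEliminationResult(
                    final=_cox_results(cph, len(fitted)), trace=trace
                )
            detail = best_aic
            reason = "aic improves"
        step += 1
        trace.append({"step": step, "removed": worst, "p": detail, "reason": reason})
        current = [v for v in current if v != worst]
    return BackwardEliminationResult(final=[], trace=trace)


def cox_risk_score(records, covariates: list[str]) -> pd.Series:
    """Linear predictor from a Cox fit on the given covariates.

    Used to build the "with RBR" / "without RBR" risk scores fed to the
    time-dependent AUC comparison.
    """
    df = _as_frame(records).reset_index(drop=True)
    cph, data = _fit_cox(df, covariates)
    scores = cph.predict_partial_hazard(df[covariates]).apply(np.log)
    scores.index = df.index
    return scores


@dataclass
class TimeAUCSeries:
    times: np.ndarray
    auc: np.ndarray  # NaN where not evaluable
    model_tag: str = ""


def six_month_grid(records, step: float = 6.0) -> np.ndarray:
    """Evaluation times every ``step`` months within the follow-up range."""
    df = _as_frame(records)
    tmax = float(df["os_months"].max())
    return np.arange(step, tmax, step)


def time_dependent_auc(records, risk_score, grid=None, model_tag: str = "") -> TimeAUCSeries:
    """Cumulative/dynamic AUC with IPCW at each grid time.

    Cases are subjects with an observed event by time t, controls those
    still at risk beyond t; censoring is handled by inverse-probability-of-
    censoring weights estimated from the same records.  Grid points where
    no comparable pair exists (or outside the follow-up range) yield NaN.
    """
    df = _as_frame(records)
    times = six_month_grid(df) if grid is None else np.asarray(grid, dtype=float)
    if times.size == 0:
        raise EvaluationError("empty evaluation grid")
    score = np.asarray(risk_score, dtype=float)
    surv = Surv.from_arrays(event=df["event"].astype(bool), time=df["os_months"])
    aucs = np.full(times.shape, np.nan)
    for i, t in enumerate(times):
        try:
            a, _ = cumulative_dynamic_auc(surv, surv, score, [t])
            aucs[i] = float(a[0])
        except ValueError as exc:
            logger.debug("AUC not evaluable at t=%.1f: %s", t, exc)
    return TimeAUCSeries(times=times, auc=aucs, model_tag=model_tag)


# --- PRF analyses ---------------------------------------------------------


@dataclass
class PrfThresholds:
    """Three-group PRF cutpoints; defaults are the published pair."""

    low_cut: float = DEFAULT_PRF_LOW_CUT
    high_cut: float = DEFAULT_PRF_HIGH_CUT

    def __post_init__(self) -> None:
        if not self.low_cut < self.high_cut:
            raise EvaluationError("low_cut must be below high_cut")


@dataclass
class CutoffScanResult:
    grid: np.ndarray
    p_values: pd.DataFrame  # cohorts x grid, NaN = non-evaluable
    common_significant_interval: tuple[float, float] | None


def prf_cutoff_scan(
    cohorts: dict[str, pd.DataFrame],
    feature: str,
    grid: np.ndarray | None = None,
    alpha: float = 0.05,
    step: float = DEFAULT_SCAN_STEP,
) -> CutoffScanResult:
    """Scan dichotomization cutoffs for simultaneous significance.

    For each candidate cutoff, every cohort is split at the cutoff and a
    two-group log-rank test run; the result is the maximal contiguous grid
    interval on which all cohorts are simultaneously significant at
    ``alpha`` (None when no such cutoff exists).  A cutoff outside a
    cohort's observed feature range, or leaving a side empty, is
    non-evaluable there.  The default grid steps by ``step`` across the
    pooled observed range.
    """
    if not cohorts:
        raise EvaluationError("need at least one cohort")
    if grid is None:
        pooled = np.concatenate([np.asarray(c[feature], dtype=float) for c in cohorts.values()])
        lo = np.floor(pooled.min() / step) * step
        hi = np.ceil(pooled.max() / step) * step
        grid = np.arange(lo + step, hi, step)
    grid = np.asarray(grid, dtype=float)
    pmat = pd.DataFrame(np.nan, index=sorted(cohorts), columns=grid)
    for name in sorted(cohorts):
        df = cohorts[name]
        x = df[feature].to_numpy(dtype=float)
        for c in grid:
            if c <= x.min() or c > x.max():
                continue
            hi_grp = x >= c
            if df.loc[hi_grp, "event"].sum() + df.loc[~hi_grp, "event"].sum() < 1:
                continue
            try:
                _, p = log_rank(df, np.where(hi_grp, "hi", "lo"))
            except EvaluationError:
                continue
            pmat.loc[name, c] = p
    sig = (pmat < alpha).all(axis=0).to_numpy()
    interval = None
    best_len = 0
    i = 0
    while i < len(grid):
        if sig[i]:
            j = i
            while j + 1 < len(grid) and sig[j + 1]:
                j += 1
            if j - i + 1 > best_len:
                best_len = j - i + 1
                interval = (float(grid[i]), float(grid[j]))
            i = j + 1
        else:
            i += 1
    return CutoffScanResult(grid=grid, p_values=pmat, common_significant_interval=interval)


@dataclass
class ThreeGroupResult:
    labels: pd.Series  # Low / Mid / High per patient
    overall_chi2: float | None
    overall_p: float | None
    pairwise_p: dict[str, float]  # Bonferroni-corrected, capped at 1
    group_counts: dict[str, int]


def prf_three_group(
    records, feature: str, thresholds: PrfThresholds | None = None
) -> ThreeGroupResult:
    """Stratify by PRF into Low / Mid / High and test survival differences.

    Low < low_cut <= Mid < high_cut <= High.  The overall test is the
    k-group log-rank; pairwise log-rank p-values are Bonferroni-multiplied
    by 3 and capped at 1.  If fewer than two groups are populated the tests
    degrade gracefully (None / empty) with a warning.
    """
    thr = thresholds or PrfThresholds()
    df = _as_frame(records).reset_index(drop=True)
    x = df[feature].to_numpy(dtype=float)
    if np.isnan(x).all():
        raise EvaluationError(f"feature column '{feature}' is empty")
    labels = pd.Series(
        np.where(x < thr.low_cut, "Low", np.where(x < thr.high_cut, "Mid", "High")),
        index=df.index,
        name="prf_group",
    )
    counts = labels.value_counts().to_dict()
    present = [g for g in ("Low", "Mid", "High") if counts.get(g, 0) > 0]
    if len(present) < 2:
        logger.warning("only %d PRF group(s) populated; no test run", len(present))
        return ThreeGroupResult(labels, None, None, {}, counts)
    if len(present) < 3:
        logger.warning("PRF group(s) %s empty; degrading to %d groups",
                       sorted(set(("Low", "Mid", "High")) - set(present)), len(present))
    chi2, p = log_rank(df, labels.to_numpy())
    pairwise: dict[str, float] = {}
    for a, b in (("Low", "Mid"), ("Mid", "High"), ("Low", "High")):
        if counts.get(a, 0) == 0 or counts.get(b, 0) == 0:
            continue
        sel = labels.isin([a, b]).to_numpy()
        try:
            _, praw = log_rank(df.loc[sel], labels[sel].to_numpy())
        except EvaluationError:
            continue
        pairwise[f"{a}_vs_{b}"] = min(1.0, 3.0 * praw)
    return ThreeGroupResult(labels, chi2, p, pairwise, counts)
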