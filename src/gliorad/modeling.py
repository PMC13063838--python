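"""Risk-model training: median-survival dichotomization and the CV-LASSO
majority-vote ensemble.

The training recipe has three parts:

1. Overall survival is dichotomized at the cohort's Kaplan-Meier median
   survival time (MST): deaths and long follow-ups at or beyond the MST are
   "long OS", deaths before it "short OS", and censored cases with
   follow-up shorter than the MST are excluded as unlabelable
   (:func:`dichotomize_os`, :func:`apply_d1_filter`).
2. An L1-penalized (LASSO) logistic regression of short-vs-long OS on the
   489 radiomic features is fitted 99 times, each with a different 10-fold
   cross-validation split choosing the penalty ``lambda_min``; predictors
   are standardized internally and coefficients reported on the original
   feature scale (:func:`fit_lasso_iteration`, :func:`fit_ensemble`).
   Features with a non-zero median coefficient across the 99 iterations are
   the selected set.
3. New patients get a radiomic-based risk (RBR) label by majority vote of
   the 99 per-iteration classifiers at probability threshold 0.5
   (:func:`predict_rbr`).  With 99 voters a tie is impossible; at least 50
   high votes means high risk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from sklearn.model_selection import StratifiedKFold

from ._lasso_path import logistic_lasso_path


class ModelingError(ValueError):
    pass


@dataclass
class SurvivalRecord:
    """One patient's follow-up plus binarized clinical covariates.

    ``event`` is 1 for death, 0 for censoring.  Binary covariates use 1 for
    the adverse level (age >= 65, KPS <= 70, resection < 90%, no
    chemoradiotherapy, MGMT unmethylated, TERT mutant); optional covariates
    may be None when unavailable for a cohort.
    """

    patient_id: str
    os_months: float
    event: int
    age_binary: int | None = None
    kps_binary: int | None = None
    eor_binary: int | None = None
    tmzrt_binary: int | None = None
    mgmt: int | None = None
    tert: int | None = None

    def __post_init__(self) -> None:
        if self.os_months <= 0:
            raise ModelingError("os_months must be positive")
        if self.event not in (0, 1):
            raise ModelingError("event flag must be 0 or 1")


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([r.__dict__ for r in records])


def km_median(records, method: str = "km") -> float:
    """Median survival time: smallest time with S(t) <= 0.5.

    ``method="km"`` (default) uses the Kaplan-Meier product-limit estimate,
    which is the appropriate median under right censoring; ``method="raw"``
    is the plain sample median of the observed times, offered for
    uncensored or exploratory use.  Raises :class:`ModelingError` when
    there are no events or the survival curve never reaches 0.5.
    """
    df = _as_frame(records)
    if df["event"].sum() < 1:
        raise ModelingError("median survival needs at least one event")
    if method == "raw":
        return float(np.median(df["os_months"]))
    if method != "km":
        raise ModelingError(f"unknown median method '{method}'")
    kmf = KaplanMeierFitter()
    kmf.fit(df["os_months"], df["event"])
    mst = float(kmf.median_survival_time_)
    if not np.isfinite(mst):
        raise ModelingError("survival curve never reaches 0.5; median undefined")
    return mst


def dichotomize_os(records, mst: float) -> pd.DataFrame:
    """Label each patient short / long / excluded relative to the MST.

    Observed survival at or beyond the MST (death or censoring) is long OS;
    death before the MST is short OS; censoring before the MST is excluded
    as ambiguous.
    """
    if mst <= 0:
        raise ModelingError("mst must be positive")
    df = _as_frame(records)
    label = np.where(
        df["os_months"] >= mst,
        "long",
        np.where(df["event"] == 1, "short", "excluded"),
    )
    return pd.DataFrame({"patient_id": df["patient_id"], "label": label})


@dataclass
class FilterReport:
    n_input: int
    n_excluded: int
    n_retained: int
    mst: float
    excluded_ids: list[str] = field(default_factory=list)


def apply_d1_filter(records, mst: float | None = None) -> tuple[pd.DataFrame, FilterReport]:
    """Drop censored cases with follow-up shorter than the (KM) median.

    The retained cohort is the one used for model training; every retained
    patient has an unambiguous short/long label.
    """
    df = _as_frame(records).reset_index(drop=True)
    mst_val = km_median(df) if mst is None else mst
    drop = (df["event"] == 0) & (df["os_months"] < mst_val)
    report = FilterReport(
        n_input=len(df),
        n_excluded=int(drop.sum()),
        n_retained=int((~drop).sum()),
        mst=mst_val,
        excluded_ids=df.loc[drop, "patient_id"].tolist(),
    )
    return df.loc[~drop].reset_index(drop=True), report


# --- LASSO ensemble -------------------------------------------------------

_N_FOLDS = 10


def _lambda_path(Xs: np.ndarray, y: np.ndarray, n_lambda: int, eps: float) -> np.ndarray:
    """Geometric penalty grid from the data-driven lambda_max downward."""
    n = len(y)
    resid = y - y.mean()
    lmax = float(np.abs(Xs.T @ resid).max()) / n
    if lmax <= 0:
        lmax = 1e-3
    return np.geomspace(lmax, lmax * eps, n_lambda)


def _deviance(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


@dataclass
class LassoIterationResult:
    """One CV-LASSO fit: the selected penalty and the refit coefficients.

    Coefficients are on the original feature scale; features with zero
    in-sample variance are fixed at coefficient 0.
    """

    iteration_index: int
    fold_seed: int
    lambda_min: float
    coefficients: np.ndarray  # original scale, length = n features
    intercept: float

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        eta = self.intercept + X @ self.coefficients
        return 1.0 / (1.0 + np.exp(-eta))


def fit_lasso_iteration(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    seed: int,
    iteration_index: int = 1,
    n_lambda: int = 25,
    lambda_min_ratio: float = 1e-2,
    solver_opts: dict | None = None,
) -> LassoIterationResult:
    """One 10-fold cross-validated LASSO logistic fit.

    The penalty grid runs geometrically downward from the data-driven
    maximum with warm-started coordinate descent; ``lambda_min`` minimizes
    mean held-out binomial deviance over a stratified 10-fold split drawn
    from ``seed``, and the reported model is the full-data path solution at
    ``lambda_min``.  Identical seeds give identical folds and therefore
    identical results.
    """
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ModelingError("both short and long OS classes are required")
    if np.isnan(Xa).any():
        raise ModelingError("feature matrix contains missing values")
    mean = Xa.mean(axis=0)
    sd = Xa.std(axis=0)
    keep = sd > 0
    Xs = (Xa[:, keep] - mean[keep]) / sd[keep]
    lambdas = _lambda_path(Xs, y, n_lambda, lambda_min_ratio)
    n_folds = min(_N_FOLDS, int(np.bincount(y).min()))
    if n_folds < 2:
        raise ModelingError("too few samples in the minority class for CV")
    opts = solver_opts or {}
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    dev = np.zeros(len(lambdas))
    for tr, te in skf.split(Xs, y):
        coefs, b0s = logistic_lasso_path(Xs[tr], y[tr], lambdas, **opts)
        eta = b0s[None, :] + Xs[te] @ coefs.T  # n_test x n_lambda
        p = 1.0 / (1.0 + np.exp(-eta))
        for k in range(len(lambdas)):
            dev[k] += _deviance(p[:, k], y[te])
    k_min = int(np.argmin(dev))
    lam_min = float(lambdas[k_min])
    full_coefs, full_b0s = logistic_lasso_path(Xs, y, lambdas, **opts)
    coef_s, b0_s = full_coefs[k_min], float(full_b0s[k_min])
    coef = np.zeros(Xa.shape[1])
    coef[keep] = coef_s / sd[keep]
    intercept = b0_s - float(np.sum(coef_s * mean[keep] / sd[keep]))
    return LassoIterationResult(
        iteration_index=iteration_index,
        fold_seed=seed,
        lambda_min=lam_min,
        coefficients=coef,
        intercept=intercept,
    )


@dataclass
class EnsembleModel:
    """99 CV-LASSO iterations plus their median-coefficient summary."""

    iterations: list[LassoIterationResult]
    feature_names: list[str]
    median_coefficients: np.ndarray
    selected_features: list[str]
    training_mst: float | None = None
    catalog_hash: str | None = None
    base_seed: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "base_seed": self.base_seed,
            "training_mst": self.training_mst,
            "catalog_hash": self.catalog_hash,
            "feature_names": self.feature_names,
            "median_coefficients": self.median_coefficients.tolist(),
            "selected_features": self.selected_features,
            "iterations": [
                {
                    "iteration_index": it.iteration_index,
                    "fold_seed": it.fold_seed,
                    "lambda_min": it.lambda_min,
                    "intercept": it.intercept,
                    "coefficients": it.coefficients.tolist(),
                }
                for it in self.iterations
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "EnsembleModel":
        d = json.loads(Path(path).read_text())
        iters = [
            LassoIterationResult(
                iteration_index=i["iteration_index"],
                fold_seed=i["fold_seed"],
                lambda_min=i["lambda_min"],
                coefficients=np.asarray(i["coefficients"]),
                intercept=i["intercept"],
            )
            for i in d["iterations"]
        ]
        return cls(
            iterations=iters,
            feature_names=d["feature_names"],
            median_coefficients=np.asarray(d["median_coefficients"]),
            selected_features=d["selected_features"],
            training_mst=d["training_mst"],
            catalog_hash=d["catalog_hash"],
            base_seed=d["base_seed"],
        )


def fit_ensemble(
    X: pd.DataFrame,
    y: np.ndarray,
    n_iter: int = 99,
    base_seed: int = 0,
    training_mst: float | None = None,
    catalog_hash: str | None = None,
    n_lambda: int = 25,
    solver_opts: dict | None = None,
) -> EnsembleModel:
    """Repeat the 10-fold CV-LASSO fit ``n_iter`` times with distinct folds.

    Iteration ``i`` uses fold seed ``base_seed + i``.  The median of each
    feature's coefficient across iterations defines the selected feature
    set (non-zero median).
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"f{i}" for i in range(np.asarray(X).shape[1])
    ]
    iters = [
        fit_lasso_iteration(
            X, y, seed=base_seed + i, iteration_index=i, n_lambda=n_lambda,
            solver_opts=solver_opts,
        )
        for i in range(1, n_iter + 1)
    ]
    coef_mat = np.vstack([it.coefficients for it in iters])
    med = np.median(coef_mat, axis=0)
    selected = [n for n, c in zip(names, med) if c != 0.0]
    return EnsembleModel(
        iterations=iters,
        feature_names=names,
        median_coefficients=med,
        selected_features=selected,
        training_mst=training_mst,
        catalog_hash=catalog_hash,
        base_seed=base_seed,
    )


def predict_rbr(model: EnsembleModel, X_new: pd.DataFrame) -> pd.DataFrame:
    """Radiomic-based risk by majority vote of the ensemble's classifiers.

    Each iteration votes high risk when its predicted probability of short
    OS is at least 0.5; a patient is high risk when at least 50 of the 99
    votes are high (strict majority of an odd vote count).
    """
    missing = [c for c in model.feature_names if c not in X_new.columns]
    if missing:
        raise ModelingError(f"feature columns missing from input: {missing[:5]}")
    Xa = X_new[model.feature_names].to_numpy(dtype=float)
    votes = np.zeros(len(Xa), dtype=int)
    for it in model.iterations:
        votes += (it.predict_proba(Xa) >= 0.5).astype(int)
    majority = (len(model.iterations) + 1) // 2
    rbr = np.where(votes >= majority, "high", "low")
    ids = (
        X_new["patient_id"].to_numpy()
        if "patient_id" in X_new
        else np.asarray([f"P{i:04d}" for i in range(len(Xa))])
    )
    return pd.DataFrame({"patient_id": ids, "rbr": rbr, "votes_high": votes})


def classification_metrics(
    rbr_labels: pd.DataFrame, dichotomized_truth: pd.DataFrame
) -> dict[str, float]:
    """Accuracy / precision / recall of RBR against dichotomized OS.

    Patients labelled ``excluded`` (censored before the MST) are not
    evaluable and are dropped.  The positive class is (high risk, short OS).
    """
    merged = rbr_labels.merge(dichotomized_truth, on="patient_id")
    merged = merged[merged["label"] != "excluded"]
    if merged.empty:
        raise ModelingError("no evaluable patients after exclusions")
    pred = merged["rbr"] == "high"
    truth = merged["label"] == "short"
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    tn = int((~pred & ~truth).sum())
    return {
        "accuracy": (tp + tn) / len(merged),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "recall": tp / (tp + fn) if tp + fn else float("nan"),
        "n_evaluable": len(merged),
    }
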