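"""Logistic recurrence classification and ROC evaluation.

Meta-genes act as regressors in an unpenalized logistic model; the model
is evaluated by stratified k-fold cross-validation within the discovery
cohort (meta-gene loadings re-estimated inside each training fold so no
held-out sample leaks into the PCA), by transfer to external cohorts,
and within WHO-grade strata.  AUCs carry DeLong standard errors and
paired curves are compared with DeLong's test.

:class:`RecurrenceClassifier` is the sklearn estimator face (fit on a
samples x genes frame + binary outcome; predict_proba); the module
functions implement the study-level procedures around it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .io import ExpressionMatrix, PhenotypeTable, ValidationError
from .metagene import MetageneTransformer, compute_metagenes

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class LogisticModel:
    """Maximum-likelihood logistic fit with Wald inference."""

    params: pd.Series               # includes "intercept"
    cov: pd.DataFrame
    conf_int: pd.DataFrame          # columns lower, upper (log-odds scale)
    wald_p: pd.Series
    converged: bool
    separation: bool
    fitted_on: str = ""
    n_obs: int = 0

    @property
    def odds_ratios(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "OR": np.exp(self.params),
            "ci_low": np.exp(self.conf_int["lower"]),
            "ci_high": np.exp(self.conf_int["upper"]),
            "p": self.wald_p,
        })
        return out.drop(index="intercept", errors="ignore")

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        names = [n for n in self.params.index if n != "intercept"]
        missing = [n for n in names if n not in X.columns]
        if missing:
            raise ValidationError(f"missing regressors: {missing}")
        return (self.params["intercept"]
                + X[names].to_numpy() @ self.params[names].to_numpy())


@dataclass
class RocResult:
    """AUC with DeLong standard error and the full ROC curve."""

    auc: float
    se: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_pos: int
    n_neg: int
    description: str = ""

    def summary(self) -> str:
        return f"AUC = {self.auc:.2f} ± {self.se:.2f}"


@dataclass
class DeLongResult:
    """Paired comparison of two correlated ROC curves."""

    auc1: float
    auc2: float
    difference: float
    variance: float
    z: float
    p_value: float


# ---------------------------------------------------------------------------
# AUC / DeLong machinery
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata
    return rankdata(x, method="average")


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components.

    Returns (auc, v10, v01): v10 has one entry per positive (its mean
    win-rate over negatives, ties half credit), v01 one per negative.
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValidationError("both outcome classes must be present")
    combined = np.concatenate([pos, neg])
    r_all = _midrank(combined)
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    auc = v10.mean()
    return auc, v10, v01


def roc_auc(scores, labels, description: str = "") -> RocResult:
    """Mann-Whitney AUC (ties half credit) with DeLong variance and the
    threshold-sweep ROC curve."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    auc, v10, v01 = _placements(scores, labels)
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    fpr, tpr, thr = roc_curve(labels, scores)
    return RocResult(auc=float(auc), se=float(np.sqrt(max(var, 0.0))),
                     fpr=fpr, tpr=tpr, thresholds=thr,
                     n_pos=m, n_neg=n, description=description)


def delong_test(scores1, scores2, labels) -> DeLongResult:
    """DeLong's paired test of two correlated AUCs on the same samples."""
    scores1 = np.asarray(scores1, dtype=float)
    scores2 = np.asarray(scores2, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(scores1) != len(scores2) or len(scores1) != len(labels):
        raise ValidationError("paired score vectors must match labels in length")
    a1, v10_1, v01_1 = _placements(scores1, labels)
    a2, v10_2, v01_2 = _placements(scores2, labels)
    m, n = len(v10_1), len(v01_1)
    diff = a1 - a2
    if m > 1:
        s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
    else:
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
    else:
        s01 = np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = 2.0 * norm.sf(abs(z))
    return DeLongResult(auc1=float(a1), auc2=float(a2), difference=float(diff),
                        variance=float(max(var, 0.0)), z=float(z),
                        p_value=float(p))


# ---------------------------------------------------------------------------
# logistic fitting
# ---------------------------------------------------------------------------

def fit_logistic(y, X: pd.DataFrame, fitted_on: str = "") -> LogisticModel:
    """Unpenalized maximum-likelihood logistic regression with Wald CIs.

    Complete separation and non-convergence are detected and flagged on
    the returned model (coefficients at the last iterate), never raised
    silently.
    """
    y = np.asarray(y).astype(float)
    if len(np.unique(y)) < 2:
        raise ValidationError("outcome must contain both classes")
    X = pd.DataFrame(X)
    if X.isna().any().any():
        raise ValidationError("regressors contain missing values")
    if len(y) <= X.shape[1] + 1:
        raise ValidationError("need n > number of regressors + 1")
    design = sm.add_constant(X.astype(float), has_constant="add")
    design = design.rename(columns={"const": "intercept"})
    separation = False
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except Exception:
            res = sm.Logit(y, design).fit(disp=0, method="bfgs", maxiter=500)
            separation = True
        for w in caught:
            msg = str(w.message).lower()
            if "separation" in msg:
                separation = True
            if "converge" in msg or "maximum" in msg:
                converged = False
    retvals = getattr(res, "mle_retvals", None) or {}
    converged = converged and bool(retvals.get("converged", True))
    params = pd.Series(res.params, index=design.columns)
    if np.abs(params.drop("intercept", errors="ignore")).max() > 25:
        separation = True
    cov = pd.DataFrame(res.cov_params(), index=design.columns,
                       columns=design.columns)
    ci = res.conf_int()
    ci = pd.DataFrame(np.asarray(ci), index=design.columns,
                      columns=["lower", "upper"])
    pvals = pd.Series(np.asarray(res.pvalues), index=design.columns)
    if separation:
        logger.warning("fit_logistic: (quasi-)complete separation detected")
    return LogisticModel(params=params, cov=cov, conf_int=ci, wald_p=pvals,
                         converged=converged and not separation,
                         separation=separation, fitted_on=fitted_on,
                         n_obs=len(y))


def predict_prob(model: LogisticModel, X: pd.DataFrame) -> np.ndarray:
    """Recurrence probabilities from a fitted logistic model."""
    from scipy.special import expit
    return expit(model.linear_predictor(pd.DataFrame(X)))


# ---------------------------------------------------------------------------
# sklearn estimator
# ---------------------------------------------------------------------------

class RecurrenceClassifier(ClassifierMixin, BaseEstimator):
    """Meta-gene logistic recurrence classifier.

    ``fit(X, y)`` takes a (samples x genes) DataFrame and a binary
    outcome; module PC1 loadings and the logistic coefficients are both
    learned from the training samples, so the estimator can sit inside
    sklearn model selection without leakage.

    Parameters
    ----------
    modules : mapping module name -> gene id list
    covariates : optional DataFrame aligned to X with extra regressors
        (e.g. WHO grade as a numeric ordinal).
    """

    def __init__(self, modules: Mapping[str, Sequence] = None,
                 covariates: Optional[pd.DataFrame] = None):
        self.modules = modules
        self.covariates = covariates

    def _design(self, X: pd.DataFrame, transformer) -> pd.DataFrame:
        mg = transformer.transform(X)
        if self.covariates is not None:
            cov = self.covariates.loc[X.index]
            mg = pd.concat([mg, cov], axis=1)
        return mg

    def fit(self, X, y):
        if not isinstance(X, pd.DataFrame):
            raise ValidationError("RecurrenceClassifier requires a DataFrame")
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValidationError("outcome must contain both classes")
        self.transformer_ = MetageneTransformer(self.modules).fit(X)
        design = self._design(X, self.transformer_)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.logistic_ = LogisticRegression(C=np.inf, max_iter=2000)
            self.logistic_.fit(design.to_numpy(), y)
        self.feature_names_ = list(design.columns)
        return self

    def decision_function(self, X):
        check_is_fitted(self)
        design = self._design(X, self.transformer_)
        return self.logistic_.decision_function(design.to_numpy())

    def predict_proba(self, X):
        check_is_fitted(self)
        design = self._design(X, self.transformer_)
        return self.logistic_.predict_proba(design.to_numpy())

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] > 0.5).astype(int)]


# ---------------------------------------------------------------------------
# study-level procedures
# ---------------------------------------------------------------------------

def _samples_frame(x: ExpressionMatrix) -> pd.DataFrame:
    return x.data.T


def cross_validate(x: ExpressionMatrix, pheno: PhenotypeTable,
                   modules: Mapping[str, Sequence], k: int = 10,
                   seed: int = 0, mode: str = "strict",
                   folds=None) -> RocResult:
    """Pooled out-of-fold ROC of the meta-gene logistic classifier.

    mode="strict" (default) re-estimates per-module PC1 loadings inside
    each training fold and projects the held-out samples onto them;
    mode="whole-cohort" computes meta-genes once on all samples and
    cross-validates only the logistic fit (kept for comparability, known
    to be optimistic).

    ``folds`` optionally supplies a precomputed per-sample fold index
    (overriding the seeded stratified partition), e.g. to mirror an
    external fold scheme.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    pheno = pheno.aligned_to(x)
    y = pheno.recurrence.to_numpy()
    frame = _samples_frame(x)
    if folds is not None:
        folds = np.asarray(folds)
        if len(folds) != len(y):
            raise ValidationError("folds length must match n_samples")
        splits = [(np.flatnonzero(folds != f), np.flatnonzero(folds == f))
                  for f in np.unique(folds)]
    else:
        min_class = min((y == 1).sum(), (y == 0).sum())
        if min_class >= k:
            splitter = StratifiedKFold(n_splits=k, shuffle=True,
                                       random_state=seed)
            splits = splitter.split(frame, y)
        else:
            logger.warning("cross_validate: class with %d samples < %d folds; "
                           "falling back to unstratified folds", min_class, k)
            splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
            splits = splitter.split(frame)

    oof = np.full(len(y), np.nan)
    if mode == "whole-cohort":
        mg_all = compute_metagenes(x, modules).scores.T  # samples x modules
    elif mode != "strict":
        raise ValidationError(f"unknown CV mode {mode!r}")

    for train_idx, test_idx in splits:
        if len(np.unique(y[train_idx])) < 2:
            raise ValidationError("a class is absent from a training fold")
        if mode == "strict":
            clf = RecurrenceClassifier(modules)
            clf.fit(frame.iloc[train_idx], y[train_idx])
            oof[test_idx] = clf.predict_proba(frame.iloc[test_idx])[:, 1]
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                lr = LogisticRegression(C=np.inf, max_iter=2000)
                lr.fit(mg_all.iloc[train_idx].to_numpy(), y[train_idx])
            oof[test_idx] = lr.predict_proba(
                mg_all.iloc[test_idx].to_numpy())[:, 1]
    assert not np.isnan(oof).any()
    return roc_auc(oof, y, description=f"{k}-fold CV ({mode})")


def evaluate_external(train: tuple, test: tuple,
                      modules: Mapping[str, Sequence],
                      max_missing_fraction: float = 0.5):
    """Train on one cohort, evaluate on another.

    Meta-genes are recomputed within each cohort from the shared module
    gene lists (orientation keeps the signs comparable); the logistic
    model fitted on the training cohort's meta-genes scores the test
    cohort's.  Returns (RocResult, LogisticModel).
    """
    (x_tr, ph_tr), (x_te, ph_te) = train, test
    for name, genes in modules.items():
        present = sum(g in x_te.data.index for g in genes)
        if present < (1 - max_missing_fraction) * len(genes):
            raise ValidationError(
                f"module {name}: only {present}/{len(genes)} genes present "
                "in test cohort")
    ph_tr = ph_tr.aligned_to(x_tr)
    ph_te = ph_te.aligned_to(x_te)
    mg_tr = compute_metagenes(x_tr, modules).scores.T
    mg_te = compute_metagenes(x_te, modules).scores.T
    model = fit_logistic(ph_tr.recurrence.to_numpy(), mg_tr,
                         fitted_on="train")
    probs = predict_prob(model, mg_te)
    roc = roc_auc(probs, ph_te.recurrence.to_numpy(),
                  description="external validation")
    return roc, model


def multivariate_model(x: ExpressionMatrix, pheno: PhenotypeTable,
                       modules: Mapping[str, Sequence], module_name: str,
                       covariates: Sequence[str] = ("who_grade",),
                       grade_encoding: str = "ordinal") -> LogisticModel:
    """Within-cohort logistic fit of one module meta-gene plus clinical
    covariates; the module's OR/CI/p within this fit quantify whether it
    adds information over grade.

    Samples missing any requested covariate are dropped (with a log line
    reporting the count).
    """
    pheno = pheno.aligned_to(x)
    mg = compute_metagenes(x, {module_name: modules[module_name]}).scores.T
    design = mg.copy()
    for cov in covariates:
        if cov not in pheno.data.columns:
            raise ValidationError(f"unknown covariate {cov!r}")
        col = pheno.data[cov]
        if cov == "who_grade" and grade_encoding == "dummy":
            dummies = pd.get_dummies(col.astype("Int64"), prefix="who",
                                     drop_first=True).astype(float)
            design = pd.concat([design, dummies], axis=1)
        else:
            design[cov] = col.astype(float)
    keep = design.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("multivariate_model: %d samples dropped for missing "
                    "covariates", n_dropped)
    design = design[keep]
    y = pheno.recurrence[keep].to_numpy()
    return fit_logistic(y, design, fitted_on="multivariate")


def stratified_by_grade(x: ExpressionMatrix, pheno: PhenotypeTable,
                        modules: Mapping[str, Sequence],
                        grade: int) -> RocResult:
    """ROC of the meta-gene classifier restricted to one WHO grade.

    Meta-genes and the logistic fit use the full cohort; only the
    evaluation is subset, mirroring per-grade performance read-outs.
    """
    pheno = pheno.aligned_to(x)
    in_stratum = pheno.who_grade == grade
    if not in_stratum.any():
        raise ValidationError(f"no samples of WHO grade {grade}")
    y_str = pheno.recurrence[in_stratum]
    if y_str.nunique() < 2:
        raise ValidationError(
            f"WHO grade {grade} stratum has a single outcome class "
            "(recurrence labels are rare in some strata)")
    mg = compute_metagenes(x, modules).scores.T
    model = fit_logistic(pheno.recurrence.to_numpy(), mg, fitted_on="full")
    probs = pd.Series(predict_prob(model, mg), index=mg.index)
    return roc_auc(probs[in_stratum].to_numpy(), y_str.to_numpy(),
                   description=f"WHO grade {grade} stratum")
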