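"""Propensity-score estimation, IPTW weights, and covariate balance.

The propensity model is a maximum-likelihood logistic regression of the
treatment indicator on baseline covariates. Inverse-probability-of-treatment
weights target the ATE by default — ``1/e`` for treated patients and
``1/(1-e)`` for controls — because the population-average contrast is what
a public-payer evaluation prices; the weighted group sizes then exceed the
raw arm sizes, as in the usual "weighted N" table header. Stabilized
weights (multiplied by the marginal arm prevalence) and percentile
truncation are available as options.

Balance is summarized by weighted standardized differences: for a
continuous covariate ``(m1 - m2) / sqrt((s1^2 + s2^2) / 2)`` with weighted
(population-formula) means and SDs, and for a binary covariate
``(p1 - p2) / sqrt((p1 (1-p1) + p2 (1-p2)) / 2)``. ``|d| < 0.1`` is the
conventional adequacy threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .exceptions import EstimationError, ValidationError

#: Default covariates of the propensity model: the prognosis-relevant
#: baseline measures (comorbidity, morbidity burden, age, residence, disease
#: duration, prior radiation). Other baseline variables are balance
#: diagnostics only.
DEFAULT_PROPENSITY_COVARIATES = (
    "charlson_1plus",
    "morbidity_score",
    "age",
    "urban",
    "months_dx_to_2l",
    "prior_radiation",
)

#: Covariates reported in the balance table (superset of the model).
DEFAULT_BALANCE_COVARIATES = (
    "age",
    "male",
    "income_quintile",
    "urban",
    "morbidity_score",
    "adg_count",
    "charlson_1plus",
    "prior_radiation",
    "prior_resection",
    "firstline_class",
    "months_dx_to_2l",
)

BALANCE_THRESHOLD = 0.1


@dataclass
class PropensityFit:
    """Fitted propensity model and per-patient scores in (0, 1)."""

    covariates: list
    scores: np.ndarray
    coefficients: pd.Series
    treated: np.ndarray  # boolean treatment indicator, aligned with scores
    dropped: list = field(default_factory=list)

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        if np.any((s <= 0.0) | (s >= 1.0)):
            raise EstimationError("propensity scores must lie strictly in (0, 1)")


@dataclass
class WeightVector:
    """Per-patient IPTW weights with their estimand bookkeeping."""

    weights: np.ndarray
    estimand: str                # "ATE" or "ATT"
    stabilized: bool
    weighted_n: dict             # arm -> sum of weights, the "weighted N"

    def __post_init__(self):
        if np.any(self.weights < 0):
            raise EstimationError("IPTW weights must be nonnegative")


def _design_matrix(cohort: pd.DataFrame, covariates) -> pd.DataFrame:
    missing = [c for c in covariates if c not in cohort.columns]
    if missing:
        raise ValidationError(f"missing covariate column(s): {missing}")
    X = pd.DataFrame(index=cohort.index)
    for c in covariates:
        col = cohort[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
        else:
            X[c] = col.astype(float)
    return X


def fit_propensity(cohort: pd.DataFrame,
                   covariates=DEFAULT_PROPENSITY_COVARIATES) -> PropensityFit:
    """Maximum-likelihood logistic propensity model.

    Categorical covariates are expanded into indicator columns; constant
    (degenerate) columns are dropped with a warning. Perfect separation is
    reported as an :class:`EstimationError` advising covariate revision.
    """
    if set(cohort["arm"]) != {"control", "treated"} and \
            not {"control", "treated"}.issuperset(set(cohort["arm"])):
        raise ValidationError("arm column must contain 'control'/'treated'")
    treated = (cohort["arm"] == "treated").to_numpy()
    if treated.all() or (~treated).all():
        raise ValidationError("both arms must be present to fit a propensity model")

    X = _design_matrix(cohort, covariates)
    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    if dropped:
        warnings.warn(
            f"dropping degenerate (constant) propensity columns: {dropped}",
            stacklevel=2,
        )
        X = X.drop(columns=dropped)
    if X.shape[1] == 0:
        raise ValidationError("no usable covariates remain for the propensity model")

    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=PerfectSeparationWarning)
            res = sm.Logit(treated.astype(float), design).fit(disp=0)
    except (PerfectSeparationError, PerfectSeparationWarning,
            np.linalg.LinAlgError) as exc:
        raise EstimationError(
            "propensity model failed to converge (possible perfect "
            "separation); revise the covariate specification"
        ) from exc
    scores = res.predict(design)
    eps = 1e-12
    scores = np.clip(scores, eps, 1 - eps)
    coefs = pd.Series(res.params, index=["intercept", *X.columns])
    return PropensityFit(covariates=list(X.columns), scores=scores,
                         coefficients=coefs, treated=treated, dropped=dropped)


def compute_iptw(fit: PropensityFit, estimand: str = "ATE",
                 stabilized: bool = False,
                 truncate_percentiles: tuple | None = None) -> WeightVector:
    """IPTW weights from fitted propensity scores.

    ATE: ``1/e`` (treated), ``1/(1-e)`` (controls); ATT: ``1`` (treated),
    ``e/(1-e)`` (controls). Stabilization multiplies by the marginal arm
    prevalence. Optional symmetric percentile truncation (e.g. ``(1, 99)``)
    caps extreme weights.
    """
    e = fit.scores
    t = fit.treated
    p_treated = t.mean()
    if estimand == "ATE":
        w = np.where(t, 1.0 / e, 1.0 / (1.0 - e))
        if stabilized:
            w = w * np.where(t, p_treated, 1.0 - p_treated)
    elif estimand == "ATT":
        w = np.where(t, 1.0, e / (1.0 - e))
    else:
        raise ValidationError(f"estimand must be 'ATE' or 'ATT', got {estimand!r}")
    if truncate_percentiles is not None:
        lo, hi = np.percentile(w, truncate_percentiles)
        w = np.clip(w, lo, hi)
    weighted_n = {
        "control": float(w[~t].sum()),
        "treated": float(w[t].sum()),
    }
    return WeightVector(weights=w, estimand=estimand, stabilized=stabilized,
                        weighted_n=weighted_n)


# ---------------------------------------------------------------------------
# standardized differences
# ---------------------------------------------------------------------------

def _weighted_mean_sd(x: np.ndarray, w: np.ndarray) -> tuple:
    m = np.average(x, weights=w)
    var = np.average((x - m) ** 2, weights=w)  # population formula
    return m, np.sqrt(var)


def smd_continuous(m1: float, s1: float, m2: float, s2: float) -> float:
    """Standardized difference from summary moments of a continuous covariate."""
    denom = np.sqrt((s1 ** 2 + s2 ** 2) / 2.0)
    if denom == 0:
        if m1 == m2:
            return 0.0
        raise EstimationError("zero pooled SD with unequal means")
    return (m1 - m2) / denom


def smd_binary(p1: float, p2: float) -> float:
    """Standardized difference from the two proportions of a binary covariate."""
    denom = np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2.0)
    if denom == 0:
        if p1 == p2:
            return 0.0
        raise EstimationError("degenerate proportions with unequal values")
    return (p1 - p2) / denom


def standardized_difference(x1, x2, w1=None, w2=None,
                            binary: bool | None = None) -> float:
    """Signed (weighted) standardized difference between two samples.

    ``binary=None`` auto-detects indicator data (values within {0, 1}).
    Weighted moments use the population (frequency-weight) formula without
    a finite-sample correction. The result is antisymmetric under swapping
    the samples and invariant under affine rescaling of continuous data.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    w1 = np.ones_like(x1) if w1 is None else np.asarray(w1, dtype=float)
    w2 = np.ones_like(x2) if w2 is None else np.asarray(w2, dtype=float)
    if x1.shape != w1.shape or x2.shape != w2.shape:
        raise ValidationError("weights must align with values")
    if binary is None:
        binary = set(np.unique(np.concatenate([x1, x2]))) <= {0.0, 1.0}
    if binary:
        p1 = np.average(x1, weights=w1)
        p2 = np.average(x2, weights=w2)
        return smd_binary(p1, p2)
    m1, s1 = _weighted_mean_sd(x1, w1)
    m2, s2 = _weighted_mean_sd(x2, w2)
    return smd_continuous(m1, s1, m2, s2)


def balance_table(cohort: pd.DataFrame, weights: WeightVector | None = None,
                  covariates=DEFAULT_BALANCE_COVARIATES,
                  threshold: float = BALANCE_THRESHOLD) -> pd.DataFrame:
    """Weighted standardized-difference table, one row per covariate level.

    Categorical covariates are expanded into one indicator row per level
    (all levels, to mirror a descriptive baseline table). Returns columns
    ``covariate, treated_summary, control_summary, smd, abs_smd, balanced``;
    ``balanced`` is ``|smd| < threshold``.
    """
    t = (cohort["arm"] == "treated").to_numpy()
    w = weights.weights if weights is not None else np.ones(len(cohort))
    rows = []
    for c in covariates:
        if c not in cohort.columns:
            raise ValidationError(f"missing balance covariate: {c}")
        col = cohort[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            for level in sorted(col.unique()):
                x = (col == level).to_numpy(dtype=float)
                d = standardized_difference(x[t], x[~t], w[t], w[~t], binary=True)
                rows.append((f"{c}={level}",
                             np.average(x[t], weights=w[t]),
                             np.average(x[~t], weights=w[~t]), d))
        else:
            x = col.to_numpy(dtype=float)
            d = standardized_difference(x[t], x[~t], w[t], w[~t])
            rows.append((c,
                         np.average(x[t], weights=w[t]),
                         np.average(x[~t], weights=w[~t]), d))
    out = pd.DataFrame(rows, columns=["covariate", "treated_summary",
                                      "control_summary", "smd"])
    out["abs_smd"] = out["smd"].abs().round(2)
    out["balanced"] = out["smd"].abs() < threshold
    return out
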