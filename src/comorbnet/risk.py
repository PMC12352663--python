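"""Per-condition logistic risk models and the individualized risk matrix.

One logistic regression is fitted per health condition over six demographic
predictors: age (years), weight (lbs), breed background (mixed = 1, purebred
reference) and three sex-status dummies (spayed female reference).  The
fitted per-dog probabilities P(y in d) form the risk matrix that every
downstream co-occurrence test consumes.

Reference levels are arbitrary for the pipeline: any full-rank coding gives
identical fitted probabilities, which is all downstream stages use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import Cohort

__all__ = [
    "DESIGN_COLUMNS",
    "RiskModel",
    "RiskMatrix",
    "encode_design",
    "fit_condition_model",
    "fit_all",
    "predict_risk",
    "coefficient_table",
]

# Deterministic design column order; spayed_female / purebred are reference.
DESIGN_COLUMNS = (
    "age",
    "weight",
    "breed_mixed",
    "sex_intact_female",
    "sex_intact_male",
    "sex_neutered_male",
)

COEF_NAMES = ("intercept",) + DESIGN_COLUMNS

#: events-per-parameter guard: six predictors * ten events each
MIN_EVENTS_DEFAULT = 60

_RIDGE_LAMBDA = 1e-4
_PROB_EPS = 1e-12


@dataclass
class RiskModel:
    """Fitted logistic model for one condition.

    ``beta`` holds (intercept, age, weight, breed_mixed, sex dummies) in
    log-odds units on the raw covariate scale.  ``penalized`` marks the weak
    L2 fallback engaged on separation or non-convergence.
    """

    condition_id: str
    beta: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    converged: bool
    penalized: bool
    n_events: int

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (7,):
            raise ValueError(f"beta must have 7 entries, got {self.beta.shape}")


@dataclass
class RiskMatrix:
    """Dogs x conditions matrix of fitted probabilities, strictly in (0, 1)."""

    values: np.ndarray
    dog_ids: list
    condition_ids: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.dog_ids), len(self.condition_ids)):
            raise ValueError("risk matrix shape does not match its indices")
        if not ((self.values > 0) & (self.values < 1)).all():
            raise ValueError("risk probabilities must lie strictly in (0, 1)")
        self._col = {cid: j for j, cid in enumerate(self.condition_ids)}

    def column(self, condition_id) -> np.ndarray:
        return self.values[:, self._col[condition_id]]


def encode_design(cohort: Cohort) -> pd.DataFrame:
    """Six-predictor design matrix (no intercept column), one row per dog."""
    if cohort.N == 0:
        raise ValueError("cannot encode an empty cohort")
    rows = np.empty((cohort.N, 6))
    for i, dog in enumerate(cohort.dogs):
        rows[i, 0] = dog.age
        rows[i, 1] = dog.weight
        rows[i, 2] = 1.0 if dog.breed_background == "mixed" else 0.0
        rows[i, 3] = 1.0 if dog.sex_status == "intact_female" else 0.0
        rows[i, 4] = 1.0 if dog.sex_status == "intact_male" else 0.0
        rows[i, 5] = 1.0 if dog.sex_status == "neutered_male" else 0.0
    return pd.DataFrame(
        rows, index=[d.dog_id for d in cohort.dogs], columns=list(DESIGN_COLUMNS)
    )


def _standardize(X: np.ndarray):
    """Z-score continuous columns for optimizer stability; return inverse map."""
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    return (X - mean) / std, mean, std


def _unscale(beta_s: np.ndarray, cov_s: np.ndarray, mean, std):
    """Map coefficients (and covariance) from z-scored back to raw scale.

    beta_raw = T @ beta_s with T the affine back-transform, so the raw-scale
    covariance is T Cov T'.
    """
    k = len(beta_s)
    T = np.zeros((k, k))
    T[0, 0] = 1.0
    T[0, 1:] = -mean / std
    T[np.arange(1, k), np.arange(1, k)] = 1.0 / std
    beta = T @ beta_s
    cov = T @ cov_s @ T.T
    bse = np.sqrt(np.clip(np.diag(cov), 0, None))
    return beta, bse


def _ridge_fallback(Xs: np.ndarray, y: np.ndarray) -> np.ndarray:
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(C=1.0 / _RIDGE_LAMBDA, solver="lbfgs", max_iter=1000)
    clf.fit(Xs, y)
    return np.concatenate([clf.intercept_, clf.coef_.ravel()])


def fit_condition_model(design, outcome, condition_id) -> RiskModel:
    """Maximum-likelihood logistic fit for one condition.

    The fit runs on z-scored age/weight internally and the coefficients are
    mapped back to the raw scale.  If plain MLE fails to converge (e.g.
    separation), the model is refitted with a weak L2 penalty on the slopes
    and flagged ``penalized``.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n_events = int(y.sum())
    if n_events == 0 or n_events == len(y):
        raise ValueError(
            f"condition {condition_id}: outcome is constant "
            f"({n_events} events of {len(y)})"
        )
    Xs, mean, std = _standardize(X)
    Xc = sm.add_constant(Xs, prepend=True, has_constant="add")

    converged = False
    penalized = False
    beta_s = cov_s = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=100, tol=1e-8)
            converged = bool(res.mle_retvals.get("converged", False))
            if converged and np.isfinite(res.bse).all():
                beta_s = np.asarray(res.params, dtype=float)
                cov_s = np.asarray(res.cov_params(), dtype=float)
            else:
                converged = False
        except Exception:
            converged = False

    if beta_s is None:
        beta_s = _ridge_fallback(Xs, y)
        penalized = True
        # Wald covariance from the penalized information matrix
        p = 1.0 / (1.0 + np.exp(-Xc @ beta_s))
        W = p * (1 - p)
        H = (Xc * W[:, None]).T @ Xc
        H[1:, 1:] += _RIDGE_LAMBDA * np.eye(Xc.shape[1] - 1)
        cov_s = np.linalg.pinv(H)

    beta, bse = _unscale(beta_s, cov_s, mean, std)
    from scipy import stats

    pvals = 2 * stats.norm.sf(np.abs(beta) / np.where(bse > 0, bse, np.inf))
    return RiskModel(
        condition_id=condition_id,
        beta=beta,
        bse=bse,
        pvalues=np.asarray(pvals, dtype=float),
        converged=converged,
        penalized=penalized,
        n_events=n_events,
    )


def fit_all(
    cohort: Cohort,
    design: pd.DataFrame | None = None,
    min_events: int = MIN_EVENTS_DEFAULT,
    override: bool = False,
) -> list:
    """Fit one model per catalog condition.

    Refuses conditions with fewer than ``min_events`` events (one predictive
    variable for every ten events, six predictors) unless ``override``.
    """
    if design is None:
        design = encode_design(cohort)
    X_ind, _, cids = cohort.condition_indicators()
    models = []
    for j, cid in enumerate(cids):
        n_events = int(X_ind[:, j].sum())
        if n_events < min_events and not override:
            raise ValueError(
                f"condition {cid} has {n_events} events < {min_events}; "
                f"pass override=True to fit anyway"
            )
        models.append(
            fit_condition_model(design.values, X_ind[:, j].astype(float), cid)
        )
    return models


def predict_risk(models: list, design: pd.DataFrame) -> RiskMatrix:
    """Individualized probabilities via the inverse logit of each model."""
    X = np.asarray(design, dtype=float)
    if X.shape[1] != 6:
        raise ValueError(f"design must have 6 columns, got {X.shape[1]}")
    from scipy.special import expit

    Xc = np.column_stack([np.ones(len(X)), X])
    B = np.column_stack([m.beta for m in models])
    probs = np.clip(expit(Xc @ B), _PROB_EPS, 1 - _PROB_EPS)
    return RiskMatrix(
        values=probs,
        dog_ids=list(design.index),
        condition_ids=[m.condition_id for m in models],
    )


def coefficient_table(models: list) -> pd.DataFrame:
    """Long-format coefficient table (one row per condition x term)."""
    rows = []
    for m in models:
        for k, term in enumerate(COEF_NAMES):
            rows.append(
                {
                    "condition_id": m.condition_id,
                    "term": term,
                    "estimate": m.beta[k],
                    "standard_error": m.bse[k],
                    "p_value": m.pvalues[k],
                    "converged": m.converged,
                    "penalized": m.penalized,
                }
            )
    return pd.DataFrame(rows)
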