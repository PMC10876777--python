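"""Diagnostic classification: ridge-penalized logistic regression with LOOCV.

The model is a plain binary logistic regression on the six language
predictors. A small ridge penalty (default 1e-3 on standardized
predictors) is always applied: well-separated cohorts make the
unpenalized maximum-likelihood solution diverge, and the penalty
guarantees a unique finite fit while perturbing non-separable fits
negligibly. Validation is leave-one-out: n fits on n-1 rows, each
held-out probability pooled into one report (accuracy, precision,
recall with the patient group positive, ROC/AUC on the pooled
probabilities, 0.5 decision threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .types import ValidationError


class LogisticDiagnosticClassifier(BaseEstimator, ClassifierMixin):
    """Standardize-then-logistic classifier with a fixed ridge penalty.

    Predictors are z-scored with statistics learned in ``fit`` (so a
    held-out row is standardized by its training fold only), then passed to
    a logistic regression whose L2 penalty strength is ``ridge`` per the
    penalized log-likelihood sum(ll) - ridge * ||w||^2.

    Parameters
    ----------
    ridge : float, default 1e-3
        Nonnegative L2 penalty on the standardized-scale coefficients.
    standardize : bool, default True
    max_iter : int, default 1000
    tol : float, default 1e-8

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Coefficients on the standardized scale.
    intercept_ : float
    classes_ : ndarray
    """

    def __init__(
        self,
        ridge: float = 1e-3,
        standardize: bool = True,
        max_iter: int = 1000,
        tol: float = 1e-8,
    ):
        self.ridge = ridge
        self.standardize = standardize
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValidationError("X must be 2-dimensional")
        if np.isnan(X).any():
            raise ValidationError("X contains missing predictor values")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValidationError(f"need exactly 2 classes, got {classes.size}")
        if self.ridge < 0:
            raise ValidationError("ridge must be nonnegative")
        self.scaler_ = StandardScaler() if self.standardize else None
        Xs = self.scaler_.fit_transform(X) if self.scaler_ is not None else X
        # sklearn minimizes 0.5||w||^2 + C*sum(loss); C = 1/(2*ridge) makes
        # that proportional to sum(loss) + ridge||w||^2.
        C = np.inf if self.ridge == 0 else 1.0 / (2.0 * self.ridge)
        model = LogisticRegression(
            C=C, solver="lbfgs", max_iter=self.max_iter, tol=self.tol,
        )
        model.fit(Xs, y)
        if model.n_iter_[0] >= self.max_iter:
            raise ValidationError(
                f"logistic fit did not converge at ridge={self.ridge}"
            )
        self.model_ = model
        self.classes_ = model.classes_
        self.coef_ = model.coef_[0]
        self.intercept_ = float(model.intercept_[0])
        self.n_features_in_ = X.shape[1]
        return self

    def _transform(self, X):
        X = np.asarray(X, dtype=float)
        return self.scaler_.transform(X) if self.scaler_ is not None else X

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(self._transform(X))

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(self._transform(X))


def fit_logistic(X, y, ridge: float = 1e-3) -> tuple[np.ndarray, float]:
    """Fit the penalized logistic model; returns (weights, intercept)
    on the standardized-predictor scale."""
    clf = LogisticDiagnosticClassifier(ridge=ridge).fit(X, y)
    return clf.coef_, clf.intercept_


@dataclass
class ClassificationReport:
    """Pooled leave-one-out results."""

    per_fold: pd.DataFrame   # participant_id, y_true, probability, y_pred
    accuracy: float
    precision: float
    recall: float
    auc: float
    roc_points: list[tuple[float, float]] = field(repr=False)


def roc_auc(probabilities, labels) -> tuple[float, list[tuple[float, float]]]:
    """AUC by pairwise concordance (ties 1/2) and the ROC threshold sweep.

    The AUC is the probability that a randomly chosen positive outranks a
    randomly chosen negative; ROC points come from sweeping every unique
    probability as a threshold.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    pos = p[y == 1]
    neg = p[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both classes must be present")
    diff = pos[:, None] - neg[None, :]
    auc = float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)
    fpr, tpr, _ = roc_curve(y, p, drop_intermediate=False)
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def loocv(
    X,
    y,
    ridge: float = 1e-3,
    participant_ids: Optional[Sequence[str]] = None,
    positive_label: int = 1,
    threshold: float = 0.5,
) -> ClassificationReport:
    """Leave-one-out cross-validation of the diagnostic model.

    Each of the n folds refits the standardizer and the logistic model on
    the other n-1 rows, records the held-out probability of the positive
    (patient) class, and labels it by the 0.5 threshold. Metrics are pooled
    over folds with the patient group as the positive class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    if n < 4:
        raise ValidationError("LOOCV needs at least 4 observations")
    if min((y == c).sum() for c in np.unique(y)) < 2:
        raise ValidationError("each class needs at least 2 members")
    if participant_ids is None:
        participant_ids = [f"s{i}" for i in range(n)]
    probs = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_train = y[mask]
        if len(np.unique(y_train)) < 2:
            raise ValidationError(f"fold {i}: training data has a single class")
        clf = LogisticDiagnosticClassifier(ridge=ridge).fit(X[mask], y_train)
        pos_col = int(np.where(clf.classes_ == positive_label)[0][0])
        probs[i] = clf.predict_proba(X[i : i + 1])[0, pos_col]
    y_pred = (probs >= threshold).astype(int)
    y_true = (y == positive_label).astype(int)
    tp = int(((y_pred == 1) & (y_true == 1)).sum())
    fp = int(((y_pred == 1) & (y_true == 0)).sum())
    fn = int(((y_pred == 0) & (y_true == 1)).sum())
    accuracy = float((y_pred == y_true).mean())
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    auc, points = roc_auc(probs, y_true)
    per_fold = pd.DataFrame(
        {
            "participant_id": list(participant_ids),
            "y_true": y_true,
            "probability": probs,
            "y_pred": y_pred,
        }
    )
    return ClassificationReport(
        per_fold=per_fold,
        accuracy=accuracy,
        precision=float(precision),
        recall=float(recall),
        auc=auc,
        roc_points=points,
    )


def ablate(
    X: pd.DataFrame, y, drop: str, ridge: float = 1e-3, **kwargs
) -> ClassificationReport:
    """LOOCV after removing one named predictor column."""
    if not isinstance(X, pd.DataFrame):
        raise ValidationError("ablate requires a DataFrame with named columns")
    if drop not in X.columns:
        raise ValidationError(f"unknown predictor {drop!r}; have {list(X.columns)}")
    return loocv(X.drop(columns=[drop]).to_numpy(), y, ridge=ridge, **kwargs)
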