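"""Performance measures (AUC, MCC, sensitivity/specificity/accuracy) and the
repeated stratified cross-validation harness.

AUC is the Mann-Whitney probability that a positive-class score outranks a
negative-class one, ties half-credited — identical to the trapezoidal area
under the empirical ROC and well-defined for the discrete vote fractions the
ensemble emits.  MCC is the chance-corrected correlation of a binary
confusion matrix, the more informative measure under the heavy class
imbalance typical of prognosis cohorts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_io import BAD, GOOD
from .errors import DataError

logger = logging.getLogger(__name__)


def auc(scores, labels) -> float:
    """Area under the ROC curve via the rank-sum (Mann-Whitney) identity."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    pos = s[y == GOOD]
    neg = s[y == BAD]
    if len(pos) == 0 or len(neg) == 0:
        raise DataError("AUC needs both classes present")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    return float((r_pos - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg)))


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient; any zero marginal makes it 0."""
    if min(tp, fp, tn, fn) < 0:
        raise DataError("confusion counts must be nonnegative")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(float(denom)))


@dataclass
class EvaluationReport:
    auc: float
    mcc: float
    sensitivity: float
    specificity: float
    accuracy: float
    tp: int
    fp: int
    tn: int
    fn: int

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "mcc": self.mcc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
        }


def evaluate_predictions(scores, predicted, labels) -> EvaluationReport:
    """Full report from continuous scores, hard classes and true labels.

    Sensitivity/specificity with an empty class denominator are reported as
    0.0 (they carry no information there; AUC still requires both classes).
    """
    y = np.asarray(labels)
    p = np.asarray(predicted)
    tp = int(((p == GOOD) & (y == GOOD)).sum())
    fp = int(((p == GOOD) & (y == BAD)).sum())
    tn = int(((p == BAD) & (y == BAD)).sum())
    fn = int(((p == BAD) & (y == GOOD)).sum())
    total = tp + fp + tn + fn
    return EvaluationReport(
        auc=auc(scores, y),
        mcc=mcc(tp, fp, tn, fn),
        sensitivity=tp / (tp + fn) if tp + fn else 0.0,
        specificity=tn / (tn + fp) if tn + fp else 0.0,
        accuracy=(tp + tn) / total if total else 0.0,
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def repeated_cv(
    make_estimator,
    X: pd.DataFrame,
    y: pd.Series,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> list[EvaluationReport]:
    """Repeated stratified k-fold CV with the whole pipeline refit per fold.

    *make_estimator* returns a fresh trainable object exposing
    ``fit(X_train, y_train)``, ``score(X_test)`` (continuous) and
    ``predict(X_test)`` (hard classes); a fresh instance is built inside
    every fold, so feature filtering and module selection cannot leak into
    the held-out columns.  One report per repeat (pooled out-of-fold
    predictions).
    """
    from .ensemble import stratified_folds  # local import avoids a cycle

    yy = y.loc[X.columns]
    rng = np.random.default_rng(seed)
    fold_seeds = rng.integers(0, 2**31 - 1, size=repeats)
    reports = []
    for r in range(repeats):
        folds = stratified_folds(yy, k, int(fold_seeds[r]))
        scores = np.empty(X.shape[1])
        classes = np.empty(X.shape[1], dtype=int)
        for train_idx, test_idx in folds:
            est = make_estimator()
            est.fit(X.iloc[:, train_idx], yy.iloc[train_idx])
            test_cols = X.iloc[:, test_idx]
            scores[test_idx] = np.asarray(est.score(test_cols), float)
            classes[test_idx] = np.asarray(est.predict(test_cols), int)
        reports.append(evaluate_predictions(scores, classes, yy))
    return reports


def summarize_reports(reports: list[EvaluationReport]) -> dict:
    """Mean and sd of each metric across repeats."""
    out = {}
    for name in ("auc", "mcc", "sensitivity", "specificity", "accuracy"):
        vals = np.array([getattr(r, name) for r in reports], float)
        out[f"{name}_mean"] = float(vals.mean())
        out[f"{name}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return out
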