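"""Nearest-centroid (mean-vector) classification.

The model stores the per-class mean vectors C+ (good outcome) and C- (bad
outcome).  A sample s is scored by y = <s - (C+ + C-)/2, C+ - C->; positive y
assigns the positive (good-outcome) class, zero or negative y the negative
class.  |w| with w = C+ - C- is also the feature-ranking weight used by the
flat baseline classifiers.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import BAD, GOOD
from .errors import DataError


@dataclass
class CentroidModel:
    feature_keys: list[tuple[str, str]] | list[str]
    c_plus: np.ndarray
    c_minus: np.ndarray
    n_plus: int
    n_minus: int

    @property
    def c_mid(self) -> np.ndarray:
        return (self.c_plus + self.c_minus) / 2.0

    @property
    def w(self) -> np.ndarray:
        return self.c_plus - self.c_minus

    def to_dict(self) -> dict:
        return {
            "feature_keys": [list(k) if isinstance(k, tuple) else k for k in self.feature_keys],
            "c_plus": [float.hex(float(v)) for v in self.c_plus],
            "c_minus": [float.hex(float(v)) for v in self.c_minus],
            "n_plus": int(self.n_plus),
            "n_minus": int(self.n_minus),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CentroidModel":
        keys = [tuple(k) if isinstance(k, list) else k for k in d["feature_keys"]]
        return cls(
            feature_keys=keys,
            c_plus=np.array([float.fromhex(v) for v in d["c_plus"]]),
            c_minus=np.array([float.fromhex(v) for v in d["c_minus"]]),
            n_plus=int(d["n_plus"]),
            n_minus=int(d["n_minus"]),
        )


def _align_labels(X: pd.DataFrame, y: pd.Series) -> np.ndarray:
    missing = [s for s in X.columns if s not in y.index]
    if missing:
        raise DataError(f"samples without labels: {missing[:5]}")
    return y.loc[X.columns].to_numpy()


def fit_centroid(X: pd.DataFrame, y: pd.Series) -> CentroidModel:
    """Fit class centroids on a features x samples matrix.

    *y* maps sample id -> class (1 good/positive, 0 bad/negative); both
    classes must be present and X must be NaN-free.
    """
    if X.isna().to_numpy().any():
        raise DataError("NaN in feature matrix; impute or drop before fitting")
    yy = _align_labels(X, y)
    pos = yy == GOOD
    neg = yy == BAD
    if not pos.any() or not neg.any():
        raise DataError("both classes must be present to fit a centroid model")
    values = X.to_numpy(float)
    return CentroidModel(
        feature_keys=list(X.index),
        c_plus=values[:, pos].mean(axis=1),
        c_minus=values[:, neg].mean(axis=1),
        n_plus=int(pos.sum()),
        n_minus=int(neg.sum()),
    )


def decision_values(model: CentroidModel, X: pd.DataFrame) -> np.ndarray:
    """Signed decision value per sample (column) of X.

    X may contain extra features; the model's features are extracted in model
    order.  Missing features are an error (frozen feature lists from training
    are the contract).
    """
    try:
        sub = X.loc[model.feature_keys]
    except KeyError as exc:
        raise DataError(f"input lacks model features: {exc}") from exc
    values = sub.to_numpy(float)
    if np.isnan(values).any():
        raise DataError("NaN among model features at predict time")
    return (values - model.c_mid[:, None]).T @ model.w


def decision_value(model: CentroidModel, s: np.ndarray) -> float:
    """Decision value for one raw feature vector (model feature order)."""
    s = np.asarray(s, float)
    if s.shape != (len(model.feature_keys),):
        raise DataError(
            f"feature vector of length {s.shape} does not match {len(model.feature_keys)} model features"
        )
    return float((s - model.c_mid) @ model.w)


def predict(model: CentroidModel, X: pd.DataFrame) -> np.ndarray:
    """Hard class per sample: positive (1) iff y > 0, else negative (0)."""
    return np.where(decision_values(model, X) > 0, GOOD, BAD)


def rank_features(model: CentroidModel) -> list:
    """Features sorted by |w| descending; ties keep original order."""
    w = np.abs(model.w)
    order = sorted(range(len(w)), key=lambda i: (-w[i], i))
    return [model.feature_keys[i] for i in order]
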