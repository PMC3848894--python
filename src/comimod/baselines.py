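"""Comparison classifiers: flat top-k centroid models on miRNA, mRNA or CoMi
feature spaces, and gene-set-statistic (set-median / set-mean) features.

The flat classifier ranks features once by the centroid weight |w| on the
full training data, sweeps the number of retained features k (1..200 by
default) with shared stratified CV folds, and keeps the k with the best
pooled out-of-fold AUC (ties go to the smallest k).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centroid import CentroidModel, fit_centroid, rank_features
from .data_io import GeneSetCollection
from .ensemble import stratified_folds
from .errors import DataError
from .evaluation import auc

logger = logging.getLogger(__name__)

FEATURE_SPACES = ("mirna", "mrna", "comi", "set_stat")


@dataclass
class FlatClassifierModel:
    feature_space: str
    selected_features: list
    model: CentroidModel
    k: int
    cv_auc: float
    cv_auc_by_k: dict[int, float] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kind": "flat",
            "feature_space": self.feature_space,
            "selected_features": [
                list(f) if isinstance(f, tuple) else f for f in self.selected_features
            ],
            "model": self.model.to_dict(),
            "k": int(self.k),
            "cv_auc": float(self.cv_auc),
            "cv_auc_by_k": {str(k): float(v) for k, v in self.cv_auc_by_k.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FlatClassifierModel":
        return cls(
            feature_space=d["feature_space"],
            selected_features=[tuple(f) if isinstance(f, list) else f
                               for f in d["selected_features"]],
            model=CentroidModel.from_dict(d["model"]),
            k=int(d["k"]),
            cv_auc=float(d["cv_auc"]),
            cv_auc_by_k={int(k): v for k, v in d.get("cv_auc_by_k", {}).items()},
            provenance=d.get("provenance", {}),
        )


def _prefix_oof_decisions(
    X: pd.DataFrame,
    y: pd.Series,
    ranked: list,
    folds,
    rank_in_fold: bool,
) -> np.ndarray:
    """Out-of-fold decision values for every prefix length of the ranking.

    Returns (n_features, n_samples): row k-1 holds the decision values of the
    top-k centroid classifier.  Decision values for all prefixes come from
    one cumulative sum of per-feature contributions (s_j - mid_j) * w_j in
    ranked order.
    """
    values = X.to_numpy(float)
    pos_of = {f: i for i, f in enumerate(X.index)}
    out = np.empty((X.shape[0], X.shape[1]))
    for train_idx, test_idx in folds:
        model = fit_centroid(X.iloc[:, train_idx], y.iloc[train_idx])
        order = rank_features(model) if rank_in_fold else ranked
        rows = np.array([pos_of[f] for f in order])
        contrib = (values[rows][:, test_idx] - model.c_mid[rows, None]) * model.w[rows, None]
        out[:, test_idx] = np.cumsum(contrib, axis=0)
    return out


def fit_flat(
    X: pd.DataFrame,
    y: pd.Series,
    k_grid=None,
    folds: int = 5,
    seed: int = 0,
    rank_in_fold: bool = False,
    feature_space: str = "mrna",
) -> FlatClassifierModel:
    """Top-k centroid classifier with CV-chosen k.

    Ranking uses the full training data once by default (set *rank_in_fold*
    for the stricter per-fold re-ranking).  *k_grid* defaults to 1..200,
    truncated to the number of available features with a warning.
    """
    yy = y.loc[X.columns]
    n_features = X.shape[0]
    if k_grid is None:
        k_grid = range(1, 201)
    k_grid = sorted({int(k) for k in k_grid})
    if any(k < 1 for k in k_grid):
        raise DataError("k_grid entries must be >= 1")
    if k_grid[-1] > n_features:
        logger.warning("k_grid truncated to %d available features", n_features)
        k_grid = [k for k in k_grid if k <= n_features]
        if not k_grid:
            raise DataError("no usable k in k_grid")
    full_model = fit_centroid(X, yy)
    ranked = rank_features(full_model)
    fold_list = stratified_folds(yy, folds, seed)
    oof = _prefix_oof_decisions(X, yy, ranked, fold_list, rank_in_fold)
    cv_auc_by_k = {k: auc(oof[k - 1], yy) for k in k_grid}
    best_k = max(k_grid, key=lambda k: (cv_auc_by_k[k], -k))
    top = ranked[:best_k]
    refit = fit_centroid(X.loc[top], yy)
    return FlatClassifierModel(
        feature_space=feature_space,
        selected_features=top,
        model=refit,
        k=best_k,
        cv_auc=cv_auc_by_k[best_k],
        cv_auc_by_k=cv_auc_by_k,
    )


def set_statistic_features(
    expr: pd.DataFrame,
    sets: GeneSetCollection,
    statistic: str = "median",
    min_measured: int = 2,
) -> pd.DataFrame:
    """Per-set summary expression (sets x samples).

    Entry (s, j) is the median (or mean) expression of set s's measured
    members in sample j; sets with fewer than *min_measured* measured members
    are dropped with a warning.
    """
    if statistic not in {"median", "mean"}:
        raise DataError(f"statistic must be 'median' or 'mean', got {statistic!r}")
    reducer = np.nanmedian if statistic == "median" else np.nanmean
    measured = set(expr.index)
    rows, keys, dropped = [], [], 0
    for set_id in sets:
        members = [g for g in sets.members(set_id) if g in measured]
        if len(members) < min_measured:
            dropped += 1
            continue
        rows.append(reducer(expr.loc[members].to_numpy(float), axis=0))
        keys.append(set_id)
    if dropped:
        logger.warning("set_statistic_features: dropped %d set(s) with < %d measured members",
                       dropped, min_measured)
    if not rows:
        raise DataError("no gene set with enough measured members")
    return pd.DataFrame(np.vstack(rows), index=pd.Index(keys, name="set_id"),
                        columns=expr.columns)
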