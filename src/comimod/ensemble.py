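"""Module-wise weak centroid classifiers, cross-validated module selection,
and the majority-voting ensemble.

Each GO-term module trains one centroid classifier on its CoMi rows.  Modules
are screened by stratified k-fold cross-validation: the AUC of the pooled
out-of-fold decision values must reach the selection threshold (0.6 by
default).  Selected weak classifiers are refit on all training samples and
vote; the vote fraction is the ensemble's continuous score.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .centroid import CentroidModel, decision_values, fit_centroid
from .data_io import BAD, GOOD
from .errors import DataError, NoModulesSelectedError
from .evaluation import auc
from .modules import Module, build_modules

logger = logging.getLogger(__name__)


@dataclass
class WeakClassifier:
    module: Module
    model: CentroidModel
    cv_auc: float

    def to_dict(self) -> dict:
        return {
            "gobp_id": self.module.gobp_id,
            "member_features": [list(k) for k in self.module.member_features],
            "model": self.model.to_dict(),
            "cv_auc": float(self.cv_auc),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WeakClassifier":
        module = Module(d["gobp_id"], [tuple(k) for k in d["member_features"]])
        return cls(module=module, model=CentroidModel.from_dict(d["model"]), cv_auc=d["cv_auc"])


@dataclass
class EnsembleModel:
    weak: list[WeakClassifier]
    selection_threshold: float
    feature_keys: list[tuple[str, str]] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def module_ids(self) -> list[str]:
        return [w.module.gobp_id for w in self.weak]

    def to_dict(self) -> dict:
        return {
            "kind": "ensemble",
            "selection_threshold": float(self.selection_threshold),
            "feature_keys": [list(k) for k in self.feature_keys],
            "weak": [w.to_dict() for w in self.weak],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleModel":
        return cls(
            weak=[WeakClassifier.from_dict(w) for w in d["weak"]],
            selection_threshold=d["selection_threshold"],
            feature_keys=[tuple(k) for k in d.get("feature_keys", [])],
            provenance=d.get("provenance", {}),
        )


def stratified_folds(y: pd.Series, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shared stratified fold assignment (train_idx, test_idx) pairs."""
    counts = y.value_counts()
    if counts.min() < k:
        raise DataError(f"need >= {k} samples per class for {k}-fold stratified CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y.to_numpy()))


def module_cv_auc(
    profile: pd.DataFrame,
    module: Module,
    y: pd.Series,
    folds: list[tuple[np.ndarray, np.ndarray]],
) -> float:
    """AUC of pooled out-of-fold decision values for one module."""
    X = profile.loc[module.member_features]
    yy = y.loc[profile.columns]
    scores = np.empty(X.shape[1])
    for train_idx, test_idx in folds:
        model = fit_centroid(X.iloc[:, train_idx], yy.iloc[train_idx])
        scores[test_idx] = decision_values(model, X.iloc[:, test_idx])
    return auc(scores, yy)


def select_modules(
    profile: pd.DataFrame,
    modules: list[Module],
    y: pd.Series,
    k_folds: int = 5,
    threshold: float = 0.6,
    seed: int = 0,
) -> list[WeakClassifier]:
    """Screen modules by CV AUC and refit the survivors on all samples.

    The same fold assignment (fixed by *seed*) is reused for every module so
    the AUCs are comparable.  Raises NoModulesSelectedError when nothing
    reaches *threshold*.
    """
    yy = y.loc[profile.columns]
    folds = stratified_folds(yy, k_folds, seed)
    selected: list[WeakClassifier] = []
    for module in modules:
        cv_auc = module_cv_auc(profile, module, yy, folds)
        if cv_auc >= threshold:
            model = fit_centroid(profile.loc[module.member_features], yy)
            selected.append(WeakClassifier(module=module, model=model, cv_auc=cv_auc))
    if not selected:
        raise NoModulesSelectedError(
            f"no module reached CV AUC >= {threshold}; consider lowering the threshold"
        )
    logger.info("selected %d/%d modules at AUC >= %.3g", len(selected), len(modules), threshold)
    return selected


def fit_ensemble(
    profile: pd.DataFrame,
    y: pd.Series,
    min_module_size: int = 6,
    k_folds: int = 5,
    threshold: float = 0.6,
    seed: int = 0,
    provenance: dict | None = None,
) -> EnsembleModel:
    """Convenience wrapper: build modules from a filtered profile, select, assemble."""
    modules = build_modules(profile, min_module_size=min_module_size)
    weak = select_modules(profile, modules, y, k_folds=k_folds, threshold=threshold, seed=seed)
    return EnsembleModel(
        weak=weak,
        selection_threshold=threshold,
        feature_keys=list(profile.index),
        provenance=provenance or {},
    )


def _votes_and_sums(model: EnsembleModel, profile: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if not model.weak:
        raise DataError("ensemble has no weak classifiers")
    dv = np.vstack([decision_values(w.model, profile) for w in model.weak])
    return (dv > 0), dv.sum(axis=0)


def score_ensemble(model: EnsembleModel, profile: pd.DataFrame) -> pd.Series:
    """Vote fraction (positive votes / number of weak classifiers) per sample."""
    votes, _ = _votes_and_sums(model, profile)
    return pd.Series(votes.mean(axis=0), index=profile.columns, name="vote_fraction")


def predict_ensemble(model: EnsembleModel, profile: pd.DataFrame) -> pd.DataFrame:
    """Majority-vote class and vote fraction per sample.

    An exact vote tie (possible with an even number of weak classifiers) is
    resolved by the sign of the summed continuous decision values, a zero sum
    going to the negative class.
    """
    votes, dv_sum = _votes_and_sums(model, profile)
    frac = votes.mean(axis=0)
    cls = np.where(frac > 0.5, GOOD, np.where(frac < 0.5, BAD, np.where(dv_sum > 0, GOOD, BAD)))
    return pd.DataFrame(
        {"label": cls.astype(int), "vote_fraction": frac}, index=profile.columns
    )


class EnsemblePipeline:
    """Leakage-free trainable wrapper: profile filtering, module building and
    AUC-based selection are all refit on whatever training columns ``fit``
    receives.

    Operates on a *raw* (unfiltered) CoMi profile; CoMi scores themselves are
    per-sample quantities, so computing them once for all samples leaks
    nothing.  ``frozen_modules`` reproduces the original protocol in which the
    module list was selected once on the full cohort (leaky; off by default).
    ``on_empty`` controls what happens when no module passes the threshold:
    "error" raises, "all" votes over every module (useful for null
    calibration, where nothing may pass).
    """

    def __init__(
        self,
        drop_fraction: float = 0.10,
        min_module_size: int = 6,
        k_folds: int = 5,
        threshold: float = 0.6,
        seed: int = 0,
        frozen_modules: list[Module] | None = None,
        on_empty: str = "error",
    ):
        if on_empty not in {"error", "all"}:
            raise DataError("on_empty must be 'error' or 'all'")
        self.drop_fraction = drop_fraction
        self.min_module_size = min_module_size
        self.k_folds = k_folds
        self.threshold = threshold
        self.seed = seed
        self.frozen_modules = frozen_modules
        self.on_empty = on_empty
        self.model_: EnsembleModel | None = None

    def fit(self, raw_profile: pd.DataFrame, y: pd.Series) -> "EnsemblePipeline":
        from .comi import filter_profile

        filtered = filter_profile(raw_profile, drop_fraction=self.drop_fraction)
        if self.frozen_modules is not None:
            modules = [m for m in self.frozen_modules
                       if all(k in filtered.index for k in m.member_features)]
        else:
            modules = build_modules(filtered, min_module_size=self.min_module_size)
        yy = y.loc[filtered.columns]
        try:
            weak = select_modules(filtered, modules, yy, k_folds=self.k_folds,
                                  threshold=self.threshold, seed=self.seed)
        except NoModulesSelectedError:
            if self.on_empty == "error":
                raise
            logger.warning("no module passed AUC >= %.3g; voting over all %d modules",
                           self.threshold, len(modules))
            weak = select_modules(filtered, modules, yy, k_folds=self.k_folds,
                                  threshold=0.0, seed=self.seed)
        self.model_ = EnsembleModel(
            weak=weak, selection_threshold=self.threshold, feature_keys=list(filtered.index)
        )
        return self

    def _require_fitted(self) -> EnsembleModel:
        if self.model_ is None:
            raise DataError("pipeline is not fitted")
        return self.model_

    def score(self, profile: pd.DataFrame) -> pd.Series:
        return score_ensemble(self._require_fitted(), profile)

    def predict(self, profile: pd.DataFrame) -> pd.Series:
        return predict_ensemble(self._require_fitted(), profile)["label"]
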