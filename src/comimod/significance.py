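"""Inference on selected module sets: resampling specificity and
cross-cohort stability.

The specificity test asks whether the AUC-selected modules beat ensembles of
randomly drawn module sets of the same size (trained on the training cohort,
evaluated on a disjoint test cohort; the random sets skip the AUC screen).
The stability test scores the overlap of two independently selected module
sets against the hypergeometric null over the shared module universe.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .centroid import decision_values, fit_centroid
from .comi import hypergeom_tail
from .errors import DataError
from .evaluation import auc
from .modules import Module


@dataclass
class ResamplingResult:
    observed_auc: float
    null_aucs: np.ndarray
    p_value: float

    def to_dict(self) -> dict:
        return {
            "observed_auc": self.observed_auc,
            "p_value": self.p_value,
            "n_resamples": int(len(self.null_aucs)),
            "null_mean": float(self.null_aucs.mean()),
            "null_sd": float(self.null_aucs.std(ddof=1)) if len(self.null_aucs) > 1 else 0.0,
        }


@dataclass
class OverlapResult:
    n_universe: int
    n_set_a: int
    n_set_b: int
    n_common: int
    p_value: float

    @property
    def pct_of_a(self) -> float:
        return 100.0 * self.n_common / self.n_set_a

    @property
    def pct_of_b(self) -> float:
        return 100.0 * self.n_common / self.n_set_b

    def to_dict(self) -> dict:
        return {
            "n_universe": self.n_universe,
            "n_set_a": self.n_set_a,
            "n_set_b": self.n_set_b,
            "n_common": self.n_common,
            "p_value": self.p_value,
            "pct_of_a": self.pct_of_a,
            "pct_of_b": self.pct_of_b,
        }


def _vote_matrix(
    modules: list[Module],
    train_profile: pd.DataFrame,
    train_y: pd.Series,
    test_profile: pd.DataFrame,
) -> np.ndarray:
    """Boolean votes (modules x test samples) of centroid models fit on train."""
    rows = []
    for module in modules:
        model = fit_centroid(train_profile.loc[module.member_features], train_y)
        rows.append(decision_values(model, test_profile) > 0)
    return np.vstack(rows)


def specificity_test(
    all_modules: list[Module],
    selected: list[Module],
    train: tuple[pd.DataFrame, pd.Series],
    test: tuple[pd.DataFrame, pd.Series],
    B: int = 10_000,
    seed: int = 0,
) -> ResamplingResult:
    """Empirical p-value of the selected modules' test AUC against random sets.

    Each of the *B* null draws samples ``len(selected)`` modules uniformly
    without replacement from *all_modules*, combines their train-fit centroid
    classifiers by majority vote with no AUC screen, and records the test
    AUC of the vote fraction.  The add-one estimator
    p = (1 + #{null >= observed}) / (B + 1) never reports exactly zero.
    """
    if B < 1:
        raise DataError("B must be >= 1")
    if not selected:
        raise DataError("no selected modules")
    if len(selected) >= len(all_modules):
        raise DataError("selected set must be a strict subset of all modules (null is degenerate)")
    train_profile, train_y = train
    test_profile, test_y = test
    train_y = train_y.loc[train_profile.columns]
    test_y = test_y.loc[test_profile.columns]

    obs_votes = _vote_matrix(selected, train_profile, train_y, test_profile)
    observed = auc(obs_votes.mean(axis=0), test_y)

    votes = _vote_matrix(all_modules, train_profile, train_y, test_profile)
    rng = np.random.default_rng(seed)
    null_aucs = np.empty(B)
    n_pick = len(selected)
    for b in range(B):
        idx = rng.choice(len(all_modules), size=n_pick, replace=False)
        null_aucs[b] = auc(votes[idx].mean(axis=0), test_y)
    p = (1 + int((null_aucs >= observed).sum())) / (B + 1)
    return ResamplingResult(observed_auc=observed, null_aucs=null_aucs, p_value=p)


def stability_test(set_a, set_b, universe) -> OverlapResult:
    """Hypergeometric overlap of two module-id sets within a shared universe."""
    a, b, u = set(set_a), set(set_b), set(universe)
    if not u:
        raise DataError("empty module universe")
    if not a <= u or not b <= u:
        raise DataError("both module sets must be subsets of the universe")
    if not a or not b:
        raise DataError("both module sets must be non-empty")
    x = len(a & b)
    p = hypergeom_tail(x, M=len(u), K=len(a), N=len(b))
    return OverlapResult(
        n_universe=len(u), n_set_a=len(a), n_set_b=len(b), n_common=x, p_value=p
    )
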