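"""Random-forest case-control discrimination from vOTU profiles.

A 1000-tree random forest scores samples, the ROC/AUC is computed from
those scores with the rank (Mann-Whitney) formulation — half credit for
score ties, identical to the trapezoidal area under the empirical ROC —
and a stratified bootstrap percentile interval provides the 95% CI.
Feature importances (mean impurity decrease) drive the top-k
feature-subset AUC curve: features are ranked once on the full model,
the forest is retrained on each top-k subset, and the best k is the
smallest k attaining the maximal AUC.

The evaluation scheme matters at small n: out-of-bag (OOB) votes are the
default, with resubstitution and 5-fold cross-validation also available,
because near-1 resubstitution AUCs are optimistic.  The one-pass
ranking-then-evaluating subset scheme shares training information with
the ranking and is therefore itself optimistic; that caveat is surfaced
in the result rather than hidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from scipy.stats import rankdata

from .profiling import AbundanceProfile


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    curve: pd.DataFrame  # columns fpr, tpr
    evaluation: str
    n_bootstrap: int = 0

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise ValueError("CI must bracket the AUC")


@dataclass
class SubsetCurve:
    k_values: list[int]
    auc_values: list[float]
    best_k: int
    best_auc: float
    note: str = (
        "importance ranking and subset evaluation share training data; "
        "subset AUCs are optimistic"
    )


def _frame(profile) -> pd.DataFrame:
    return profile.data if isinstance(profile, AbundanceProfile) else profile


def rank_auc(scores, labels) -> float:
    """AUC by the rank formulation with half credit for score ties.

    Equals the probability that a random positive outscores a random
    negative, and the trapezoidal area under the empirical ROC curve.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_auc(
    scores,
    labels,
    *,
    n_bootstrap: int = 2000,
    seed: int = 0,
    evaluation: str = "resubstitution",
) -> RocResult:
    """ROC curve, rank-formula AUC, and stratified-bootstrap percentile CI.

    Bootstrap resamples positives and negatives separately (2000 draws by
    default); set ``n_bootstrap=0`` to skip the CI (it then collapses to
    the point estimate).
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    auc = rank_auc(s, y)
    fpr, tpr, _ = roc_curve(y, s)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        pos = np.flatnonzero(y == 1)
        neg = np.flatnonzero(y == 0)
        draws = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            bp = rng.choice(pos, size=len(pos), replace=True)
            bn = rng.choice(neg, size=len(neg), replace=True)
            idx = np.concatenate([bp, bn])
            draws[b] = rank_auc(s[idx], y[idx])
        lo, hi = np.percentile(draws, [2.5, 97.5])
        lo, hi = min(lo, auc), max(hi, auc)
    else:
        lo = hi = auc
    return RocResult(
        auc=auc, ci_low=float(lo), ci_high=float(hi), curve=curve,
        evaluation=evaluation, n_bootstrap=n_bootstrap,
    )


def _scores_for(
    model: RandomForestClassifier,
    X: np.ndarray,
    y: np.ndarray,
    evaluation: str,
    seed: int,
) -> np.ndarray:
    if evaluation == "resub":
        return model.predict_proba(X)[:, 1]
    if evaluation == "oob":
        scores = model.oob_decision_function_[:, 1]
        if np.isnan(scores).any():
            # a sample in every bootstrap draw (vanishingly rare at 1000 trees)
            scores = np.where(np.isnan(scores), 0.5, scores)
        return scores
    if evaluation == "cv5":
        n_min = int(min(np.bincount(y)))
        if n_min < 5:
            raise ValueError(
                f"smallest class has {n_min} samples; use at most {n_min} folds"
            )
        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        fresh = RandomForestClassifier(
            n_estimators=model.n_estimators, random_state=seed
        )
        return cross_val_predict(fresh, X, y, cv=cv, method="predict_proba")[:, 1]
    raise ValueError(f"unknown evaluation {evaluation!r}; legal: oob, cv5, resub")


def train_rf(
    profile,
    design,
    *,
    n_trees: int = 1000,
    seed: int = 0,
    evaluation: str = "oob",
    n_bootstrap: int = 2000,
) -> tuple[RocResult, pd.Series]:
    """Train the forest and return (ROC result, importance ranking).

    Importances are mean impurity decrease, sorted descending with ties
    broken by feature id so the ranking is reproducible for a fixed seed.
    """
    data = _frame(profile)
    y = np.array([1 if l == design.case_label else 0
                  for l in design.label_series().loc[data.index]])
    if min(int(y.sum()), int(len(y) - y.sum())) < 3:
        raise ValueError("need at least 3 samples per class")
    X = data.to_numpy(dtype=float)
    model = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=seed
    )
    model.fit(X, y)
    scores = _scores_for(model, X, y, evaluation, seed)
    roc = roc_auc(scores, y, n_bootstrap=n_bootstrap, seed=seed, evaluation=evaluation)
    importance = pd.Series(model.feature_importances_, index=data.columns)
    importance = importance.iloc[
        sorted(range(len(importance)),
               key=lambda i: (-importance.iloc[i], importance.index[i]))
    ]
    return roc, importance


def default_k_grid(n_features: int) -> list[int]:
    """{1..50} plus {60, 80, 100, ...}, capped at the feature count."""
    grid = list(range(1, min(50, n_features) + 1))
    k = 60
    while k < n_features:
        grid.append(k)
        k += 20
    if n_features not in grid:
        grid.append(n_features)
    return grid


def feature_subset_curve(
    profile,
    design,
    *,
    k_grid: list[int] | None = None,
    n_trees: int = 1000,
    seed: int = 0,
    evaluation: str = "oob",
) -> SubsetCurve:
    """AUC of the forest retrained on the top-k most important features.

    The ranking comes from one full-model fit; ties in the best AUC
    resolve to the smallest k.
    """
    data = _frame(profile)
    if k_grid is None:
        k_grid = default_k_grid(len(data.columns))
    if not k_grid:
        raise ValueError("k grid is empty")
    if max(k_grid) > len(data.columns):
        raise ValueError("k grid exceeds the feature count")
    _, importance = train_rf(
        profile, design, n_trees=n_trees, seed=seed,
        evaluation=evaluation, n_bootstrap=0,
    )
    aucs = []
    for k in k_grid:
        top = list(importance.index[:k])
        roc, _ = train_rf(
            data[top], design, n_trees=n_trees, seed=seed,
            evaluation=evaluation, n_bootstrap=0,
        )
        aucs.append(roc.auc)
    best_idx = int(np.argmax(aucs))  # argmax takes the first (smallest k) on ties
    return SubsetCurve(
        k_values=list(k_grid),
        auc_values=aucs,
        best_k=int(k_grid[best_idx]),
        best_auc=float(aucs[best_idx]),
    )
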