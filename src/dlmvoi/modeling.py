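"""Train/test split, nested-CV objective, and optimized gradient boosting.

The classifier distinguishing clinically significant (CS) from non-CS
lesions is an extreme-gradient-boosting tree ensemble.  Its feature list
and hyperparameters come from sequential model-free optimization of an
objective that (stage 1) runs JMIM feature selection on the training
portions of a randomized five-times-repeated 5-fold split, ranks features
by selection frequency, and (stage 2) scores the top-k features with
10-fold cross-validation of the booster, returning the mean area under the
precision-recall curve (average precision).  The held-out test partition is
never touched before final evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score
from sklearn.model_selection import KFold
from xgboost import XGBClassifier

from .jmim import discretize_table, _jmim_core

__all__ = [
    "SplitSpec", "TrialParams", "FittedModel", "split_cohort",
    "class_weight_center", "select_features_nested", "trial_objective",
    "optimize", "predict", "auprc",
]


@dataclass(frozen=True)
class SplitSpec:
    """4:1 train:test split specification."""

    seed: int = 0
    train_fraction: float = 0.8
    groups: tuple | None = None  # optional patient ids, one per lesion


@dataclass(frozen=True)
class TrialParams:
    """One optimization trial: feature count plus booster hyperparameters."""

    n_features: int = 22
    booster: str = "gbtree"
    n_rounds: int = 17
    max_depth: int = 4
    learning_rate: float = 0.1
    class_weight: float = 1.0
    mi_bins: int = 10

    def __post_init__(self) -> None:
        if self.n_features < 1 or self.n_rounds < 1:
            raise ValueError("n_features and n_rounds must be >= 1")
        if self.class_weight <= 0:
            raise ValueError("class_weight must be > 0")


@dataclass
class FittedModel:
    """Frozen feature list + trained booster + training metadata."""

    features: tuple[str, ...]
    booster: XGBClassifier
    params: TrialParams
    seed: int
    objective_value: float | None = None


def split_cohort(
    n_lesions: int,
    labels: Sequence[int] | None = None,
    spec: SplitSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded, unstratified 4:1 lesion-level split.

    With ``spec.groups`` given, whole patients are assigned to one side so
    no patient spans both sets (sizes then only approximate 4:1).
    """
    spec = spec or SplitSpec()
    if n_lesions < 5:
        raise ValueError("need at least 5 lesions to split 4:1")
    rng = np.random.default_rng(spec.seed)
    n_train = int(np.floor(spec.train_fraction * n_lesions))
    if spec.groups is None:
        perm = rng.permutation(n_lesions)
        return np.sort(perm[:n_train]), np.sort(perm[n_train:])
    groups = np.asarray(spec.groups)
    uniq = rng.permutation(np.unique(groups))
    train_groups: set = set()
    count = 0
    for g in uniq:
        if count >= n_train:
            break
        train_groups.add(g)
        count += int((groups == g).sum())
    is_train = np.isin(groups, list(train_groups))
    return np.flatnonzero(is_train), np.flatnonzero(~is_train)


def class_weight_center(labels: np.ndarray) -> float:
    """Imbalance ratio r = (# negative) / (# positive) on the given rows."""
    y = np.asarray(labels).ravel().astype(bool)
    pos = int(y.sum())
    if pos == 0 or pos == y.size:
        raise ValueError("both classes required")
    return (y.size - pos) / pos


def select_features_nested(
    table: pd.DataFrame,
    labels: np.ndarray,
    k: int,
    seed: int,
    n_repeats: int = 5,
    n_splits: int = 5,
    mi_bins: int = 10,
) -> tuple[str, ...]:
    """Stage-1 robust feature list: JMIM on each training portion of a
    randomized ``n_repeats``-times-repeated ``n_splits``-fold split, features
    ranked by selection frequency (ties by mean selection rank, then column
    order) and the top-k returned.

    Binning is computed once on the full training split (it is unsupervised);
    the repeated folds randomize only which rows JMIM sees."""
    y = np.asarray(labels).ravel()
    cols = list(table.columns)
    X = discretize_table(table, mi_bins)
    freq = np.zeros(len(cols))
    rank_sum = np.zeros(len(cols))
    for rep in range(n_repeats):
        kf = KFold(n_splits=n_splits, shuffle=True,
                   random_state=(seed * 1000 + rep) % (2 ** 31))
        for tr, _ in kf.split(X):
            sel, _crit = _jmim_core(X[tr], y[tr], k)
            for r, fidx in enumerate(sel):
                freq[fidx] += 1
                rank_sum[fidx] += r

    def key(ci):
        f = freq[ci]
        mean_rank = rank_sum[ci] / f if f else np.inf
        return (-f, mean_rank, ci)

    ranked = sorted(range(len(cols)), key=key)
    return tuple(cols[i] for i in ranked[:k])


def _make_booster(params: TrialParams, seed: int) -> XGBClassifier:
    return XGBClassifier(
        booster=params.booster,
        n_estimators=params.n_rounds,
        max_depth=params.max_depth,
        learning_rate=params.learning_rate,
        scale_pos_weight=params.class_weight,
        random_state=seed,
        n_jobs=1,
        eval_metric="logloss",
        tree_method="exact",
        verbosity=0,
    )


def trial_objective(
    train_table: pd.DataFrame,
    labels: np.ndarray,
    params: TrialParams,
    seed: int,
) -> float:
    """Mean average precision over a 10-fold CV at the trial's parameters.

    Stage 1 picks the trial's top-k features on the training rows only;
    stage 2 cross-validates the booster on those features.
    """
    y = np.asarray(labels).ravel().astype(int)
    if params.n_features > train_table.shape[1]:
        raise ValueError("n_features exceeds available features")
    feats = select_features_nested(train_table, y, params.n_features, seed,
                                   mi_bins=params.mi_bins)
    X = train_table[list(feats)].to_numpy()
    kf = KFold(n_splits=10, shuffle=True, random_state=seed)
    scores = []
    for tr, va in kf.split(X):
        if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
            continue  # fold without both classes carries no PR information
        clf = _make_booster(params, seed)
        clf.fit(X[tr], y[tr])
        p = clf.predict_proba(X[va])[:, 1]
        scores.append(average_precision_score(y[va], p))
    if not scores:
        raise ValueError("no validation fold contained both classes")
    return float(np.mean(scores))


def _sample_params(rng: np.random.Generator, r: float, n_features_cap: int) -> TrialParams:
    """One draw from the search space; the class-weight space is centered on
    the training imbalance ratio r (spanning r/2 .. 2r)."""
    return TrialParams(
        n_features=int(rng.integers(2, min(40, n_features_cap) + 1)),
        booster="gbtree",
        n_rounds=int(rng.integers(5, 201)),
        max_depth=int(rng.integers(2, 7)),
        learning_rate=float(np.exp(rng.uniform(np.log(0.01), np.log(0.3)))),
        class_weight=float(np.exp(rng.uniform(np.log(r / 2), np.log(2 * r)))),
    )


def optimize(
    train_table: pd.DataFrame,
    labels: np.ndarray,
    budget: int = 30,
    seed: int = 0,
) -> tuple[TrialParams, FittedModel, list[dict]]:
    """Sequential seeded search over the trial space; returns the argmax
    trial, the final model refit on all training rows with that trial's
    stage-1 feature list, and the full objective trace."""
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if train_table.shape[1] == 0 or len(train_table) == 0:
        raise ValueError("empty training table")
    y = np.asarray(labels).ravel().astype(int)
    r = class_weight_center(y)
    rng = np.random.default_rng(seed)
    trace: list[dict] = []
    best: tuple[float, TrialParams] | None = None
    for t in range(budget):
        params = _sample_params(rng, r, train_table.shape[1])
        value = trial_objective(train_table, y, params, seed)
        trace.append({"trial": t, "value": value, "params": params.__dict__.copy()})
        if best is None or value > best[0]:
            best = (value, params)
    assert best is not None
    value, params = best
    feats = select_features_nested(train_table, y, params.n_features, seed,
                                   mi_bins=params.mi_bins)
    clf = _make_booster(params, seed)
    clf.fit(train_table[list(feats)].to_numpy(), y)
    model = FittedModel(features=feats, booster=clf, params=params, seed=seed,
                        objective_value=value)
    return params, model, trace


def predict(model: FittedModel, table: pd.DataFrame) -> np.ndarray:
    """Per-lesion CS probability scores in [0, 1]."""
    missing = [c for c in model.features if c not in table.columns]
    if missing:
        raise KeyError(f"missing feature columns: {missing[:5]}")
    return model.booster.predict_proba(table[list(model.features)].to_numpy())[:, 1]


def auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve (average precision)."""
    y = np.asarray(labels).ravel().astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    return float(average_precision_score(y, np.asarray(scores).ravel()))
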