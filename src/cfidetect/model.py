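"""Replicated linear SVM classification and NCA-based feature selection.

The evaluation protocol mirrors a replicated hold-out design: for each of 30
replicates the feature table is split 6:4 into training and test rows
(stratified by class), features are standardized with training statistics,
a linear soft-margin SVM is trained with its regularization parameter C
chosen by 5-fold cross-validation over a log-spaced grid spanning
[1e-4, 1e4], and per-class rates plus overall accuracy are recorded on the
test rows.  Two tasks are supported: two-class (normal vs injured, classes 1
and 2 merged) and three-class.

Feature selection uses neighbourhood component analysis (NCA): per-feature
distance weights are learned by maximizing the expected leave-one-out
soft-nearest-neighbour accuracy with an L2 shrinkage penalty; features are
ranked by weight and SVMs are evaluated over the top-m subsets for
m = 1..100 to trace an accuracy-vs-subset-size curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.svm import LinearSVC

from .features import FeatureTable
from .metrics import ReplicateSummary, confusion_rates

__all__ = [
    "TrainConfig",
    "NCAResult",
    "task_labels",
    "split_data",
    "train_svm",
    "run_replicates",
    "nca_objective",
    "nca_rank",
    "incremental_selection",
]


def _default_c_grid() -> np.ndarray:
    # 17 log-spaced points, half-decade steps, spanning [1e-4, 1e4]
    return np.logspace(-4, 4, 17)


@dataclass(frozen=True)
class TrainConfig:
    """Protocol parameters for replicated SVM evaluation."""

    task: str = "two"  # "two" (normal vs injured) or "three"
    split_ratio: float = 0.6  # training fraction of the 6:4 partition
    cv_folds: int = 5
    c_grid: np.ndarray = field(default_factory=_default_c_grid)
    replicates: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("two", "three"):
            raise ValueError("task must be 'two' or 'three'")
        if not (0.0 < self.split_ratio < 1.0):
            raise ValueError("split_ratio must lie in (0, 1)")
        grid = np.asarray(self.c_grid, dtype=float)
        if grid.min() < 1e-4 - 1e-12 or grid.max() > 1e4 + 1e-8:
            raise ValueError("c_grid must stay within [1e-4, 1e4]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def task_labels(labels: pd.Series | np.ndarray, task: str) -> np.ndarray:
    """Map 3-level injury labels to task labels (two-class merges 1 and 2)."""
    y = np.asarray(labels)
    if task == "two":
        return (y > 0).astype(int)
    return y.astype(int)


def _replicate_seeds(master_seed: int, n: int) -> list[int]:
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def split_data(
    table: FeatureTable, config: TrainConfig, replicate_seed: int
) -> tuple[list, list]:
    """Stratified random train/test partition, reproducible from the seed."""
    y = task_labels(table.labels, config.task)
    classes, counts = np.unique(y, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if int(np.floor(cnt * config.split_ratio)) < config.cv_folds:
            raise ValueError(
                f"class {cls} has too few samples ({cnt}) for a "
                f"{config.split_ratio:.0%} split with {config.cv_folds}-fold CV"
            )
    ids = np.asarray(table.df.index)
    train_ids, test_ids = train_test_split(
        ids, train_size=config.split_ratio, stratify=y, random_state=replicate_seed
    )
    return list(train_ids), list(test_ids)


@dataclass
class FittedSVM:
    """A CV-tuned linear soft-margin SVM (one-vs-rest for > 2 classes)."""

    estimator: LinearSVC
    best_c: float
    cv_table: pd.DataFrame  # columns: C, mean_cv_accuracy

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, dtype=float))


def _make_svc(c: float, seed: int) -> LinearSVC:
    # hinge loss = the classical soft-margin primal; one-vs-rest multi-class
    return LinearSVC(C=c, loss="hinge", max_iter=20000, tol=1e-4, random_state=seed)


def train_svm(X, y, config: TrainConfig, seed: int = 0) -> FittedSVM:
    """Grid-search C by stratified k-fold CV and refit on the full training set.

    Ties in CV accuracy resolve to the smaller C (the grid is ascending and
    the first maximum wins).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain at least 2 classes")
    grid = np.sort(np.asarray(config.c_grid, dtype=float))
    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
    scores = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for c in grid:
            acc = cross_val_score(_make_svc(c, seed), X, y, cv=cv, scoring="accuracy")
            scores.append(float(acc.mean()))
        best_idx = int(np.argmax(scores))  # first max -> smallest C on ties
        best_c = float(grid[best_idx])
        est = _make_svc(best_c, seed).fit(X, y)
    return FittedSVM(
        estimator=est,
        best_c=best_c,
        cv_table=pd.DataFrame({"C": grid, "mean_cv_accuracy": scores}),
    )


def run_replicates(
    table: FeatureTable,
    config: TrainConfig,
    input_label: str = "",
    feature_subset: list[str] | None = None,
) -> ReplicateSummary:
    """Run the full replicated protocol and summarize per-replicate rates.

    Each replicate re-splits, re-normalizes on its training rows, re-tunes C
    and evaluates on its held-out rows; all randomness descends from
    ``config.seed`` through per-replicate derived seeds.
    """
    work = table.select_features(feature_subset) if feature_subset else table
    records = []
    for rep_seed in _replicate_seeds(config.seed, config.replicates):
        train_ids, test_ids = split_data(work, config, rep_seed)
        normed = work.normalize(train_ids)
        X_tr = normed.df.loc[train_ids].to_numpy()
        X_te = normed.df.loc[test_ids].to_numpy()
        y_tr = task_labels(normed.labels.loc[train_ids], config.task)
        y_te = task_labels(normed.labels.loc[test_ids], config.task)
        fitted = train_svm(X_tr, y_tr, config, seed=rep_seed)
        y_pred = fitted.predict(X_te)
        rec = confusion_rates(y_te, y_pred, config.task)
        rec["best_C"] = fitted.best_c
        rec["train_acc"] = 100.0 * float(np.mean(fitted.predict(X_tr) == y_tr))
        records.append(rec)
    return ReplicateSummary(
        records=pd.DataFrame(records), input_label=input_label, task=config.task
    )


# ---------------------------------------------------------------------------
# Neighbourhood component analysis feature selection


def nca_objective(
    w: np.ndarray, X: np.ndarray, y: np.ndarray, lam: float
) -> tuple[float, np.ndarray]:
    """Regularized NCA objective (to maximize) and its gradient.

    F(w) = sum_i p_i - lam * sum_r w_r^2, where p_i = sum_{j: y_j = y_i} p_ij
    and p_ij are soft-neighbour probabilities under the weighted L1 distance
    d(x_i, x_j) = sum_r w_r^2 |x_ir - x_jr| (p_ii = 0).  The softmax is
    computed with a log-sum-exp shift so large distances stay finite.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = X.shape
    D = np.abs(X[:, None, :] - X[None, :, :])  # (n, n, d)
    dist = D @ (w**2)  # (n, n)
    np.fill_diagonal(dist, np.inf)
    neg = -dist
    shift = neg.max(axis=1, keepdims=True)
    ex = np.exp(neg - shift)
    p = ex / ex.sum(axis=1, keepdims=True)  # p[i, j] = p_ij
    same = (y[:, None] == y[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)
    p_i = (p * same).sum(axis=1)
    value = float(p_i.sum() - lam * np.sum(w**2))

    # dF/dw_r = 2 w_r * sum_i ( p_i * sum_j p_ij D_ijr - sum_{j in class} p_ij D_ijr )
    #           - 2 lam w_r
    all_term = np.einsum("ij,ijr->r", p * p_i[:, None], D)
    class_term = np.einsum("ij,ijr->r", p * same, D)
    grad = 2.0 * w * (all_term - class_term) - 2.0 * lam * w
    if not np.isfinite(value) or not np.isfinite(grad).all():
        raise FloatingPointError("non-finite NCA objective or gradient")
    return value, grad


@dataclass
class NCAResult:
    """Learned feature weights, ranking and (optionally) the top-m curve."""

    weights: np.ndarray  # non-negative, normalized to max 1
    ranking: np.ndarray  # feature indices by descending weight
    incremental_curve: np.ndarray | None = None  # mean ACC (%) at m = 1..top_m
    incremental_se: np.ndarray | None = None
    selected_size: int | None = None
    feature_names: list[str] | None = None


def nca_rank(
    X,
    y,
    lam: float | None = None,
    seed: int = 0,
    max_iter: int = 100,
    feature_names: list[str] | None = None,
) -> NCAResult:
    """Learn NCA feature weights and rank features by importance.

    ``lam`` defaults to 1 / n_train.  Optimization is bound-constrained
    L-BFGS from uniform initial weights; the reported weights are normalized
    to a maximum of 1.  Ranking ties break by feature index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = X.shape
    if lam is None:
        lam = 1.0 / n
    if lam < 0:
        raise ValueError("regularization lambda must be non-negative")
    w0 = np.ones(d)

    def neg(w):
        v, g = nca_objective(w, X, y, lam)
        return -v, -g

    res = minimize(neg, w0, jac=True, method="L-BFGS-B",
                   bounds=[(0.0, None)] * d, options={"maxiter": max_iter})
    w = np.abs(res.x)
    top = w.max()
    if top > 0:
        w = w / top
    ranking = np.argsort(-w, kind="stable")
    return NCAResult(weights=w, ranking=ranking, feature_names=feature_names)


def incremental_selection(
    table: FeatureTable,
    config: TrainConfig,
    nca: NCAResult | None = None,
    top_m: int = 100,
    lam: float | None = None,
) -> NCAResult:
    """Evaluate SVMs over top-m feature subsets for m = 1..top_m.

    With a precomputed ``nca`` the ranking is held fixed across replicates
    (the one-replicate-curve view); otherwise NCA is refit per replicate on
    that replicate's normalized training rows only, and the curve averages
    the per-replicate accuracies (leakage-safe default).  Returns an
    ``NCAResult`` whose ``selected_size`` is the smallest m with mean ACC >=
    full-feature mean ACC - 1 SE, falling back to the curve argmax.
    """
    n_feat = len(table.feature_names)
    if n_feat < top_m:
        warnings.warn(
            f"only {n_feat} features available; truncating the curve", stacklevel=2
        )
        top_m = n_feat

    rep_seeds = _replicate_seeds(config.seed, config.replicates)
    acc = np.zeros((config.replicates, top_m))
    full_acc = np.zeros(config.replicates)
    weights_sum = np.zeros(n_feat)
    for r, rep_seed in enumerate(rep_seeds):
        train_ids, test_ids = split_data(table, config, rep_seed)
        normed = table.normalize(train_ids)
        X_tr = normed.df.loc[train_ids].to_numpy()
        X_te = normed.df.loc[test_ids].to_numpy()
        y_tr = task_labels(normed.labels.loc[train_ids], config.task)
        y_te = task_labels(normed.labels.loc[test_ids], config.task)
        if nca is None:
            rep_nca = nca_rank(X_tr, y_tr, lam=lam, seed=rep_seed)
        else:
            rep_nca = nca
        weights_sum += rep_nca.weights
        fitted_full = train_svm(X_tr, y_tr, config, seed=rep_seed)
        full_acc[r] = 100.0 * float(np.mean(fitted_full.predict(X_te) == y_te))
        for m in range(1, top_m + 1):
            cols = rep_nca.ranking[:m]
            fitted = train_svm(X_tr[:, cols], y_tr, config, seed=rep_seed)
            acc[r, m - 1] = 100.0 * float(np.mean(fitted.predict(X_te[:, cols]) == y_te))

    curve = acc.mean(axis=0)
    se = acc.std(axis=0, ddof=1) / np.sqrt(config.replicates) if config.replicates > 1 \
        else np.zeros(top_m)
    full_mean = float(full_acc.mean())
    full_se = float(full_acc.std(ddof=1) / np.sqrt(config.replicates)) if (
        config.replicates > 1) else 0.0
    ok = np.flatnonzero(curve >= full_mean - full_se)
    selected = int(ok[0] + 1) if ok.size else int(np.argmax(curve) + 1)

    mean_w = weights_sum / config.replicates
    top = mean_w.max()
    if top > 0:
        mean_w = mean_w / top
    return NCAResult(
        weights=mean_w,
        ranking=np.argsort(-mean_w, kind="stable"),
        incremental_curve=curve,
        incremental_se=se,
        selected_size=selected,
        feature_names=table.feature_names,
    )
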