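"""Marker-panel classification with repeated stratified cross-validation.

A random forest (500 trees, sqrt(p) features per split) is evaluated by
five repeats of stratified five-fold cross-validation: within each repeat
the out-of-fold class probabilities are pooled into one ROC AUC, and the
reported AUC is the mean over repeats.  The 95% CI uses the Hanley-McNeil
rank-statistic standard error on the repeat-averaged out-of-fold
predictions.  Feature importance is permutation-based mean decrease in
accuracy measured on each fold's held-out samples and averaged over folds.
The panel sweep retrains on the top-k most important features over a k
grid, reporting mean and standard deviation of the AUC across independent
repetitions; the best k maximizes the mean AUC, ties broken toward the
smallest panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

N_TREES = 500


@dataclass
class ClassifierReport:
    auc: float
    ci_low: float
    ci_high: float
    per_repeat_auc: list[float]
    importance: pd.Series | None
    scheme: str


@dataclass
class PanelSweep:
    table: pd.DataFrame   # columns: k, mean_auc, sd_auc
    best_k: int
    best_auc: float
    order: list[str] = field(default_factory=list)


def _encode_labels(labels: pd.Series) -> tuple[np.ndarray, str]:
    classes = sorted(pd.unique(labels))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    y = (labels == classes[1]).to_numpy(dtype=int)
    return y, classes[1]


def _forest(seed: int, n_trees: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed,
        n_jobs=1)


def hanley_mcneil_ci(auc: float, n_pos: int, n_neg: int,
                     level: float = 0.95) -> tuple[float, float]:
    """Rank-statistic (Hanley-McNeil) confidence interval for an AUC."""
    from scipy.stats import norm
    a = min(max(auc, 1e-12), 1 - 1e-12)
    q1 = a / (2 - a)
    q2 = 2 * a ** 2 / (1 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a ** 2)
           + (n_neg - 1) * (q2 - a ** 2)) / (n_pos * n_neg)
    z = norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(max(var, 0.0))
    return max(0.0, auc - half), min(1.0, auc + half)


def cv_auc(
    features: pd.DataFrame,
    labels: pd.Series,
    n_repeats: int = 5,
    n_folds: int = 5,
    seed: int = 0,
    n_trees: int = N_TREES,
    compute_importance: bool = True,
    importance_shuffles: int = 3,
) -> ClassifierReport:
    """Repeated stratified k-fold CV of a random forest.

    Per repeat, out-of-fold probabilities are pooled into one AUC; the
    report's AUC is the mean over repeats and its CI is Hanley-McNeil on
    the repeat-averaged predictions.  Importance (optional) is the mean
    decrease in held-out accuracy when a feature's column is permuted,
    averaged over all folds of all repeats.
    """
    labels = labels.loc[features.index]
    y, _pos = _encode_labels(labels)
    x = features.to_numpy(dtype=float)
    n, p = x.shape
    if min((y == 0).sum(), (y == 1).sum()) < n_folds:
        raise ValueError("each class needs at least n_folds samples")

    ss = np.random.SeedSequence(seed)
    repeat_seeds = ss.generate_state(n_repeats)
    perm_rng = np.random.default_rng(ss.spawn(1)[0])

    oof_sum = np.zeros(n)
    per_repeat = []
    imp_drop = np.zeros(p)
    imp_n = 0
    for r in range(n_repeats):
        rseed = int(repeat_seeds[r] % (2 ** 31))
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=rseed)
        oof = np.zeros(n)
        for fold, (tr, te) in enumerate(skf.split(x, y)):
            clf = _forest(rseed + fold, n_trees)
            clf.fit(x[tr], y[tr])
            oof[te] = clf.predict_proba(x[te])[:, 1]
            if compute_importance:
                base_acc = (clf.predict(x[te]) == y[te]).mean()
                for j in range(p):
                    drop = 0.0
                    for _ in range(importance_shuffles):
                        xs = x[te].copy()
                        xs[:, j] = perm_rng.permutation(xs[:, j])
                        acc = (clf.predict(xs) == y[te]).mean()
                        drop += base_acc - acc
                    imp_drop[j] += drop / importance_shuffles
                imp_n += 1
        per_repeat.append(float(roc_auc_score(y, oof)))
        oof_sum += oof

    auc = float(np.mean(per_repeat))
    ci_low, ci_high = hanley_mcneil_ci(
        float(roc_auc_score(y, oof_sum / n_repeats)),
        int(y.sum()), int((1 - y).sum()))
    ci_low, ci_high = min(ci_low, auc), max(ci_high, auc)
    importance = None
    if compute_importance and imp_n:
        importance = pd.Series(imp_drop / imp_n, index=features.columns,
                               name="mean_decrease_accuracy")
    return ClassifierReport(
        auc=auc, ci_low=ci_low, ci_high=ci_high,
        per_repeat_auc=per_repeat, importance=importance,
        scheme=f"{n_repeats}x{n_folds}-fold stratified CV, "
               f"{n_trees}-tree random forest")


def importance_ranking(report: ClassifierReport) -> list[str]:
    """Features ordered by decreasing importance, ties by id."""
    if report.importance is None:
        raise ValueError("report carries no importances")
    s = report.importance
    order = sorted(s.index, key=lambda f: (-s[f], f))
    return order


def panel_sweep(
    features: pd.DataFrame,
    labels: pd.Series,
    order: list[str],
    k_grid: list[int] | None = None,
    n_repetitions: int = 10,
    n_folds: int = 5,
    seed: int = 0,
    n_trees: int = N_TREES,
) -> PanelSweep:
    """AUC as a function of panel size along an importance ordering.

    For each k, the model is retrained on the top-k features only, with
    ``n_repetitions`` independent stratified CV runs; the sweep records the
    mean and standard deviation of the per-run pooled AUC.
    """
    p = len(order)
    if k_grid is None:
        k_grid = [k for k in range(5, min(50, p) + 1, 5)] or [p]
    if any(k > p or k < 1 for k in k_grid):
        raise ValueError("k grid outside [1, #features]")
    k_grid = sorted(set(k_grid))
    labels = labels.loc[features.index]
    y, _ = _encode_labels(labels)

    rows = []
    for k in k_grid:
        x = features[order[:k]].to_numpy(dtype=float)
        aucs = np.empty(n_repetitions)
        for rep in range(n_repetitions):
            rseed = seed * 1_000_003 % (2 ** 31 - 1) + 31 * k + rep
            skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                  random_state=rseed)
            oof = np.zeros(len(y))
            for fold, (tr, te) in enumerate(skf.split(x, y)):
                clf = _forest(rseed + fold + 1, n_trees)
                clf.fit(x[tr], y[tr])
                oof[te] = clf.predict_proba(x[te])[:, 1]
            aucs[rep] = roc_auc_score(y, oof)
        rows.append({"k": k, "mean_auc": aucs.mean(),
                     "sd_auc": aucs.std(ddof=0)})
    table = pd.DataFrame(rows)
    best = table.loc[table["mean_auc"].idxmax()]
    # ties toward parsimony: idxmax takes the first (smallest k) maximum
    return PanelSweep(table=table, best_k=int(best["k"]),
                      best_auc=float(best["mean_auc"]), order=list(order))
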