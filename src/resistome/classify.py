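"""Per-drug resistance classification on selected core genes.

Protocol: per-feature Z-score standardization fitted on training data only;
SMOTE oversampling of the minority class applied *inside* each training fold
(never to validation data — oversampling before splitting leaks synthetic
copies of validation points into training); random-forest hyperparameters
chosen by grid search under stratified 5-fold cross-validation scored by
mean fold ROC AUC, without a separate test set; evaluation by ROC and PR
curves (mean ± sd over folds) and a pooled confusion matrix at probability
threshold 0.5; per-gene Gini importances from a final refit on the full
(balanced) data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .types import ResistomeError

log = logging.getLogger(__name__)


def zscore_fit_apply(train: np.ndarray, *apply_to: np.ndarray) -> tuple[np.ndarray, ...]:
    """Standardize features using mean/sd estimated on ``train`` only.

    Population standard deviation; constant features map to all-zero
    columns. Returns the transformed train matrix followed by each
    ``apply_to`` matrix transformed with the train statistics.
    """
    train = np.asarray(train, dtype=float)
    if train.size == 0:
        raise ResistomeError("empty training matrix")
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)

    def tf(m: np.ndarray) -> np.ndarray:
        out = (np.asarray(m, dtype=float) - mean) / safe
        out[:, sd == 0] = 0.0
        return out

    return (tf(train), *(tf(m) for m in apply_to))


def smote_oversample(minority: np.ndarray, k_neighbors: int, n_synthetic: int,
                     rng: np.random.Generator) -> np.ndarray:
    """SMOTE interpolation: synthesize minority points between neighbors.

    Each synthetic point is ``x + lam * (x_nn - x)`` with ``lam ~ U(0, 1)``,
    ``x`` a uniformly sampled minority point and ``x_nn`` one of its
    ``k_neighbors`` nearest minority neighbors (Euclidean, excluding itself).
    ``k_neighbors`` is shrunk to ``|minority| - 1`` with a warning if needed.
    """
    minority = np.asarray(minority, dtype=float)
    m = minority.shape[0]
    if m < 2:
        raise ResistomeError("SMOTE needs at least 2 minority points to interpolate")
    if n_synthetic == 0:
        return np.empty((0, minority.shape[1]))
    if k_neighbors > m - 1:
        log.warning("smote_oversample: k_neighbors %d > %d available; shrunk",
                    k_neighbors, m - 1)
        k_neighbors = m - 1
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(minority)
    _, idx = nn.kneighbors(minority)
    neighbors = idx[:, 1:]  # drop self

    base = rng.integers(0, m, size=n_synthetic)
    pick = rng.integers(0, k_neighbors, size=n_synthetic)
    lam = rng.random(n_synthetic)
    x = minority[base]
    x_nn = minority[neighbors[base, pick]]
    return x + lam[:, None] * (x_nn - x)


def balance_with_smote(X: np.ndarray, y: np.ndarray, k_neighbors: int,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Augment the minority class with SMOTE points until classes balance.

    The original points are preserved verbatim (synthetic rows appended).
    Already-balanced data are returned unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == n1:
        return X, y
    minority_label = 1 if n1 < n0 else 0
    deficit = abs(n0 - n1)
    synth = smote_oversample(X[y == minority_label], k_neighbors, deficit, rng)
    X_aug = np.vstack([X, synth])
    y_aug = np.concatenate([y, np.full(deficit, minority_label)])
    return X_aug, y_aug


def undersample_majority(X: np.ndarray, y: np.ndarray,
                         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random majority downsampling to the minority class size."""
    y = np.asarray(y, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == n1:
        return np.asarray(X, float), y
    minority_label = 1 if n1 < n0 else 0
    maj_idx = np.flatnonzero(y != minority_label)
    keep = rng.choice(maj_idx, size=min(n0, n1), replace=False)
    idx = np.sort(np.concatenate([np.flatnonzero(y == minority_label), keep]))
    return np.asarray(X, float)[idx], y[idx]


def _curve_counts(probs: np.ndarray, labels: np.ndarray):
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ResistomeError("both classes required for a curve")
    order = np.argsort(-probs, kind="mergesort")
    p_sorted = probs[order]
    y_sorted = labels[order]
    # group tied scores so the curve is threshold-wise well defined
    distinct = np.where(np.diff(p_sorted))[0]
    cut = np.concatenate([distinct, [len(p_sorted) - 1]])
    tp = np.cumsum(y_sorted)[cut].astype(float)
    fp = (cut + 1) - tp
    return tp, fp, n_pos, n_neg, p_sorted[cut]


def roc_points(probs: np.ndarray, labels: np.ndarray):
    """ROC curve points and trapezoidal AUC.

    The trapezoid over tie-grouped thresholds equals the Mann-Whitney
    U statistic normalized by ``n_pos * n_neg`` with half credit for ties.
    Returns (fpr, tpr, thresholds, auc).
    """
    tp, fp, n_pos, n_neg, thr = _curve_counts(probs, labels)
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, thr, auc


def pr_points(probs: np.ndarray, labels: np.ndarray):
    """Precision-recall curve points and trapezoidal AUC on the recall grid.

    Returns (recall, precision, thresholds, auc). The curve starts at
    recall 0 with the precision of the highest-score group.
    """
    tp, fp, n_pos, _, thr = _curve_counts(probs, labels)
    recall = tp / n_pos
    precision = tp / (tp + fp)
    recall = np.concatenate([[0.0], recall])
    precision = np.concatenate([[precision[0]], precision])
    auc = float(np.trapezoid(precision, recall))
    return recall, precision, thr, auc


def roc_auc(probs: np.ndarray, labels: np.ndarray) -> float:
    return roc_points(probs, labels)[3]


def pr_auc(probs: np.ndarray, labels: np.ndarray) -> float:
    return pr_points(probs, labels)[3]


def confusion_at(probs: np.ndarray, labels: np.ndarray,
                 threshold: float = 0.5) -> dict[str, int]:
    """Confusion counts predicting resistant (1) iff prob >= threshold."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = (probs >= threshold).astype(int)
    return {
        "tp": int(np.sum((pred == 1) & (labels == 1))),
        "fp": int(np.sum((pred == 1) & (labels == 0))),
        "tn": int(np.sum((pred == 0) & (labels == 0))),
        "fn": int(np.sum((pred == 0) & (labels == 1))),
    }


@dataclass
class ClassifierReport:
    """Cross-validated evaluation of the per-drug resistance model."""

    best_params: dict
    fold_roc_aucs: list[float]
    fold_pr_aucs: list[float]
    oof_probs: np.ndarray
    labels: np.ndarray
    confusion: dict[str, int]
    importances: np.ndarray
    genes: list[str] = field(default_factory=list)

    @property
    def roc_auc_mean(self) -> float:
        return float(np.mean(self.fold_roc_aucs))

    @property
    def roc_auc_sd(self) -> float:
        return float(np.std(self.fold_roc_aucs, ddof=1))

    @property
    def pr_auc_mean(self) -> float:
        return float(np.mean(self.fold_pr_aucs))

    @property
    def pr_auc_sd(self) -> float:
        return float(np.std(self.fold_pr_aucs, ddof=1))

    def to_jsonable(self) -> dict:
        return {
            "best_params": {k: (None if v is None else v) for k, v in self.best_params.items()},
            "roc_auc_mean": self.roc_auc_mean,
            "roc_auc_sd": self.roc_auc_sd,
            "pr_auc_mean": self.pr_auc_mean,
            "pr_auc_sd": self.pr_auc_sd,
            "fold_roc_aucs": list(map(float, self.fold_roc_aucs)),
            "fold_pr_aucs": list(map(float, self.fold_pr_aucs)),
            "confusion": self.confusion,
            "importances": {g: float(i) for g, i in zip(self.genes, self.importances)},
        }


def cv_grid_search(X: np.ndarray, y: np.ndarray, grid: list[dict] | None = None,
                   n_folds: int = 5, seed: int = 0, use_smote: bool = True,
                   undersample: bool = False, smote_k: int = 5,
                   genes: list[str] | None = None) -> ClassifierReport:
    """Grid-searched, stratified k-fold evaluation of a random forest.

    The winning grid point maximizes mean fold ROC AUC; its per-fold
    validation probabilities concatenate into an out-of-fold prediction
    vector covering each sample exactly once. Class balancing (SMOTE or
    optional undersampling) happens inside each training fold only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if grid is None:
        grid = [{"n_estimators": 200}]
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ResistomeError("both classes required")
    if counts.min() < n_folds:
        raise ResistomeError(
            f"smallest class has {counts.min()} samples < {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    fold_seeds = rng.integers(0, 2**31 - 1, size=(len(grid), n_folds))
    refit_seed = int(rng.integers(0, 2**31 - 1))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    results = []
    for gi, params in enumerate(grid):
        oof = np.full(len(y), np.nan)
        roc_f, pr_f = [], []
        for fi, (tr, va) in enumerate(splits):
            fseed = int(fold_seeds[gi, fi])
            frng = np.random.default_rng(fseed)
            X_tr, X_va = zscore_fit_apply(X[tr], X[va])
            y_tr = y[tr]
            if undersample:
                X_tr, y_tr = undersample_majority(X_tr, y_tr, frng)
            elif use_smote:
                X_tr, y_tr = balance_with_smote(X_tr, y_tr, smote_k, frng)
            clf = RandomForestClassifier(random_state=fseed, n_jobs=1, **params)
            clf.fit(X_tr, y_tr)
            probs = clf.predict_proba(X_va)[:, 1]
            oof[va] = probs
            roc_f.append(roc_auc(probs, y[va]))
            pr_f.append(pr_auc(probs, y[va]))
        results.append((float(np.mean(roc_f)), gi, params, oof, roc_f, pr_f))

    best = max(results, key=lambda r: (r[0], -r[1]))  # ties -> first grid point
    _, _, params, oof, roc_f, pr_f = best
    assert not np.isnan(oof).any()

    X_all, = zscore_fit_apply(X)
    y_all = y
    if undersample:
        X_all, y_all = undersample_majority(X_all, y_all, np.random.default_rng(refit_seed))
    elif use_smote:
        X_all, y_all = balance_with_smote(X_all, y_all, smote_k,
                                          np.random.default_rng(refit_seed))
    final = RandomForestClassifier(random_state=refit_seed, n_jobs=1, **params)
    final.fit(X_all, y_all)

    return ClassifierReport(
        best_params=dict(params),
        fold_roc_aucs=roc_f,
        fold_pr_aucs=pr_f,
        oof_probs=oof,
        labels=y,
        confusion=confusion_at(oof, y),
        importances=final.feature_importances_,
        genes=genes or [f"f{i}" for i in range(X.shape[1])],
    )


def cv_auc_fixed(X: np.ndarray, y: np.ndarray, n_folds: int = 5, seed: int = 0,
                 use_smote: bool = True, smote_k: int = 5,
                 **rf_params) -> float:
    """Mean fold ROC AUC for one fixed random-forest configuration.

    Convenience route for calibration experiments (e.g. label-permutation
    nulls) that do not need the full grid search.
    """
    rf_params.setdefault("n_estimators", 100)
    report = cv_grid_search(X, y, grid=[rf_params], n_folds=n_folds, seed=seed,
                            use_smote=use_smote, smote_k=smote_k)
    return report.roc_auc_mean
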