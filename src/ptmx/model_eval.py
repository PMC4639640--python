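"""RBF-SVM training, wrapper feature selection and stringency-level evaluation.

Cross-validation pools out-of-fold scores over the 10 folds and computes a
single ROC/AUC and one metric row per specificity stringency level, matching
a single-value performance table rather than per-fold averages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

#: libsvm-style default grids: cost 2^-5..2^15, gamma 2^-15..2^3, step 2^2
DEFAULT_COST_GRID = [2.0 ** e for e in range(-5, 16, 2)]
DEFAULT_GAMMA_GRID = [2.0 ** e for e in range(-15, 4, 2)]

STRINGENCY_LEVELS = {"high": 0.95, "medium": 0.90, "low": 0.85}


def stratified_folds(labels, n_folds: int = 10, seed: int = 0) -> np.ndarray:
    """Seeded stratified fold assignment (array of fold ids, one per sample).

    Each class must have at least n_folds members; per-fold class counts are
    within one of the proportional share.
    """
    y = np.asarray(labels).ravel()
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than {n_folds} folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(y.size, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((y.size, 1)), y)):
        assignment[test_idx] = fold
    return assignment


@dataclass
class TrainedClassifier:
    """A fitted RBF SVM producing scores in [0, 1].

    With probability=True the score is the Platt-calibrated class-1
    probability; otherwise it is the logistic of the decision function —
    monotone in the SVM margin, so ROC/AUC and threshold sweeps are
    unaffected, but cheaper to fit.
    """

    cost: float
    gamma: float | str
    weight_ratio: float
    weight_mode: str
    probability: bool
    _svc: SVC

    def score(self, X) -> np.ndarray:
        if self.probability:
            return self._svc.predict_proba(np.asarray(X, dtype=float))[:, 1]
        return expit(self._svc.decision_function(np.asarray(X, dtype=float)))


def train_svm(
    features,
    labels,
    cost: float = 1.0,
    gamma: float | str = "scale",
    weight_ratio: float | None = None,
    weight_mode: str = "positive",
    probability: bool = False,
    seed: int = 0,
) -> TrainedClassifier:
    """Fit an RBF SVM with imbalance weighting.

    weight_mode "positive" (default) weights the positive/minority class by
    the negative/positive count ratio so total class weights balance;
    "negative" applies the ratio to the negative class instead (the literal
    reading of the source description, available for comparison).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).ravel()
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if weight_ratio is None:
        weight_ratio = n_neg / n_pos
    if weight_mode == "positive":
        class_weight = {1: weight_ratio, 0: 1.0}
    elif weight_mode == "negative":
        class_weight = {1: 1.0, 0: weight_ratio}
    else:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    if np.all(X == X[0]):
        logger.warning("degenerate features: all rows identical; fit proceeds")
    kwargs = {}
    if probability:
        # libsvm's built-in Platt scaling; parameter deprecated upstream but
        # still the closest match to LIBSVM-style probability output
        kwargs["probability"] = True
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*probability.*", category=FutureWarning
        )
        svc = SVC(
            kernel="rbf",
            C=cost,
            gamma=gamma,
            class_weight=class_weight,
            random_state=seed,
            **kwargs,
        )
        svc.fit(X, y)
    return TrainedClassifier(
        cost=cost,
        gamma=gamma,
        weight_ratio=weight_ratio,
        weight_mode=weight_mode,
        probability=probability,
        _svc=svc,
    )


def cv_scores(
    features,
    labels,
    fold_assignment,
    cost: float = 1.0,
    gamma: float | str = "scale",
    weight_mode: str = "positive",
    seed: int = 0,
) -> np.ndarray:
    """Pooled out-of-fold scores: each instance scored exactly once by the
    model trained on the other folds."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).ravel()
    folds = np.asarray(fold_assignment)
    scores = np.empty(y.size, dtype=float)
    for fold in np.unique(folds):
        test = folds == fold
        clf = train_svm(
            X[~test], y[~test], cost=cost, gamma=gamma,
            weight_mode=weight_mode, seed=seed,
        )
        scores[test] = clf.score(X[test])
    return scores


def roc_auc(scores, labels) -> tuple[float, np.ndarray]:
    """AUC via the rank statistic U/(n1*n0) with mid-rank ties, plus the ROC
    polyline from a unique-threshold sweep (columns FPR, TPR)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).ravel()
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-s, kind="mergesort")
    sorted_scores = s[order]
    tps = np.cumsum(y[order] == 1)
    fps = np.cumsum(y[order] == 0)
    distinct = np.r_[np.nonzero(np.diff(sorted_scores))[0], s.size - 1]
    points = np.column_stack(
        [np.r_[0.0, fps[distinct] / n_neg], np.r_[0.0, tps[distinct] / n_pos]]
    )
    return float(auc), points


def grid_search(
    features,
    labels,
    cost_grid=None,
    gamma_grid=None,
    n_folds: int = 10,
    seed: int = 0,
    weight_mode: str = "positive",
) -> tuple[float, float]:
    """Pick (cost, gamma) maximizing pooled CV AUC; ties resolve to the
    smaller cost, then the smaller gamma."""
    cost_grid = sorted(cost_grid if cost_grid is not None else DEFAULT_COST_GRID)
    gamma_grid = sorted(gamma_grid if gamma_grid is not None else DEFAULT_GAMMA_GRID)
    if not cost_grid or not gamma_grid:
        raise ValueError("grids must be non-empty")
    folds = stratified_folds(labels, n_folds=n_folds, seed=seed)
    best = None
    for cost in cost_grid:
        for gamma in gamma_grid:
            scores = cv_scores(
                features, labels, folds, cost=cost, gamma=gamma,
                weight_mode=weight_mode, seed=seed,
            )
            auc, _ = roc_auc(scores, labels)
            if best is None or auc > best[0]:
                best = (auc, cost, gamma)
    logger.info("grid search: cost=%g gamma=%g (CV AUC %.4f)", best[1], best[2], best[0])
    return best[1], best[2]


@dataclass
class SelectionTrace:
    """CV AUC as ranked GO features are added one by one on top of the
    sequence baseline (entry 0 = sequence-only)."""

    auc_at_step: list[float]
    optimal_t: int
    optimal_auc: float
    cost: float
    gamma: float | str


def forward_select(
    seq_features,
    ranked_go_features,
    labels,
    n_folds: int = 10,
    seed: int = 0,
    cost: float | None = None,
    gamma: float | str | None = None,
    cost_grid=None,
    gamma_grid=None,
    retune_every: int = 0,
    weight_mode: str = "positive",
) -> SelectionTrace:
    """Wrapper forward selection over pre-ranked GO feature columns.

    Hyperparameters are grid-searched once on the sequence-only baseline and
    then held fixed (set retune_every=t to re-run the grid search every t
    steps; 0 disables).  Pass cost and gamma explicitly to skip the search.
    """
    seq = np.asarray(seq_features, dtype=float)
    go = np.asarray(ranked_go_features, dtype=float)
    y = np.asarray(labels).ravel()
    folds = stratified_folds(y, n_folds=n_folds, seed=seed)
    if cost is None or gamma is None:
        cost, gamma = grid_search(
            seq, y, cost_grid=cost_grid, gamma_grid=gamma_grid,
            n_folds=n_folds, seed=seed, weight_mode=weight_mode,
        )
    aucs: list[float] = []
    k = go.shape[1]
    for t in range(k + 1):
        if retune_every and t and t % retune_every == 0:
            cost, gamma = grid_search(
                np.hstack([seq, go[:, :t]]), y, cost_grid=cost_grid,
                gamma_grid=gamma_grid, n_folds=n_folds, seed=seed,
                weight_mode=weight_mode,
            )
        X = seq if t == 0 else np.hstack([seq, go[:, :t]])
        scores = cv_scores(X, y, folds, cost=cost, gamma=gamma,
                           weight_mode=weight_mode, seed=seed)
        auc, _ = roc_auc(scores, y)
        aucs.append(auc)
    optimal_t = int(np.argmax(aucs))
    return SelectionTrace(
        auc_at_step=aucs,
        optimal_t=optimal_t,
        optimal_auc=float(aucs[optimal_t]),
        cost=cost,
        gamma=gamma,
    )


def metrics_at_stringency(scores, labels, sp_level: float) -> dict:
    """Confusion metrics at the threshold maximizing Sn subject to Sp > sp_level.

    Thresholds sweep the unique scores descending (predict positive when
    score >= threshold); the all-negative operating point (Sp = 1, Sn = 0) is
    always available, so a threshold exists for any sp_level < 1.
    MCC is defined as 0 when any denominator factor vanishes.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).ravel()
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    best = None
    thresholds = np.r_[np.inf, np.unique(s)[::-1]]
    for thr in thresholds:
        pred = s >= thr
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        sp = (n_neg - fp) / n_neg
        if sp > sp_level:
            sn = tp / n_pos
            if best is None or sn > best[0]:
                best = (sn, thr, tp, fp)
    if best is None:
        raise ValueError(f"no threshold attains Sp > {sp_level}")
    sn, thr, tp, fp = best
    tn = n_neg - fp
    fn = n_pos - tp
    return confusion_metrics(tp=tp, fp=fp, tn=tn, fn=fn) | {"threshold": float(thr)}


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict:
    """Acc/Sn/Sp/Pre/MCC from raw confusion counts."""
    total = tp + fp + tn + fn
    acc = (tp + tn) / total
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    pre = tp / (tp + fp) if tp + fp else 0.0
    denom = (tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return {
        "TP": tp, "FP": fp, "TN": tn, "FN": fn,
        "Acc": acc, "Sn": sn, "Sp": sp, "Pre": pre, "MCC": float(mcc),
    }


@dataclass
class StringencyReport:
    """Pooled CV evaluation: AUC, ROC points and one metric row per level."""

    auc: float
    roc_points: np.ndarray
    levels: dict[str, dict]
    scores: np.ndarray = field(repr=False, default=None)


def evaluate_cv(
    features,
    labels,
    n_folds: int = 10,
    seed: int = 0,
    cost: float = 1.0,
    gamma: float | str = "scale",
    weight_mode: str = "positive",
    stringency_levels: dict[str, float] | None = None,
) -> StringencyReport:
    """Pooled 10-fold CV scores -> AUC plus high/medium/low stringency rows."""
    y = np.asarray(labels).ravel()
    folds = stratified_folds(y, n_folds=n_folds, seed=seed)
    scores = cv_scores(features, y, folds, cost=cost, gamma=gamma,
                       weight_mode=weight_mode, seed=seed)
    auc, points = roc_auc(scores, y)
    levels = {
        name: metrics_at_stringency(scores, y, sp)
        for name, sp in (stringency_levels or STRINGENCY_LEVELS).items()
    }
    return StringencyReport(auc=auc, roc_points=points, levels=levels, scores=scores)
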