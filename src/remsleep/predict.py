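"""RD1-based prediction of antidepressant response to ketamine.

Response is defined as a >= 50% reduction in HAM-D score one day after
administration (the threshold is inclusive: exactly 50% counts as
response).  The harness evaluates how well a single baseline feature —
first-REM-period density, RD1 — separates responders from non-responders:

* repeated stratified hold-out validation (default 1000 iterations of a
  70-30 train/test split, class proportions preserved in each split);
* a soft-margin SVM with an RBF kernel fit on each training split, with
  feature standardization fit on the training split only (no leakage);
* per-iteration accuracy, true- and false-positive rates;
* one pooled ROC curve over the test-set decision scores of every
  iteration, with the area under it (AUC) by the trapezoidal rule;
* the median accuracy with a 2.5/97.5-percentile 95% interval.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import DegenerateSample


def label_responders(
    hamd_baseline: float, hamd_day1: float, threshold: float = 0.50
) -> bool:
    """Responder iff the day-1 score dropped by at least ``threshold``
    (fractional) from baseline."""
    if hamd_baseline is None or hamd_day1 is None or np.isnan(hamd_baseline) or np.isnan(hamd_day1):
        raise ValueError("both HAM-D scores are required to label response")
    if hamd_baseline <= 0:
        raise ValueError("baseline HAM-D must be positive")
    return (hamd_baseline - hamd_day1) / hamd_baseline >= threshold


@dataclass
class PredictionConfig:
    n_iterations: int = 1000
    train_fraction: float = 0.70
    kernel: str = "rbf"
    regularization: float = 1.0       # SVC C
    kernel_width: str | float = "scale"  # SVC gamma; "scale" = 1/(d*var)
    seed: int = 0
    response_scale: str = "HAMD"      # or "MADRS" (same threshold rule)
    response_threshold: float = 0.50

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train fraction must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("need at least one iteration")
        if self.kernel != "rbf":
            raise ValueError("only the RBF kernel is supported")


@dataclass
class PredictionReport:
    accuracies: np.ndarray
    tpr: np.ndarray                 # per-iteration, proportions
    fpr: np.ndarray
    iteration_auc: np.ndarray
    roc_fpr: np.ndarray             # pooled ROC points
    roc_tpr: np.ndarray
    auc: float
    median_accuracy: float
    accuracy_ci: tuple[float, float]
    mean_tpr_pct: float             # 0-100 scale, reporting convention
    mean_fpr_pct: float
    n_subjects: int
    n_positive: int

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("accuracies", "tpr", "fpr", "iteration_auc", "roc_fpr", "roc_tpr"):
            d[k] = [float(v) for v in d[k]]
        d["accuracy_ci"] = [float(v) for v in d["accuracy_ci"]]
        return d


def roc_and_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Threshold-sweep ROC on decision scores and trapezoidal AUC.

    Ties in the scores move the curve diagonally, so the trapezoidal AUC
    equals the normalized Mann-Whitney statistic
    ``U / (n_pos * n_neg)`` with midrank tie handling.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateSample("ROC needs both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp = np.cumsum(y_sorted == 1)
    fp = np.cumsum(y_sorted == 0)
    # keep only the last point of each distinct-score block
    distinct = np.nonzero(np.diff(s_sorted))[0]
    idx = np.concatenate([distinct, [s.size - 1]])
    tpr = np.concatenate([[0.0], tp[idx] / n_pos])
    fpr = np.concatenate([[0.0], fp[idx] / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def accuracy_summary(accuracies: Sequence[float]) -> tuple[float, float, float]:
    """Median and 2.5/97.5-percentile bounds of an accuracy distribution."""
    a = np.asarray(accuracies, dtype=float)
    if a.size == 0:
        raise ValueError("empty accuracy list")
    return (
        float(np.median(a)),
        float(np.percentile(a, 2.5)),
        float(np.percentile(a, 97.5)),
    )


def holdout_validate(
    features: Sequence[float],
    labels: Sequence[int],
    cfg: Optional[PredictionConfig] = None,
) -> PredictionReport:
    """Repeated stratified hold-out validation of the RBF-SVM classifier.

    ``features`` is the per-subject predictor (baseline RD1); ``labels``
    the responder indicator.  Each iteration draws a stratified
    train/test split, standardizes using training statistics only, fits
    the SVM and scores the test split; decision scores are pooled across
    iterations for a single ROC/AUC, and the per-iteration AUC
    distribution is kept alongside.
    """
    cfg = cfg or PredictionConfig()
    X = np.asarray(features, dtype=float).reshape(-1, 1)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels differ in length")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if np.ptp(X) == 0:
        raise DegenerateSample("constant feature carries no information")
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos < 2 or n_neg < 2:
        raise DegenerateSample("need at least two members of each class")

    splitter = StratifiedShuffleSplit(
        n_splits=cfg.n_iterations,
        train_size=cfg.train_fraction,
        random_state=int(cfg.seed) % (2**31),
    )
    acc = np.empty(cfg.n_iterations)
    tpr = np.empty(cfg.n_iterations)
    fpr = np.empty(cfg.n_iterations)
    it_auc = np.empty(cfg.n_iterations)
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []

    for k, (tr, te) in enumerate(splitter.split(X, y)):
        scaler = StandardScaler().fit(X[tr])
        clf = SVC(
            C=cfg.regularization,
            kernel=cfg.kernel,
            gamma=cfg.kernel_width,
        ).fit(scaler.transform(X[tr]), y[tr])
        Xte = scaler.transform(X[te])
        pred = clf.predict(Xte)
        score = clf.decision_function(Xte)
        yte = y[te]
        acc[k] = float((pred == yte).mean())
        pos, neg = yte == 1, yte == 0
        tpr[k] = float(pred[pos].mean()) if pos.any() else np.nan
        fpr[k] = float(pred[neg].mean()) if neg.any() else np.nan
        _, _, it_auc[k] = roc_and_auc(score, yte)
        # decision scores are standardized per iteration before pooling:
        # raw SVM scores carry fit-specific scale and offset, and pooling
        # incommensurable scores attenuates the pooled ROC
        sd = score.std()
        pooled_scores.append((score - score.mean()) / sd if sd > 0 else score)
        pooled_labels.append(yte)

    roc_fpr, roc_tpr, auc = roc_and_auc(
        np.concatenate(pooled_scores), np.concatenate(pooled_labels)
    )
    med, lo, hi = accuracy_summary(acc)
    return PredictionReport(
        accuracies=acc,
        tpr=tpr,
        fpr=fpr,
        iteration_auc=it_auc,
        roc_fpr=roc_fpr,
        roc_tpr=roc_tpr,
        auc=auc,
        median_accuracy=med,
        accuracy_ci=(lo, hi),
        mean_tpr_pct=float(np.nanmean(tpr) * 100.0),
        mean_fpr_pct=float(np.nanmean(fpr) * 100.0),
        n_subjects=int(y.size),
        n_positive=n_pos,
    )
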