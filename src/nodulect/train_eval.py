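"""Training protocol helpers and evaluation metrics.

Covers the five-fold split, the step learning-rate schedule, confusion
counts, ROC/AUC (threshold sweep + trapezoid) and micro/macro AUC for
the binary task via one-vs-rest pooling, plus the ablation grid runner
(manual vs Otsu threshold x radiomics on/off).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "TrainConfig", "EvalReport", "five_fold_split", "lr_at_epoch",
    "confusion_counts", "accuracy", "roc_curve", "micro_macro_auc", "stratified_five_fold",
    "evaluate_scores", "train", "run_ablation",
]


@dataclass
class TrainConfig:
    """The printed training recipe."""

    lr0: float = 1e-3
    lr_decay: float = 0.9
    lr_step: int = 10
    epochs: int = 100
    batch_size: int = 16
    beta1: float = 0.9
    beta2: float = 0.999
    dropout: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr0 <= 0 or self.epochs < 1:
            raise ValueError("lr0 must be positive and epochs >= 1")


@dataclass
class EvalReport:
    accuracy: float
    auc: float
    micro_auc: float
    macro_auc: float
    roc_points: List[Tuple[float, float]]
    confusion: Dict[str, int] = field(default_factory=dict)


def five_fold_split(sample_ids: Sequence, seed: int = 0) -> List[List]:
    """Seeded shuffle + round-robin assignment into five disjoint subsets.

    Subset sizes differ by at most one; the union is the input exactly.
    """
    ids = list(sample_ids)
    if len(ids) < 5:
        raise ValueError("need at least 5 samples for a five-fold split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    subsets: List[List] = [[] for _ in range(5)]
    for pos, idx in enumerate(order):
        subsets[pos % 5].append(ids[idx])
    return subsets


def stratified_five_fold(labels: Sequence[int], seed: int = 0) -> List[List[int]]:
    """Five folds with the class mix preserved: the base split applied
    per class, merged subset-by-subset.  Returns index lists."""
    labels = np.asarray(labels)
    folds: List[List[int]] = [[] for _ in range(5)]
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c).tolist()
        for k, subset in enumerate(five_fold_split(idx, seed=seed + int(c))):
            folds[k].extend(subset)
    return [sorted(f) for f in folds]


def lr_at_epoch(lr0: float, epoch: int, decay: float = 0.9, step: int = 10) -> float:
    """Step schedule: lr0 * decay**floor(epoch / step)."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    return lr0 * decay ** (epoch // step)


# ---------------------------------------------------------------------------
# metrics


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> Dict[str, int]:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return {
        "TP": int(np.sum((y_true == 1) & (y_pred == 1))),
        "TN": int(np.sum((y_true == 0) & (y_pred == 0))),
        "FP": int(np.sum((y_true == 0) & (y_pred == 1))),
        "FN": int(np.sum((y_true == 1) & (y_pred == 0))),
    }


def accuracy(confusion: Dict[str, int]) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    total = sum(confusion[k] for k in ("TP", "TN", "FP", "FN"))
    if total == 0:
        raise ValueError("empty confusion table")
    return (confusion["TP"] + confusion["TN"]) / total


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> Tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC from a sweep over unique scores.

    Points run from (0, 0) to (1, 1) with TPR = TP/(TP+FN) and
    FPR = FP/(FP+TN) evaluated at every distinct score threshold
    (prediction positive iff score >= threshold).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")

    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    y_sorted = labels[order]
    tp = np.cumsum(y_sorted == 1)
    fp = np.cumsum(y_sorted == 0)
    # keep the last index of each distinct score (all samples >= threshold)
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def micro_macro_auc(scores: np.ndarray, labels: np.ndarray) -> Tuple[float, float]:
    """One-vs-rest micro / macro AUC for the binary sigmoid scorer.

    Per-class scores are (1 - s) for the benign class and s for the
    malignant class.  Macro averages the two per-class AUCs (equal by
    symmetry of the complement); micro pools every (sample, class)
    indicator pair and computes one AUC over the 2n pooled pairs.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    _, auc_pos = roc_curve(scores, labels)
    _, auc_neg = roc_curve(1.0 - scores, 1 - labels)
    macro = 0.5 * (auc_pos + auc_neg)
    pooled_scores = np.concatenate([1.0 - scores, scores])
    pooled_labels = np.concatenate([(labels == 0).astype(int), (labels == 1).astype(int)])
    _, micro = roc_curve(pooled_scores, pooled_labels)
    return micro, macro


def evaluate_scores(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> EvalReport:
    """Full report: confusion at the decision threshold plus ROC/AUCs."""
    conf = confusion_counts(labels, np.asarray(scores) >= threshold)
    points, auc = roc_curve(scores, labels)
    micro, macro = micro_macro_auc(scores, labels)
    return EvalReport(
        accuracy=accuracy(conf), auc=auc, micro_auc=micro, macro_auc=macro,
        roc_points=[(float(f), float(t)) for f, t in points], confusion=conf,
    )


# ---------------------------------------------------------------------------
# training wrapper and ablation grid


def train(cubes: np.ndarray, feats: np.ndarray, labels: np.ndarray,
          cfg: TrainConfig | None = None, **estimator_kwargs):
    """Train a fusion classifier with the standard recipe; returns the estimator.

    Thin wrapper over :class:`nodulect.model.FusionNoduleClassifier`
    for callers that work with arrays rather than estimators.
    """
    from .model import FusionNoduleClassifier

    cfg = cfg or TrainConfig()
    est = FusionNoduleClassifier(
        input_side=cubes.shape[1], epochs=cfg.epochs, batch_size=cfg.batch_size,
        lr=cfg.lr0, lr_decay=cfg.lr_decay, lr_step=cfg.lr_step,
        beta1=cfg.beta1, beta2=cfg.beta2, dropout=cfg.dropout,
        radiomics_dim=feats.shape[1], random_state=cfg.seed, **estimator_kwargs,
    )
    return est.fit((cubes, feats), labels)


#: ablation variants: (name, threshold_mode, use_radiomics)
DEFAULT_ABLATION_VARIANTS = [
    ("3D ResNet50 (otsu)", "otsu", False),
    ("3D ResNet50 + Radiomics (manual)", "manual", True),
    ("3D ResNet50 + Radiomics (otsu)", "otsu", True),
]


def run_ablation(prepare, train_and_score, variants=None) -> pd.DataFrame:
    """Evaluate preprocessing/radiomics variants on a shared test split.

    ``prepare(threshold_mode)`` must return
    ``(train_inputs, train_labels, test_inputs, test_labels)`` and
    ``train_and_score(train_inputs, train_labels, test_inputs,
    use_radiomics)`` the test scores.  Emits a table mirroring the
    M (manual) / O (Otsu) / R (radiomics) grid.
    """
    rows = []
    for name, mode, use_radiomics in (variants or DEFAULT_ABLATION_VARIANTS):
        tr_x, tr_y, te_x, te_y = prepare(mode)
        scores = train_and_score(tr_x, tr_y, te_x, use_radiomics)
        report = evaluate_scores(np.asarray(scores), np.asarray(te_y))
        rows.append({
            "method": name,
            "M": "Y" if mode == "manual" else "N",
            "O": "Y" if mode == "otsu" else "N",
            "R": "Y" if use_radiomics else "N",
            "micro_auc": report.micro_auc,
            "macro_auc": report.macro_auc,
            "accuracy": report.accuracy,
        })
    return pd.DataFrame(rows, columns=["method", "M", "O", "R", "micro_auc", "macro_auc", "accuracy"])
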