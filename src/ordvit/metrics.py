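"""Evaluation suite: classification metrics, one-vs-rest ROC/AUC, risk-score
behaviour, adjacency analysis of errors, and the ablation harness.

Averaging of precision/recall/F1 is support-weighted, which carries the
identity weighted-recall == accuracy.  Micro-averaged AUC pools all 4n
one-vs-rest (score, indicator) decisions into a single binary ROC problem;
ties use the midrank (trapezoidal) convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support, roc_auc_score

__all__ = [
    "MetricsReport",
    "classification_metrics",
    "ovr_roc_auc",
    "risk_monotonicity",
    "adjacency_confusion",
    "evaluate_predictions",
    "ablation_suite",
]

N_CLASSES = 4


@dataclass
class MetricsReport:
    """Full evaluation bundle for one model on one split."""

    accuracy: float
    precision_w: float
    recall_w: float
    f1_w: float
    confusion: np.ndarray
    per_class_auc: list[float | None] = field(default_factory=list)
    micro_auc: float | None = None
    adjacent_error_fraction: float = 0.0
    no_errors: bool = False
    risk_means: list[float | None] = field(default_factory=list)
    risk_monotone: bool = False
    concordance_rate: float | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confusion"] = self.confusion.tolist()
        return d


def classification_metrics(
    y_pred: Sequence[int], y_true: Sequence[int], n_classes: int = N_CLASSES
) -> dict:
    """Accuracy, support-weighted precision/recall/F1, and the confusion matrix.

    Zero-division cases (a class never predicted) contribute 0 and set the
    ``zero_division_flag``.
    """
    y_pred, y_true = np.asarray(y_pred), np.asarray(y_true)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_pred) != len(y_true):
        raise ValueError("prediction/truth length mismatch")
    labels = np.arange(n_classes)
    conf = confusion_matrix(y_true, y_pred, labels=labels)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="weighted", zero_division=0
    )
    per_class_prec = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average=None, zero_division=np.nan
    )[0]
    return {
        "accuracy": float((y_pred == y_true).mean()),
        "precision_w": float(prec),
        "recall_w": float(rec),
        "f1_w": float(f1),
        "confusion": conf,
        "zero_division_flag": bool(np.isnan(per_class_prec).any()),
    }


def ovr_roc_auc(
    class_probs: np.ndarray, y_true: Sequence[int], n_classes: int = N_CLASSES
) -> tuple[list[float | None], float]:
    """Per-class one-vs-rest AUCs and the micro-averaged AUC.

    A class absent from the truth gets AUC ``None``; the micro AUC pools the
    remaining decisions and is still computed.
    """
    class_probs = np.asarray(class_probs)
    y_true = np.asarray(y_true)
    if class_probs.shape != (len(y_true), n_classes):
        raise ValueError("class_probs must be (n, n_classes)")
    per_class: list[float | None] = []
    for c in range(n_classes):
        pos = y_true == c
        if pos.all() or not pos.any():
            per_class.append(None)
        else:
            per_class.append(float(roc_auc_score(pos, class_probs[:, c])))
    onehot = np.eye(n_classes)[y_true]
    micro = float(roc_auc_score(onehot.ravel(), class_probs.ravel()))
    return per_class, micro


def micro_auc_bruteforce(class_probs: np.ndarray, y_true: Sequence[int]) -> float:
    """Independent pair-counting micro AUC: P(score_pos > score_neg) + 0.5 P(tie).

    O(n^2) over the pooled one-vs-rest decisions; intended as a test oracle
    for small n.
    """
    class_probs = np.asarray(class_probs)
    y_true = np.asarray(y_true)
    onehot = np.eye(class_probs.shape[1])[y_true].ravel()
    scores = class_probs.ravel()
    pos = scores[onehot == 1]
    neg = scores[onehot == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return float(wins / (len(pos) * len(neg)))


def risk_monotonicity(
    risk_scores: Sequence[float], labels: Sequence[int], n_classes: int = N_CLASSES
) -> tuple[list[float | None], bool]:
    """Class-mean risk scores and whether they increase strictly with class."""
    risk_scores, labels = np.asarray(risk_scores, dtype=float), np.asarray(labels)
    means: list[float | None] = []
    for c in range(n_classes):
        sel = labels == c
        means.append(float(risk_scores[sel].mean()) if sel.any() else None)
    if any(m is None for m in means):
        return means, False
    monotone = all(a < b for a, b in zip(means, means[1:]))
    return means, monotone


def adjacency_confusion(y_pred: Sequence[int], y_true: Sequence[int]) -> tuple[float, bool]:
    """Among misclassified samples, the fraction off by exactly one ordinal step.

    Returns (fraction, no_errors_flag); fraction is 0 when there are no errors.
    """
    y_pred, y_true = np.asarray(y_pred), np.asarray(y_true)
    wrong = y_pred != y_true
    if not wrong.any():
        return 0.0, True
    adjacent = np.abs(y_pred[wrong] - y_true[wrong]) == 1
    return float(adjacent.mean()), False


def evaluate_predictions(
    class_probs: np.ndarray,
    risk_scores: Sequence[float],
    y_true: Sequence[int],
    concordance_rate: float | None = None,
) -> MetricsReport:
    """Assemble the full MetricsReport from model outputs on one split."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(class_probs).argmax(axis=1)
    cm = classification_metrics(y_pred, y_true)
    per_class_auc, micro = ovr_roc_auc(class_probs, y_true)
    adj, no_err = adjacency_confusion(y_pred, y_true)
    means, mono = risk_monotonicity(risk_scores, y_true)
    return MetricsReport(
        accuracy=cm["accuracy"],
        precision_w=cm["precision_w"],
        recall_w=cm["recall_w"],
        f1_w=cm["f1_w"],
        confusion=cm["confusion"],
        per_class_auc=per_class_auc,
        micro_auc=micro,
        adjacent_error_fraction=adj,
        no_errors=no_err,
        risk_means=means,
        risk_monotone=mono,
        concordance_rate=concordance_rate,
    )


def ablation_suite(
    model_config,
    train_config,
    train_records,
    val_records,
    test_records,
    variants: Sequence[str] = ("full", "no_progression", "no_self_attention"),
    seeds: Sequence[int] = (0, 1, 2),
) -> dict:
    """Train and evaluate each variant under identical data, seeds and budgets.

    Returns per-variant seed-mean metrics plus full-minus-variant deltas
    (accuracy, micro AUC, per-class recall).  Matched conditions: every
    variant sees the same records, the same seeds, and the same training
    configuration.
    """
    from .train import train_model  # local import to avoid a cycle
    from .model import predict_batch

    test_images = np.stack([r.pixels for r in test_records])
    test_labels = np.array([r.label for r in test_records])

    results: dict[str, dict] = {}
    for variant in variants:
        per_seed = []
        for s in seeds:
            model, _ = train_model(
                model_config, train_config, train_records, val_records, seed=s, variant=variant
            )
            probs, risks = predict_batch(test_images, model)
            rep = evaluate_predictions(probs, risks, test_labels)
            recalls = rep.confusion.diagonal() / np.maximum(rep.confusion.sum(axis=1), 1)
            per_seed.append(
                {
                    "accuracy": rep.accuracy,
                    "micro_auc": rep.micro_auc,
                    "f1_w": rep.f1_w,
                    "per_class_recall": recalls.tolist(),
                }
            )
        results[variant] = {
            "per_seed": per_seed,
            "mean": {
                "accuracy": float(np.mean([m["accuracy"] for m in per_seed])),
                "micro_auc": float(np.mean([m["micro_auc"] for m in per_seed])),
                "f1_w": float(np.mean([m["f1_w"] for m in per_seed])),
                "per_class_recall": np.mean(
                    [m["per_class_recall"] for m in per_seed], axis=0
                ).tolist(),
            },
        }
    deltas = {}
    if "full" in results:
        full = results["full"]["mean"]
        for variant in variants:
            if variant == "full":
                continue
            vm = results[variant]["mean"]
            deltas[variant] = {
                "accuracy": full["accuracy"] - vm["accuracy"],
                "micro_auc": full["micro_auc"] - vm["micro_auc"],
                "per_class_recall": (
                    np.array(full["per_class_recall"]) - np.array(vm["per_class_recall"])
                ).tolist(),
            }
    return {"variants": results, "deltas_full_minus_variant": deltas}
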