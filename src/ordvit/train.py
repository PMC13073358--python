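"""Joint training of the classification and risk-regression heads.

The objective per example with true class ``y`` is

    L = w_y * CE(softmax(logits), y) + lambda_reg * (risk - y/3)^2

where ``w_y`` is an inverse-frequency class weight normalized to mean one
(applied to the cross-entropy term only) and the regression targets are the
equally spaced ordinal anchors 0, 1/3, 2/3, 1.  Optimization uses AdamW
(decoupled weight decay), shuffled mini-batches, on-the-fly augmentation on
the training split only, and early stopping on validation loss with the
best-validation checkpoint retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .autograd import Tensor
from .model import ModelConfig, ModelWeights, build_model, forward_batch, predict_batch
from .pipeline import AugConfig, augment
from .synth import ImageRecord

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "AdamW",
    "class_weights",
    "combined_loss",
    "batch_loss",
    "train_model",
    "multi_seed_run",
]

RISK_TARGETS = np.array([0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0])


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 1e-2
    batch_size: int = 32
    max_epochs: int = 50
    patience: int = 5
    lambda_reg: float = 0.5
    class_weighting: bool = True
    augment: AugConfig = field(default_factory=AugConfig)

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1  # 0-based index into the lists
    stopped_early: bool = False

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


class AdamW:
    """AdamW with decoupled weight decay over a list of parameter tensors."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-2,
    ):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p.data -= self.lr * (m_hat / (np.sqrt(v_hat) + self.eps) + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def class_weights(labels: Sequence[int], n_classes: int = 4) -> np.ndarray:
    """Inverse-frequency weights w_c = N / (n_classes * n_c), mean one."""
    labels = np.asarray(labels)
    counts = np.bincount(labels, minlength=n_classes)
    for c in range(n_classes):
        if counts[c] == 0:
            raise ValueError(f"class {c} has no labeled examples")
    return len(labels) / (n_classes * counts.astype(float))


def combined_loss(
    class_probs: np.ndarray,
    risk_score: float,
    label: int,
    lambda_reg: float = 0.5,
    weight: float = 1.0,
) -> float:
    """Probability-space loss for one prediction (reporting/diagnostic API).

    The true-class probability is clamped at 1e-12 before the log.  Training
    itself computes cross-entropy from logits via log-sum-exp; see
    :func:`batch_loss`.
    """
    if label not in range(len(class_probs)):
        raise ValueError(f"label {label} out of range")
    p = max(float(class_probs[label]), 1e-12)
    ce = -np.log(p)
    mse = (float(risk_score) - RISK_TARGETS[label]) ** 2
    return weight * ce + lambda_reg * mse


def batch_loss(
    logits: Tensor,
    risk: Tensor,
    labels: np.ndarray,
    lambda_reg: float,
    weights: np.ndarray,
) -> Tensor:
    """Differentiable mean loss over a batch (CE from logits, numerically stable)."""
    n = len(labels)
    log_probs = logits.log_softmax()
    picked = log_probs[np.arange(n), labels]
    ce = (picked * (-weights[labels])).mean()
    resid = risk - RISK_TARGETS[labels]
    return ce + lambda_reg * (resid * resid).mean()


def _eval_split(
    records: Sequence[ImageRecord],
    model: ModelWeights,
    cfg: TrainConfig,
    weights_vec: np.ndarray,
    batch_size: int = 64,
) -> tuple[float, float]:
    """(mean loss, accuracy) on a split, eval mode, no augmentation."""
    losses, correct = [], 0
    for start in range(0, len(records), batch_size):
        chunk = records[start : start + batch_size]
        images = np.stack([r.pixels for r in chunk])
        labels = np.array([r.label for r in chunk])
        logits, risk = forward_batch(images, model, train_mode=False)
        loss = batch_loss(logits, risk, labels, cfg.lambda_reg, weights_vec)
        losses.append(float(loss.data) * len(chunk))
        correct += int((logits.data.argmax(axis=1) == labels).sum())
    return sum(losses) / len(records), correct / len(records)


def train_model(
    model_config: ModelConfig,
    train_config: TrainConfig,
    train_records: Sequence[ImageRecord],
    val_records: Sequence[ImageRecord],
    seed: int = 0,
    variant: str = "full",
    verbose: bool = False,
) -> tuple[ModelWeights, TrainHistory]:
    """Train one model; returns the best-validation-loss weights and history.

    All randomness (init, shuffling, augmentation, dropout) derives from
    ``seed``, so two calls with identical inputs produce identical histories.
    Aborts with FloatingPointError if the loss diverges.
    """
    if not train_records or not val_records:
        raise ValueError("train and val record lists must be non-empty")
    model = build_model(model_config, variant, seed=seed)
    opt = AdamW(model.parameters(), lr=train_config.lr, weight_decay=train_config.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7919]))

    labels_all = [r.label for r in train_records]
    w_vec = class_weights(labels_all) if train_config.class_weighting else np.ones(4)

    history = TrainHistory()
    best_val = np.inf
    best_arrays: dict[str, np.ndarray] | None = None
    epochs_since_best = 0

    n = len(train_records)
    for epoch in range(train_config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, train_config.batch_size):
            idx = order[start : start + train_config.batch_size]
            images = np.stack(
                [augment(train_records[i].pixels, train_config.augment, rng) for i in idx]
            )
            labels = np.array([train_records[i].label for i in idx])
            logits, risk = forward_batch(images, model, train_mode=True, rng=rng)
            loss = batch_loss(logits, risk, labels, train_config.lambda_reg, w_vec)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}, batch {start // train_config.batch_size}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        val_loss, val_acc = _eval_split(val_records, model, train_config, w_vec)
        history.train_loss.append(epoch_loss / n)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        if verbose:
            print(
                f"epoch {epoch + 1:3d}  train {epoch_loss / n:.4f}  "
                f"val {val_loss:.4f}  val_acc {val_acc:.3f}"
            )
        if val_loss < best_val:
            best_val = val_loss
            history.best_epoch = epoch
            best_arrays = model.copy_arrays()
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= train_config.patience:
                history.stopped_early = True
                break

    assert best_arrays is not None
    model.load_arrays(best_arrays)
    return model, history


def lambda_grid(
    model_config: ModelConfig,
    train_config: TrainConfig,
    train_records: Sequence[ImageRecord],
    val_records: Sequence[ImageRecord],
    lambdas: Sequence[float] = (0.1, 0.25, 0.5, 1.0),
    seed: int = 0,
    variant: str = "full",
) -> dict:
    """Grid over the regression-loss weight, scored by validation accuracy.

    Returns per-lambda validation accuracy and the best setting (ties go to
    the smaller lambda).  Intended for tuning lambda_reg on the validation
    split, never on test data.
    """
    import dataclasses

    results = {}
    for lam in lambdas:
        cfg = dataclasses.replace(train_config, lambda_reg=lam)
        _, history = train_model(
            model_config, cfg, train_records, val_records, seed=seed, variant=variant
        )
        results[lam] = history.val_accuracy[history.best_epoch]
    best = max(sorted(results), key=lambda k: results[k])
    return {"val_accuracy": results, "best_lambda": best}


def multi_seed_run(
    model_config: ModelConfig,
    train_config: TrainConfig,
    train_records: Sequence[ImageRecord],
    val_records: Sequence[ImageRecord],
    test_records: Sequence[ImageRecord],
    seeds: Sequence[int] = (0, 1, 2),
    variant: str = "full",
    metric_fn=None,
) -> dict:
    """Run independent seeded trainings and report per-seed and mean metrics.

    ``metric_fn(probs, risks, labels) -> dict of scalars`` defaults to test
    accuracy.  Failed runs are recorded and flagged; the mean covers the runs
    that completed.
    """
    if not seeds:
        raise ValueError("need at least one seed")
    if metric_fn is None:

        def metric_fn(probs, risks, labels):
            return {"accuracy": float((probs.argmax(axis=1) == labels).mean())}

    per_seed, failures = {}, []
    test_images = np.stack([r.pixels for r in test_records])
    test_labels = np.array([r.label for r in test_records])
    for s in seeds:
        try:
            model, _ = train_model(
                model_config, train_config, train_records, val_records, seed=s, variant=variant
            )
            probs, risks = predict_batch(test_images, model)
            per_seed[s] = metric_fn(probs, risks, test_labels)
        except FloatingPointError as err:  # pragma: no cover - defensive
            failures.append({"seed": s, "error": str(err)})
    keys = next(iter(per_seed.values())).keys() if per_seed else []
    mean = {k: float(np.mean([m[k] for m in per_seed.values()])) for k in keys}
    return {"per_seed": per_seed, "mean": mean, "failures": failures, "partial": bool(failures)}
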