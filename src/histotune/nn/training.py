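"""Training and prediction routines for the image classifier."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import Adam, smoothed_cross_entropy
from .models import ImageClassifier

__all__ = ["TrainConfig", "train_classifier", "predict", "prepare_images"]


@dataclass
class TrainConfig:
    epochs: int = 5
    batch_size: int = 32
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    seed: int = 0


def prepare_images(images: np.ndarray) -> np.ndarray:
    """uint8 HWC images -> float32 CHW in [-0.5, 0.5]."""
    x = np.asarray(images, dtype=np.float32) / 255.0 - 0.5
    if x.ndim == 4 and x.shape[-1] in (1, 3):
        x = x.transpose(0, 3, 1, 2)
    return np.ascontiguousarray(x)


def train_classifier(
    model: ImageClassifier,
    train_xy: tuple[np.ndarray, np.ndarray],
    val_xy: tuple[np.ndarray, np.ndarray] | None,
    config: TrainConfig,
    track_metrics: bool = True,
) -> dict[str, list[float]]:
    """Minimize label-smoothed cross-entropy with Adam for the configured epochs.

    Returns a history dict with per-epoch ``train_loss``, ``train_error``
    and, when a validation set is given, ``val_loss`` / ``val_error``
    (errors in percent). ``track_metrics=False`` skips the per-epoch error
    scans (used by tuning trials, where only the final validation error
    matters). Raises on a non-finite loss with a diagnostic.
    """
    x_train, y_train = train_xy
    if len(x_train) == 0:
        raise ValueError("training set is empty")
    y_train = np.asarray(y_train)
    if y_train.min() < 0 or y_train.max() >= model.crnn_cfg.n_classes:
        raise ValueError("labels must lie in [0, n_classes)")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.learning_rate,
               weight_decay=config.weight_decay)
    history: dict[str, list[float]] = {"train_loss": [], "train_error": []}
    if val_xy is not None:
        history["val_loss"] = []
        history["val_error"] = []
    n = len(x_train)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            loss = model.train_step(x_train[idx], y_train[idx], opt)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss!r} at epoch {epoch}, batch offset {start}; "
                    "reduce the learning rate or check the input scaling"
                )
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if track_metrics:
            history["train_error"].append(_error_rate(model, x_train, y_train))
            if val_xy is not None:
                vloss, verr = _eval_loss(model, *val_xy)
                history["val_loss"].append(vloss)
                history["val_error"].append(verr)
    return history


def _error_rate(model: ImageClassifier, x, y) -> float:
    pred = model.predict(x)
    return float(100.0 * np.mean(pred != np.asarray(y)))


def _eval_loss(model: ImageClassifier, x, y) -> tuple[float, float]:
    logits = model.logits(x)
    loss, _ = smoothed_cross_entropy(logits, np.asarray(y), model.crnn_cfg.label_smoothing)
    err = float(100.0 * np.mean(logits.argmax(axis=1) != np.asarray(y)))
    return loss, err


def predict(model: ImageClassifier, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Per-class probability rows for raw or prepared images."""
    x = np.asarray(images)
    if x.dtype == np.uint8 or (x.ndim >= 3 and x.shape[-1] in (1, 3) and x.ndim == 4):
        x = prepare_images(x)
    return model.predict_proba(x, batch_size=batch_size)
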