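"""Experiment orchestration around pluggable classifier backends.

The harness wires the other modules into a train/evaluate loop: prepare a
directory-per-class dataset, optionally enhance it with quasi-2D EMD,
split it stratified, train a backend with Adam (initial lr 1e-3, weight
decay 1e-3), a reduce-on-plateau schedule (factor 0.1, patience 10 on
validation loss), batch size 32, and best-validation-loss checkpointing,
then score the checkpointed model on the held-out test partition.

Backends are deliberately small: full-size backbone networks live outside
this package and plug in through the same :class:`ClassifierBackend`
contract. Two numpy backends ship here — a softmax regression on
flattened pixels and a tiny fixed-filter CNN whose last convolutional
stage exposes feature maps and class-score gradients, which is what
Grad-CAM consumes:

    weight_k = spatial mean of d(score_c)/d(A_k)
    heatmap  = ReLU(sum_k weight_k * A_k), upsampled, min-max normalized.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np
from skimage.transform import resize as _sk_resize

from .dataset import DatasetSplit, load_labeled_set, split_dataset
from .enhance import EMDEnhancer, load_image
from .metrics import MetricsReport, PredictionSet, aggregate_report

__all__ = [
    "TrainConfig",
    "ClassifierBackend",
    "SoftmaxBackend",
    "TinyCNNBackend",
    "UnsupportedBackendError",
    "ExperimentResult",
    "run_experiment",
    "train_backend",
    "gradcam",
]


class UnsupportedBackendError(TypeError):
    """Backend lacks the convolutional access an operation requires."""


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol contract (defaults mirror the study settings)."""

    learning_rate: float = 1e-3
    weight_decay: float = 1e-3
    lr_factor: float = 0.1
    lr_patience: int = 10
    batch_size: int = 32
    epochs: int = 50


@runtime_checkable
class ClassifierBackend(Protocol):
    """Minimal contract the harness trains and evaluates against.

    Backends with a convolutional stage additionally implement
    ``last_conv_feature_maps`` and ``feature_map_gradients`` for Grad-CAM.
    """

    def initialize(self, input_shape: tuple, n_classes: int, seed: int) -> None: ...

    def train_step(self, X: np.ndarray, y: np.ndarray, lr: float, weight_decay: float) -> float: ...

    def loss(self, X: np.ndarray, y: np.ndarray) -> float: ...

    def predict_proba(self, X: np.ndarray) -> np.ndarray: ...

    def state_dict(self) -> dict: ...

    def load_state_dict(self, state: dict) -> None: ...


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _AdamState:
    """Per-parameter Adam moments (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, shapes: dict[str, tuple]):
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def update(self, params: dict, grads: dict, lr: float) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + eps)


class SoftmaxBackend:
    """Multinomial logistic regression on flattened pixels, Adam-trained.

    Has no convolutional stage, so Grad-CAM raises
    :class:`UnsupportedBackendError` on it.
    """

    def initialize(self, input_shape, n_classes: int, seed: int) -> None:
        d = int(np.prod(input_shape))
        rng = np.random.default_rng(seed)
        self.params = {"W": rng.normal(0, 0.01, (d, n_classes)), "b": np.zeros(n_classes)}
        self._adam = _AdamState({k: v.shape for k, v in self.params.items()})
        self.n_classes = n_classes

    @staticmethod
    def _flat(X: np.ndarray) -> np.ndarray:
        return X.reshape(len(X), -1)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _softmax(self._flat(X) @ self.params["W"] + self.params["b"])

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        p = self.predict_proba(X)
        return float(-np.mean(np.log(np.clip(p[np.arange(len(y)), y], 1e-12, 1.0))))

    def train_step(self, X, y, lr: float, weight_decay: float) -> float:
        Xf = self._flat(X)
        p = _softmax(Xf @ self.params["W"] + self.params["b"])
        loss = float(-np.mean(np.log(np.clip(p[np.arange(len(y)), y], 1e-12, 1.0))))
        delta = p.copy()
        delta[np.arange(len(y)), y] -= 1.0
        delta /= len(y)
        grads = {
            "W": Xf.T @ delta + weight_decay * self.params["W"],
            "b": delta.sum(axis=0),
        }
        self._adam.update(self.params, grads, lr)
        return loss

    def state_dict(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        self.params = {k: v.copy() for k, v in state.items()}


class TinyCNNBackend:
    """One fixed random conv stage + trained linear head; Grad-CAM capable.

    The convolution (``n_maps`` random 3x3x3 filters, stride 2, ReLU) is
    frozen at initialization; only the global-average-pooled linear head
    trains. That keeps training convex while still providing genuine
    spatial feature maps with analytic class-score gradients
    d(score_c)/dA_k(i,j) = W[k,c] / (h*w).
    """

    def __init__(self, n_maps: int = 8):
        self.n_maps = n_maps

    def initialize(self, input_shape, n_classes: int, seed: int) -> None:
        h, w, ch = input_shape
        rng = np.random.default_rng(seed)
        self.filters = rng.normal(0, 1.0, (self.n_maps, 3, 3, ch)) / np.sqrt(27)
        self.input_shape = (h, w, ch)
        self.n_classes = n_classes
        self.params = {
            "W": rng.normal(0, 0.01, (self.n_maps, n_classes)),
            "b": np.zeros(n_classes),
        }
        self._adam = _AdamState({k: v.shape for k, v in self.params.items()})

    def _conv(self, X: np.ndarray) -> np.ndarray:
        """Valid-mode stride-2 correlation + ReLU -> (n, h', w', n_maps)."""
        n, h, w, ch = X.shape
        hs = (h - 3) // 2 + 1
        ws = (w - 3) // 2 + 1
        windows = np.lib.stride_tricks.sliding_window_view(X, (3, 3, ch), axis=(1, 2, 3))
        windows = windows[:, ::2, ::2, 0]  # (n, hs, ws, 3, 3, ch)
        maps = np.einsum("nxyijc,kijc->nxyk", windows, self.filters)
        return np.maximum(maps, 0.0)

    def _features(self, X: np.ndarray) -> np.ndarray:
        return self._conv(X).mean(axis=(1, 2))  # global average pool

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _softmax(self._features(X) @ self.params["W"] + self.params["b"])

    def loss(self, X, y) -> float:
        p = self.predict_proba(X)
        return float(-np.mean(np.log(np.clip(p[np.arange(len(y)), y], 1e-12, 1.0))))

    def train_step(self, X, y, lr: float, weight_decay: float) -> float:
        F = self._features(X)
        p = _softmax(F @ self.params["W"] + self.params["b"])
        loss = float(-np.mean(np.log(np.clip(p[np.arange(len(y)), y], 1e-12, 1.0))))
        delta = p.copy()
        delta[np.arange(len(y)), y] -= 1.0
        delta /= len(y)
        grads = {
            "W": F.T @ delta + weight_decay * self.params["W"],
            "b": delta.sum(axis=0),
        }
        self._adam.update(self.params, grads, lr)
        return loss

    def state_dict(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        self.params = {k: v.copy() for k, v in state.items()}

    # Grad-CAM access -------------------------------------------------
    def last_conv_feature_maps(self, image: np.ndarray) -> np.ndarray:
        """(n_maps, h', w') activations of the conv stage for one image."""
        return np.moveaxis(self._conv(image[None])[0], -1, 0)

    def feature_map_gradients(self, image: np.ndarray, cls: int) -> np.ndarray:
        """d(score_cls)/d(feature maps), same shape as the maps."""
        maps = self.last_conv_feature_maps(image)
        _, h, w = maps.shape
        grad = self.params["W"][:, cls] / (h * w)
        return np.broadcast_to(grad[:, None, None], maps.shape).copy()


def gradcam(backend, image: np.ndarray, cls: int) -> np.ndarray:
    """Class-activation heatmap in [0, 1] at the input resolution.

    Per-map weights are the spatial means of the class-score gradients;
    the heatmap is the ReLU of the weighted map sum, bilinearly upsampled
    to the image's H x W and min-max normalized (an all-zero map stays
    all-zero). Requires a backend exposing its last convolutional stage.
    """
    if not hasattr(backend, "last_conv_feature_maps"):
        raise UnsupportedBackendError(
            f"{type(backend).__name__} exposes no convolutional feature maps"
        )
    maps = np.asarray(backend.last_conv_feature_maps(image), dtype=np.float64)
    grads = np.asarray(backend.feature_map_gradients(image, cls), dtype=np.float64)
    if maps.shape != grads.shape:
        raise ValueError("feature maps and gradients have mismatched shapes")
    weights = grads.mean(axis=(1, 2))
    cam = np.maximum(np.tensordot(weights, maps, axes=1), 0.0)
    cam = _sk_resize(cam, image.shape[:2], order=1, preserve_range=True)
    cam = np.maximum(cam, 0.0)  # bilinear overshoot guard
    peak = cam.max()
    return cam / peak if peak > 0 else cam


@dataclass
class ExperimentResult:
    report: MetricsReport
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")
    checkpoint: dict = field(default_factory=dict)
    split: DatasetSplit | None = None


def train_backend(
    backend,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig | None = None,
    seed: int = 0,
) -> ExperimentResult:
    """Adam + reduce-on-plateau training with best-val-loss checkpointing.

    The checkpoint is updated whenever validation loss decreases, so the
    returned state is always the epoch with minimal validation loss; the
    learning rate is multiplied by ``lr_factor`` when validation loss has
    not improved for ``lr_patience`` consecutive epochs.
    """
    cfg = config or TrainConfig()
    rng = np.random.default_rng(seed)
    n = len(X_train)
    lr = cfg.learning_rate
    result = ExperimentResult(report=None)
    stale = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        train_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            train_losses.append(backend.train_step(X_train[idx], y_train[idx], lr, cfg.weight_decay))
        val_loss = backend.loss(X_val, y_val)
        result.history.append(
            {"epoch": epoch, "train_loss": float(np.mean(train_losses)), "val_loss": val_loss, "lr": lr}
        )
        if val_loss < result.best_val_loss:
            result.best_val_loss = val_loss
            result.best_epoch = epoch
            result.checkpoint = backend.state_dict()
            stale = 0
        else:
            stale += 1
            if stale > cfg.lr_patience:
                lr *= cfg.lr_factor
                stale = 0
    backend.load_state_dict(result.checkpoint)
    return result


def _load_arrays(dataset_dir, class_names=None) -> tuple[np.ndarray, np.ndarray]:
    ls = load_labeled_set(dataset_dir, class_names=class_names)
    X = np.stack([load_image(p) for p in ls.paths])
    return X, ls.labels


def run_experiment(
    dataset_dir,
    enhancement: EMDEnhancer | None,
    backend,
    train: TrainConfig | None = None,
    seed: int = 0,
    class_names=None,
) -> ExperimentResult:
    """End-to-end: load, enhance, split, train, evaluate on test.

    ``enhancement=None`` is the no-EMD baseline. Pixels are scaled to
    [0, 1] and centered on the training mean after any enhancement. The
    reported metrics always come from the best-validation-loss checkpoint.
    Fully deterministic for a fixed seed and backend.
    """
    if class_names is None:
        # synthetic trees name their folders class_0..class_{k-1}; fall back
        # to the endoscopy class map otherwise
        dirs = sorted(p.name for p in Path(dataset_dir).iterdir() if p.is_dir())
        if all(re.fullmatch(r"class_\d+", d) for d in dirs):
            class_names = sorted(dirs, key=lambda d: int(d.split("_")[1]))
    X, y = _load_arrays(dataset_dir, class_names=class_names)
    if enhancement is not None:
        X = enhancement.fit_transform(X)
    split = split_dataset(y, seed=seed)
    if min(len(split.train_indices), len(split.val_indices), len(split.test_indices)) == 0:
        raise ValueError(
            "dataset too small: a split partition is empty "
            f"(train {len(split.train_indices)}, val {len(split.val_indices)}, "
            f"test {len(split.test_indices)}); need roughly 10+ images per class"
        )
    X = X / 255.0
    mu = X[split.train_indices].mean(axis=0)
    X = X - mu
    backend.initialize(X.shape[1:], int(y.max()) + 1, seed)
    result = train_backend(
        backend,
        X[split.train_indices],
        y[split.train_indices],
        X[split.val_indices],
        y[split.val_indices],
        train,
        seed=seed,
    )
    proba = backend.predict_proba(X[split.test_indices])
    preds = PredictionSet(
        true_labels=y[split.test_indices],
        predicted_labels=proba.argmax(axis=1),
        probabilities=proba,
        n_classes=int(y.max()) + 1,
    )
    result.report = aggregate_report(preds)
    result.split = split
    return result
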