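"""Pluggable convolutional image-classification stage.

The full-scale configuration of this stage is transfer learning: a frozen
pre-trained convolutional backbone supplies features, a global-average-
pooling head with light L1/L2 regularisation (1e-5) is trained on top (up
to 30 epochs with early stopping), then a brief fine-tuning phase (up to
10 epochs at a lowered learning rate) adapts the head further.  The
backbone is *pluggable*: any object with an ``extract(images) -> (N, D)``
method can be passed in, so any pre-trained feature extractor drops in
when one is available.

Without a backbone the stage degrades — behind an explicit flag — to a
small from-scratch convolutional network implemented in NumPy (one conv
layer, ReLU, average pooling, softmax head), sufficient for desk-scale
experiments on the synthetic cohort.  The three-class task uses focal
loss to counter class imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import CT1, CT2

FOCAL_ALPHA = 0.25
FOCAL_GAMMA = 2.0
L1L2_REG = 1e-5
MAX_EPOCHS = 30
FINE_TUNE_EPOCHS = 10


def focal_loss(probs: np.ndarray, y_true: np.ndarray,
               alpha: float = FOCAL_ALPHA, gamma: float = FOCAL_GAMMA) -> float:
    """Mean focal loss: ``-alpha * (1 - p_t)^gamma * log(p_t)``.

    ``probs`` is (N, K) class probabilities, ``y_true`` integer class
    indices.  Down-weights well-classified examples relative to plain
    cross-entropy (at the default alpha=0.25, gamma=2).
    """
    probs = np.clip(np.asarray(probs, dtype=float), 1e-12, 1.0)
    p_t = probs[np.arange(len(y_true)), np.asarray(y_true, dtype=int)]
    return float(np.mean(-alpha * (1.0 - p_t) ** gamma * np.log(p_t)))


def cross_entropy(probs: np.ndarray, y_true: np.ndarray) -> float:
    probs = np.clip(np.asarray(probs, dtype=float), 1e-12, 1.0)
    p_t = probs[np.arange(len(y_true)), np.asarray(y_true, dtype=int)]
    return float(np.mean(-np.log(p_t)))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _downscale(images: np.ndarray, edge: int) -> np.ndarray:
    n, h, w, c = images.shape
    yi = (np.arange(edge) * h / edge).astype(int)
    xi = (np.arange(edge) * w / edge).astype(int)
    return images[:, yi][:, :, xi].astype(float) / 255.0


def _conv_patches(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """im2col: (N, H, W, C) -> (N, OH, OW, k*k*C) via stride tricks."""
    n, h, w, c = x.shape
    oh, ow = (h - k) // stride + 1, (w - k) // stride + 1
    s = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x, shape=(n, oh, ow, k, k, c),
        strides=(s[0], s[1] * stride, s[2] * stride, s[1], s[2], s[3]),
        writeable=False,
    )
    return windows.reshape(n, oh, ow, k * k * c)


@dataclass
class ConvNetConfig:
    image_edge: int = 32
    n_filters: int = 8
    kernel: int = 5
    stride: int = 2
    pool: int = 2
    learning_rate: float = 0.05
    fine_tune_lr: float = 0.005
    batch_size: int = 32
    max_epochs: int = MAX_EPOCHS
    fine_tune_epochs: int = FINE_TUNE_EPOCHS
    patience: int = 5
    reg: float = L1L2_REG


class SmallConvNet:
    """A minimal conv -> ReLU -> average-pool -> softmax classifier.

    Trained with mini-batch SGD on cross-entropy (binary task) or focal
    loss (three-class task), with L1+L2 weight regularisation and early
    stopping on a held-out validation fold.  Single-threaded NumPy, fully
    seeded: repeated fits reproduce the same training curve.
    """

    def __init__(self, n_classes: int, task: str = CT1,
                 config: ConvNetConfig | None = None, seed: int = 0):
        self.cfg = config or ConvNetConfig()
        self.task = task
        self.n_classes = n_classes
        self.seed = seed
        self.classes_: np.ndarray | None = None
        self.history: list[float] = []

    # -- forward -----------------------------------------------------------
    def _forward(self, x: np.ndarray):
        cfg = self.cfg
        patches = _conv_patches(x, cfg.kernel, cfg.stride)  # (N, OH, OW, P)
        conv = patches @ self.Wc + self.bc  # (N, OH, OW, F)
        relu = np.maximum(conv, 0.0)
        n, oh, ow, f = relu.shape
        ph, pw = oh // cfg.pool, ow // cfg.pool
        pooled = relu[:, : ph * cfg.pool, : pw * cfg.pool].reshape(
            n, ph, cfg.pool, pw, cfg.pool, f).mean(axis=(2, 4))
        flat = pooled.reshape(n, -1)
        logits = flat @ self.Wd + self.bd
        return patches, conv, pooled, flat, _softmax(logits)

    def _loss(self, probs, y):
        return focal_loss(probs, y) if self.task == CT2 else cross_entropy(probs, y)

    # -- training ----------------------------------------------------------
    def fit(self, images: np.ndarray, labels, val_images=None, val_labels=None):
        cfg = self.cfg
        rng = np.random.default_rng(self.seed)
        self.classes_, y = np.unique(np.asarray(labels), return_inverse=True)
        x = _downscale(np.asarray(images), cfg.image_edge)
        n = len(x)
        if val_images is None:
            k = max(1, n // 5)
            perm = rng.permutation(n)
            val_idx, tr_idx = perm[:k], perm[k:]
            xv, yv, x, y = x[val_idx], y[val_idx], x[tr_idx], y[tr_idx]
        else:
            xv = _downscale(np.asarray(val_images), cfg.image_edge)
            yv = np.searchsorted(self.classes_, np.asarray(val_labels))

        p = cfg.kernel * cfg.kernel * 3
        self.Wc = rng.normal(0, np.sqrt(2.0 / p), size=(p, cfg.n_filters))
        self.bc = np.zeros(cfg.n_filters)
        oh = (cfg.image_edge - cfg.kernel) // cfg.stride + 1
        d = (oh // cfg.pool) ** 2 * cfg.n_filters
        self.Wd = rng.normal(0, np.sqrt(1.0 / d), size=(d, self.n_classes))
        self.bd = np.zeros(self.n_classes)

        best, best_state, stale = np.inf, None, 0
        lr = cfg.learning_rate
        for epoch in range(cfg.max_epochs + cfg.fine_tune_epochs):
            if epoch == cfg.max_epochs:
                lr = cfg.fine_tune_lr
            order = rng.permutation(len(x))
            for start in range(0, len(x), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                self._sgd_step(x[idx], y[idx], lr)
            _, _, _, _, pv = self._forward(xv)
            vloss = self._loss(pv, yv)
            self.history.append(vloss)
            if vloss < best - 1e-5:
                best, stale = vloss, 0
                best_state = (self.Wc.copy(), self.bc.copy(), self.Wd.copy(), self.bd.copy())
            else:
                stale += 1
                if stale >= cfg.patience and epoch >= cfg.max_epochs:
                    break
        if best_state is not None:
            self.Wc, self.bc, self.Wd, self.bd = best_state
        return self

    def _sgd_step(self, xb, yb, lr):
        cfg = self.cfg
        patches, conv, pooled, flat, probs = self._forward(xb)
        nb = len(xb)
        grad_logits = probs.copy()
        grad_logits[np.arange(nb), yb] -= 1.0
        if self.task == CT2:
            # focal-loss weighting of each sample's CE gradient
            p_t = np.clip(probs[np.arange(nb), yb], 1e-12, 1.0)
            wgt = FOCAL_ALPHA * (1 - p_t) ** FOCAL_GAMMA * (
                1 - FOCAL_GAMMA * p_t * np.log(p_t) / np.maximum(1 - p_t, 1e-12))
            grad_logits *= wgt[:, None]
        grad_logits /= nb

        gWd = flat.T @ grad_logits + cfg.reg * (np.sign(self.Wd) + 2 * self.Wd)
        gbd = grad_logits.sum(axis=0)
        grad_flat = grad_logits @ self.Wd.T
        n, ph, pw, f = pooled.shape
        grad_pool = grad_flat.reshape(n, ph, pw, f) / (cfg.pool * cfg.pool)
        oh = conv.shape[1]
        grad_relu = np.zeros_like(conv)
        gp = np.repeat(np.repeat(grad_pool, cfg.pool, axis=1), cfg.pool, axis=2)
        grad_relu[:, : gp.shape[1], : gp.shape[2]] = gp
        grad_conv = grad_relu * (conv > 0)
        gWc = np.einsum("nijp,nijf->pf", patches, grad_conv) + cfg.reg * (
            np.sign(self.Wc) + 2 * self.Wc)
        gbc = grad_conv.sum(axis=(0, 1, 2))

        self.Wd -= lr * gWd
        self.bd -= lr * gbd
        self.Wc -= lr * gWc
        self.bc -= lr * gbc

    # -- inference ---------------------------------------------------------
    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        x = _downscale(np.asarray(images), self.cfg.image_edge)
        return self._forward(x)[-1]

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.classes_[self.predict_proba(images).argmax(axis=1)]


class BackboneHead:
    """Frozen-backbone transfer head: softmax on extracted features."""

    def __init__(self, backbone, task: str = CT1, seed: int = 0,
                 reg: float = L1L2_REG, lr: float = 0.1,
                 max_epochs: int = MAX_EPOCHS + FINE_TUNE_EPOCHS):
        self.backbone = backbone
        self.task = task
        self.seed = seed
        self.reg = reg
        self.lr = lr
        self.max_epochs = max_epochs

    def fit(self, images, labels):
        rng = np.random.default_rng(self.seed)
        feats = np.asarray(self.backbone.extract(images), dtype=float)
        self.classes_, y = np.unique(np.asarray(labels), return_inverse=True)
        k = len(self.classes_)
        self.W = rng.normal(0, 0.01, size=(feats.shape[1], k))
        self.b = np.zeros(k)
        for _ in range(self.max_epochs):
            probs = _softmax(feats @ self.W + self.b)
            g = probs.copy()
            g[np.arange(len(y)), y] -= 1.0
            g /= len(y)
            self.W -= self.lr * (feats.T @ g + self.reg * (np.sign(self.W) + 2 * self.W))
            self.b -= self.lr * g.sum(axis=0)
        return self

    def predict_proba(self, images):
        feats = np.asarray(self.backbone.extract(images), dtype=float)
        return _softmax(feats @ self.W + self.b)

    def predict(self, images):
        return self.classes_[self.predict_proba(images).argmax(axis=1)]


def train_cnn(
    images: np.ndarray,
    labels,
    task: str = CT1,
    backbone=None,
    allow_fallback: bool = False,
    config: ConvNetConfig | None = None,
    seed: int = 0,
):
    """Train the convolutional stage.

    With a ``backbone`` (any object exposing ``extract(images)``), fits a
    regularised softmax head on its frozen features.  Without one, a small
    from-scratch NumPy conv net is trained instead — but only when
    ``allow_fallback=True``; otherwise a ``RuntimeError`` signals that the
    pre-trained backbone asset is missing.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training set contains a single class")
    if backbone is not None:
        return BackboneHead(backbone, task=task, seed=seed).fit(images, labels)
    if not allow_fallback:
        raise RuntimeError(
            "no convolutional backbone supplied; pass allow_fallback=True to "
            "train the small from-scratch network instead"
        )
    net = SmallConvNet(n_classes=len(np.unique(labels)), task=task, config=config, seed=seed)
    return net.fit(images, labels)
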