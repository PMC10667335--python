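"""Spectrogram-image classification with a fixed convolutional feature
extractor and a trained batch-norm/dense/dropout/dense head.

The classifier follows the transfer-learning recipe: a convolutional
backbone produces generic image features that are *not* updated, and a
four-layer head — batch normalization, a dense rectifier layer, dropout,
and a final dense sigmoid layer — is trained on top with the Adam optimizer
(learning rate 0.001, 10 epochs, batches of 4, binary cross-entropy, no
image augmentation).  The backbone here is a compact stack of seeded random
convolution filters (He-initialized, ReLU, stride-2) pooled to a fixed grid;
random convolutional features are a standard strong baseline for small-image
classification and keep the whole model dependency-free and CPU-fast.
Freezing the backbone also lets its activations be computed once per image
and cached across the 100 evaluation splits.

Grayscale images are replicated to three channels before the backbone, so
color and grayscale runs share one architecture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from PIL import Image

from .evaluate import EvalProtocol, EvalResult, auc
from .exceptions import ProtocolError


@dataclass(frozen=True)
class CnnConfig:
    """Architecture and optimization settings.

    input_size 600 matches the rendered spectrograms; smaller sizes
    (e.g. 128) keep CPU-only runs fast without changing the recipe.
    """

    input_size: int = 600
    hidden_units: int = 256
    dropout: float = 0.5
    learning_rate: float = 0.001
    epochs: int = 10
    batch_size: int = 4
    rng_seed: int = 0
    backbone_channels: Tuple[int, int] = (8, 16)
    pool_grid: int = 4

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid optimization settings")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


def _to_input_array(image, size: int) -> np.ndarray:
    """Normalize any image to float32 (size, size, 3) in [0, 1].

    Accepts uint8 or float arrays, (H, W) grayscale or (H, W, 3) color;
    grayscale is channel-replicated.
    """
    arr = np.asarray(image)
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float32) / 255.0
    else:
        arr = arr.astype(np.float32)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ProtocolError("expected (H, W) or (H, W, 3) image")
    if arr.shape[0] != size or arr.shape[1] != size:
        img8 = Image.fromarray(np.round(np.clip(arr, 0, 1) * 255).astype(np.uint8))
        arr = np.asarray(img8.resize((size, size), Image.BILINEAR)).astype(np.float32) / 255.0
    return np.clip(arr, 0.0, 1.0)


def _conv2d(x: np.ndarray, weights: np.ndarray, stride: int) -> np.ndarray:
    """Valid 2-D convolution via im2col.  x: (H, W, C), weights: (k, k, C, F)."""
    k = weights.shape[0]
    h, w, c = x.shape
    oh = (h - k) // stride + 1
    ow = (w - k) // stride + 1
    i0 = stride * np.arange(oh)
    j0 = stride * np.arange(ow)
    patches = np.empty((oh, ow, k * k * c), dtype=x.dtype)
    for di in range(k):
        for dj in range(k):
            block = x[np.ix_(i0 + di, j0 + dj)]
            patches[:, :, (di * k + dj) * c : (di * k + dj + 1) * c] = block
    wmat = weights.transpose(0, 1, 2, 3).reshape(k * k * c, -1)
    return patches @ wmat


class ConvBackbone:
    """Frozen random-filter feature extractor, deterministic per seed."""

    def __init__(self, cfg: CnnConfig) -> None:
        rng = np.random.default_rng(cfg.rng_seed + 101)
        c1, c2 = cfg.backbone_channels
        k = 5
        self.w1 = (rng.standard_normal((k, k, 3, c1)) * np.sqrt(2.0 / (k * k * 3))).astype(np.float32)
        self.w2 = (rng.standard_normal((k, k, c1, c2)) * np.sqrt(2.0 / (k * k * c1))).astype(np.float32)
        self.cfg = cfg
        self.n_features = 2 * cfg.pool_grid * cfg.pool_grid * c2

    def _pool(self, x: np.ndarray) -> np.ndarray:
        """Mean + standard-deviation pooling on a pool_grid^2 spatial grid.

        The std channel carries local activation texture — in spectrograms
        that is where cycle-to-cycle instability (jitter, pitch drift,
        noise) shows up, while the mean channel carries the smooth
        formant-band layout.
        """
        g = self.cfg.pool_grid
        h, w, c = x.shape
        hb = np.array_split(np.arange(h), g)
        wb = np.array_split(np.arange(w), g)
        out = np.empty((g, g, 2 * c), dtype=x.dtype)
        for i, hi in enumerate(hb):
            for j, wj in enumerate(wb):
                cell = x[np.ix_(hi, wj)]
                out[i, j, :c] = cell.mean(axis=(0, 1))
                out[i, j, c:] = cell.std(axis=(0, 1))
        return out

    def features(self, image) -> np.ndarray:
        x = _to_input_array(image, self.cfg.input_size)
        x = np.maximum(_conv2d(x, self.w1, stride=2), 0.0)
        x = np.maximum(_conv2d(x, self.w2, stride=2), 0.0)
        return self._pool(x).ravel()

    def features_batch(self, images: Sequence) -> np.ndarray:
        return np.vstack([self.features(img) for img in images])


class _Head:
    """Batch-norm -> dense(ReLU) -> dropout -> dense(sigmoid), Adam-trained."""

    def __init__(self, n_in: int, cfg: CnnConfig) -> None:
        rng = np.random.default_rng(cfg.rng_seed + 202)
        h = cfg.hidden_units
        self.cfg = cfg
        self.gamma = np.ones(n_in)
        self.beta = np.zeros(n_in)
        self.w1 = rng.standard_normal((n_in, h)) * np.sqrt(2.0 / n_in)
        self.b1 = np.zeros(h)
        self.w2 = rng.standard_normal((h, 1)) * np.sqrt(1.0 / h)
        self.b2 = np.zeros(1)
        self.run_mean = np.zeros(n_in)
        self.run_var = np.ones(n_in)
        self._adam_state = {}
        self._t = 0
        self._rng = rng

    # -- forward -----------------------------------------------------------
    def _bn_forward(self, x, training):
        eps = 1e-5
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.run_mean = 0.9 * self.run_mean + 0.1 * mu
            self.run_var = 0.9 * self.run_var + 0.1 * var
        else:
            mu, var = self.run_mean, self.run_var
        xhat = (x - mu) / np.sqrt(var + eps)
        return self.gamma * xhat + self.beta, (xhat, var, eps)

    def forward(self, x, training=False):
        out_bn, bn_cache = self._bn_forward(x, training)
        z1 = out_bn @ self.w1 + self.b1
        a1 = np.maximum(z1, 0.0)
        if training and self.cfg.dropout > 0:
            mask = (self._rng.random(a1.shape) >= self.cfg.dropout) / (1.0 - self.cfg.dropout)
        else:
            mask = np.ones_like(a1)
        d1 = a1 * mask
        z2 = d1 @ self.w2 + self.b2
        p = 1.0 / (1.0 + np.exp(-z2))
        cache = (x, bn_cache, out_bn, z1, a1, mask, d1, p)
        return p.ravel(), cache

    # -- backward ----------------------------------------------------------
    def _backward(self, cache, y):
        x, (xhat, var, eps), out_bn, z1, a1, mask, d1, p = cache
        n = y.size
        dz2 = (p - y.reshape(-1, 1)) / n  # BCE + sigmoid
        grads = {}
        grads["w2"] = d1.T @ dz2
        grads["b2"] = dz2.sum(axis=0)
        dd1 = dz2 @ self.w2.T
        da1 = dd1 * mask
        dz1 = da1 * (z1 > 0)
        grads["w1"] = out_bn.T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        dbn = dz1 @ self.w1.T
        grads["gamma"] = (dbn * xhat).sum(axis=0)
        grads["beta"] = dbn.sum(axis=0)
        # batch-norm backward (through batch statistics)
        m = x.shape[0]
        dxhat = dbn * self.gamma
        inv_std = 1.0 / np.sqrt(var + eps)
        # dx not needed (backbone frozen), but computed parameters are enough
        _ = m, dxhat, inv_std
        return grads

    def _adam_step(self, grads):
        cfg = self.cfg
        self._t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for name, g in grads.items():
            param = getattr(self, name)
            m, v = self._adam_state.get(name, (np.zeros_like(param), np.zeros_like(param)))
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            self._adam_state[name] = (m, v)
            mhat = m / (1 - b1**self._t)
            vhat = v / (1 - b2**self._t)
            setattr(self, name, param - cfg.learning_rate * mhat / (np.sqrt(vhat) + eps))

    def train(self, X, y):
        cfg = self.cfg
        n = y.size
        for _ in range(cfg.epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                if idx.size < 2:
                    continue  # batch statistics need >= 2 samples
                _, cache = self.forward(X[idx], training=True)
                self._adam_step(self._backward(cache, y[idx]))


class SpectrogramCnn:
    """Frozen-backbone image classifier with a trainable four-layer head."""

    def __init__(self, cfg: Optional[CnnConfig] = None, backbone: Optional[ConvBackbone] = None):
        self.cfg = cfg or CnnConfig()
        self.backbone = backbone or ConvBackbone(self.cfg)
        self.head = _Head(self.backbone.n_features, self.cfg)

    @property
    def head_layers(self) -> Tuple[str, str, str, str]:
        return ("batch_norm", "dense", "dropout", "dense")

    def fit(self, images: Sequence, labels: Sequence[int], features: Optional[np.ndarray] = None):
        y = np.asarray(labels, dtype=float)
        X = features if features is not None else self.backbone.features_batch(images)
        self.head.train(X, y)
        return self

    def predict_proba(self, images: Sequence, features: Optional[np.ndarray] = None) -> np.ndarray:
        X = features if features is not None else self.backbone.features_batch(images)
        p, _ = self.head.forward(X, training=False)
        return p


def build_model(cfg: Optional[CnnConfig] = None) -> SpectrogramCnn:
    """Construct the classifier; identical cfg and seed give identical
    initial parameters."""
    return SpectrogramCnn(cfg)


def train_and_eval_images(
    images: Sequence,
    labels: Sequence[int],
    cfg: Optional[CnnConfig] = None,
    protocol: Optional[EvalProtocol] = None,
) -> EvalResult:
    """Repeated-split AUC protocol on spectrogram images.

    Backbone activations are computed once per image and cached; every
    iteration draws a fresh stratified 70/30 split of *recordings*, trains a
    freshly initialized head and scores the untouched test images.  No
    augmentation is applied.
    """
    cfg = cfg or CnnConfig()
    protocol = protocol or EvalProtocol()
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size != 2 or min((y == c).sum() for c in np.unique(y)) < 2:
        raise ProtocolError("need at least two images per class")
    backbone = ConvBackbone(cfg)
    feats = backbone.features_batch(images)

    from sklearn.model_selection import train_test_split

    master = np.random.default_rng(protocol.rng_seed)
    iter_seeds = master.integers(0, 2**31 - 1, size=protocol.n_iterations)
    aucs = np.empty(protocol.n_iterations)
    for it, seed in enumerate(iter_seeds):
        seed = int(seed)
        idx_tr, idx_te = train_test_split(
            np.arange(y.size),
            train_size=protocol.train_fraction,
            random_state=seed,
            stratify=y,
        )
        iter_cfg = CnnConfig(
            input_size=cfg.input_size,
            hidden_units=cfg.hidden_units,
            dropout=cfg.dropout,
            learning_rate=cfg.learning_rate,
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            rng_seed=seed,
            backbone_channels=cfg.backbone_channels,
            pool_grid=cfg.pool_grid,
        )
        head = _Head(backbone.n_features, iter_cfg)
        head.train(feats[idx_tr], y[idx_tr].astype(float))
        scores, _ = head.forward(feats[idx_te], training=False)
        aucs[it] = auc(scores, y[idx_te])
    return EvalResult(
        auc_per_iteration=aucs,
        cv_auc_per_iteration=np.full(protocol.n_iterations, np.nan),
        model_name="cnn",
    )
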