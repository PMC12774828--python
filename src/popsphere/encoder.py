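"""Encoder network mapping one-hot genotype tensors to the 3D unit sphere,
and its contrastive training loop.

Architecture (channels-first input, shape ``(batch, 4, n_markers)``): two
1-D convolution layers (5 filters, kernel 3, stride 1, "same" padding, SiLU),
flatten, three dense layers of 256 units with batch normalization and SiLU,
a final dense layer with 3 units, and L2 normalization so every sample lands
on the unit sphere. Weights are trained with Adam (lr 0.001, beta1 0.9,
beta2 0.999) and the learning rate decays by 0.99 every 10 epochs.

The network and its backward pass are implemented directly on numpy arrays;
gradients of every layer and of the contrastive losses are analytic and are
checked against finite differences in the test suite.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from .augment import (AugmentationConfig, N_CHANNELS, augment_batch,
                      draw_rates, one_hot_batch)
from .losses import batch_loss_and_grad, select_negative_matrix

logger = logging.getLogger(__name__)

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

@dataclass
class EncoderConfig:
    """Hyperparameters of the encoder and its optimizer schedule."""

    n_markers: int = 0
    conv_layers: int = 2
    conv_filters: int = 5
    kernel: int = 3
    stride: int = 1
    dense_layers: int = 3
    dense_units: int = 256
    embedding_dim: int = 3
    epochs: int = 5000
    learning_rate: float = 0.001
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    lr_decay: float = 0.99
    lr_decay_every: int = 10
    lr_decay_unit: str = "epoch"   # "epoch" or "step"
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("conv_layers", "conv_filters", "kernel", "stride",
                     "dense_layers", "dense_units", "epochs", "batch_size",
                     "lr_decay_every"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")
        if self.lr_decay_unit not in ("epoch", "step"):
            raise ValueError("lr_decay_unit must be 'epoch' or 'step'")


@dataclass
class LossConfig:
    """Which contrastive loss to train with and how to pick negatives."""

    kind: str = "centroid"               # centroid | npair | triplet
    margin: float = 0.2                  # triplet margin
    negatives: str = "all"               # all | inverse_distance
    n_neg: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("centroid", "npair", "triplet"):
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if self.negatives not in ("all", "inverse_distance"):
            raise ValueError(f"unknown negative mode {self.negatives!r}")


@dataclass
class TrainingHistory:
    """Per-epoch training trace."""

    epoch_loss: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    epoch_seconds: list[float] = field(default_factory=list)
    seed: int = 0


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

def _silu(x: np.ndarray) -> np.ndarray:
    return x / (1.0 + np.exp(-x))


def _silu_grad(x: np.ndarray) -> np.ndarray:
    s = 1.0 / (1.0 + np.exp(-x))
    return s * (1.0 + x * (1.0 - s))


class _Conv1dSame:
    """1-D convolution, stride 1, zero 'same' padding, channels-first."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng) -> None:
        fan_in = c_in * kernel
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(c_out, c_in, kernel))
        self.b = np.zeros(c_out)
        self.kernel = kernel

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        k = self.kernel
        pad = k // 2
        n, c, d = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (pad, k - 1 - pad)))
        windows = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
        self._windows = windows                      # (n, c, d, k)
        return np.einsum("ncdk,fck->nfd", windows, self.w) + self.b[None, :, None]

    def backward(self, dout: np.ndarray):
        k = self.kernel
        pad = k // 2
        self.dw = np.einsum("ncdk,nfd->fck", self._windows, dout)
        self.db = dout.sum(axis=(0, 2))
        n, f, d = dout.shape
        c = self.w.shape[1]
        dxp = np.zeros((n, c, d + k - 1))
        for j in range(k):
            dxp[:, :, j:j + d] += np.einsum("nfd,fc->ncd", dout, self.w[:, :, j])
        return dxp[:, :, pad:pad + d]

    def grads(self):
        return [self.dw, self.db]


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng) -> None:
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray):
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.w.T

    def grads(self):
        return [self.dw, self.db]


class _BatchNorm:
    """Batch normalization over the batch axis of (batch, features)."""

    def __init__(self, n_feat: int) -> None:
        self.gamma = np.ones(n_feat)
        self.beta = np.zeros(n_feat)
        self.running_mean = np.zeros(n_feat)
        self.running_var = np.ones(n_feat)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (_BN_MOMENTUM * self.running_mean
                                 + (1.0 - _BN_MOMENTUM) * mean)
            self.running_var = (_BN_MOMENTUM * self.running_var
                                + (1.0 - _BN_MOMENTUM) * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        self._xhat = (x - mean) * self._inv_std
        return self.gamma * self._xhat + self.beta

    def backward(self, dout: np.ndarray):
        xhat = self._xhat
        self.dgamma = (dout * xhat).sum(axis=0)
        self.dbeta = dout.sum(axis=0)
        n = len(dout)
        return (self.gamma * self._inv_std / n) * (
            n * dout - dout.sum(axis=0) - xhat * (dout * xhat).sum(axis=0))

    def grads(self):
        return [self.dgamma, self.dbeta]


class _SiLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return _silu(x)

    def backward(self, dout: np.ndarray):
        return dout * _silu_grad(self._x)

    def grads(self):
        return []


class _Flatten:
    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(len(x), -1)

    def backward(self, dout: np.ndarray):
        return dout.reshape(self._shape)

    def grads(self):
        return []


class _L2Normalize:
    """Row-wise projection onto the unit sphere."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._norm = np.maximum(np.linalg.norm(x, axis=1, keepdims=True),
                                1e-12)
        self._y = x / self._norm
        return self._y

    def backward(self, dout: np.ndarray):
        y = self._y
        return (dout - y * (y * dout).sum(axis=1, keepdims=True)) / self._norm

    def grads(self):
        return []


# ---------------------------------------------------------------------------
# Encoder
# ---------------------------------------------------------------------------

class Encoder:
    """The spherical genotype encoder f_E."""

    def __init__(self, config: EncoderConfig,
                 marker_ids: list[str] | None = None) -> None:
        if config.n_markers < config.kernel:
            raise ValueError("n_markers must be at least the kernel size")
        self.config = config
        self.marker_ids = list(marker_ids) if marker_ids is not None else None
        rng = np.random.default_rng(config.seed)
        layers: list = []
        c_in = N_CHANNELS
        for _ in range(config.conv_layers):
            layers.append(_Conv1dSame(c_in, config.conv_filters,
                                      config.kernel, rng))
            layers.append(_SiLU())
            c_in = config.conv_filters
        layers.append(_Flatten())
        n_in = config.conv_filters * config.n_markers
        for _ in range(config.dense_layers):
            layers.append(_Dense(n_in, config.dense_units, rng))
            layers.append(_BatchNorm(config.dense_units))
            layers.append(_SiLU())
            n_in = config.dense_units
        layers.append(_Dense(n_in, config.embedding_dim, rng))
        layers.append(_L2Normalize())
        self.layers = layers

    # -- plumbing ----------------------------------------------------------

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if x.ndim != 3 or x.shape[1] != N_CHANNELS \
                or x.shape[2] != self.config.n_markers:
            raise ValueError(
                f"expected input (batch, {N_CHANNELS}, "
                f"{self.config.n_markers}), got {x.shape}")
        h = np.asarray(x, dtype=float)
        for layer in self.layers:
            h = layer.forward(h, training)
        return h

    def backward(self, dz: np.ndarray) -> None:
        g = dz
        for layer in reversed(self.layers):
            g = layer.backward(g)


def build_encoder(config: EncoderConfig,
                  marker_ids: list[str] | None = None) -> Encoder:
    """Build the encoder with seed-deterministic initialization."""
    return Encoder(config, marker_ids=marker_ids)


def embed(encoder: Encoder, one_hot: np.ndarray,
          inference_mode: bool = True) -> np.ndarray:
    """Embed a one-hot batch; returns (n, embedding_dim) unit vectors.

    In inference mode batch normalization uses the accumulated running
    statistics, so each row is independent of the rest of the batch.
    """
    return encoder.forward(one_hot, training=not inference_mode)


def embed_genotypes(encoder: Encoder, calls: np.ndarray,
                    batch_size: int = 256) -> np.ndarray:
    """Embed raw calls (missing allowed, routed to the missing channel),
    un-augmented, in inference mode."""
    calls = np.asarray(calls)
    out = []
    for start in range(0, len(calls), batch_size):
        x = one_hot_batch(calls[start:start + batch_size])
        out.append(embed(encoder, x, inference_mode=True))
    return np.vstack(out)


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float, beta2: float, eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            mhat = m / (1.0 - b1 ** self.t)
            vhat = v / (1.0 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _batches(n: int, batch_size: int, rng) -> list[np.ndarray]:
    order = rng.permutation(n)
    batches = [order[i:i + batch_size] for i in range(0, n, batch_size)]
    if len(batches) > 1 and len(batches[-1]) < 2:
        batches[-2] = np.concatenate([batches[-2], batches[-1]])
        batches.pop()
    return batches


def train(calls_train: np.ndarray, encoder: Encoder,
          loss_config: LossConfig | None = None,
          aug_config: AugmentationConfig | None = None,
          epochs: int | None = None, seed: int | None = None,
          log_every: int = 50):
    """Train the encoder contrastively on a complete-call genotype matrix.

    Every batch, two independently augmented views of each sample are
    embedded in a single forward pass (anchor = view 1, positive = view 2;
    negatives come from the other samples' view-1 embeddings), the selected
    contrastive loss and its gradient are evaluated, and an Adam update is
    applied. Fully reproducible given the seed.

    Returns ``(encoder, TrainingHistory)``; the encoder is trained in place.
    """
    loss_config = loss_config or LossConfig()
    aug_config = aug_config or AugmentationConfig()
    cfg = encoder.config
    epochs = cfg.epochs if epochs is None else epochs
    seed = cfg.seed if seed is None else seed
    calls_train = np.asarray(calls_train)
    if len(calls_train) < 2:
        raise ValueError("need at least 2 training samples")

    rng = np.random.default_rng(seed)
    opt = _Adam(encoder.params(), cfg.learning_rate,
                cfg.adam_beta1, cfg.adam_beta2)
    history = TrainingHistory(seed=seed)
    step = 0
    for epoch in range(epochs):
        t0 = time.perf_counter()
        if cfg.lr_decay_unit == "epoch":
            opt.lr = cfg.learning_rate * cfg.lr_decay ** (epoch // cfg.lr_decay_every)
        epoch_loss = 0.0
        n_anchors = 0
        for idx in _batches(len(calls_train), cfg.batch_size, rng):
            if cfg.lr_decay_unit == "step":
                opt.lr = cfg.learning_rate * cfg.lr_decay ** (step // cfg.lr_decay_every)
            batch = calls_train[idx]
            b = len(batch)
            pflip, pmask = draw_rates(2 * b, aug_config, rng)
            views = augment_batch(np.vstack([batch, batch]),
                                  pflip, pmask, rng)
            z = encoder.forward(views, training=True)
            z1, z2 = z[:b], z[b:]
            neg_idx = select_negative_matrix(z1, loss_config.n_neg,
                                             loss_config.negatives, rng)
            loss, dz1, dz2 = batch_loss_and_grad(
                z1, z2, neg_idx=neg_idx, kind=loss_config.kind,
                alpha=loss_config.margin)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {step}: {loss}")
            encoder.backward(np.vstack([dz1, dz2]))
            opt.step(encoder.grads())
            epoch_loss += loss
            n_anchors += b
            step += 1
        history.epoch_loss.append(epoch_loss / n_anchors)
        history.learning_rate.append(opt.lr)
        history.epoch_seconds.append(time.perf_counter() - t0)
        if log_every and (epoch % log_every == 0 or epoch == epochs - 1):
            logger.info("epoch %d/%d  loss %.5f  lr %.6f",
                        epoch + 1, epochs, history.epoch_loss[-1], opt.lr)
    return encoder, history


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(encoder: Encoder, path) -> None:
    """Save weights, batch-norm statistics, config, and marker ids."""
    arrays: dict[str, np.ndarray] = {}
    for i, layer in enumerate(encoder.layers):
        for j, p in enumerate(layer.params()):
            arrays[f"param_{i}_{j}"] = p
        if isinstance(layer, _BatchNorm):
            arrays[f"running_mean_{i}"] = layer.running_mean
            arrays[f"running_var_{i}"] = layer.running_var
    meta = {"config": asdict(encoder.config),
            "marker_ids": encoder.marker_ids}
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path, marker_ids: list[str] | None = None) -> Encoder:
    """Restore an encoder; if ``marker_ids`` is given, verify compatibility.

    A marker-set mismatch raises with the discrepancy listed, so a model
    cannot silently be fine-tuned on the wrong marker panel.
    """
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        encoder = Encoder(EncoderConfig(**meta["config"]),
                          marker_ids=meta["marker_ids"])
        if marker_ids is not None:
            saved = meta["marker_ids"]
            if saved is not None and list(marker_ids) != list(saved):
                missing = sorted(set(saved) - set(marker_ids))[:5]
                extra = sorted(set(marker_ids) - set(saved))[:5]
                raise ValueError(
                    "checkpoint marker set does not match the data: "
                    f"{len(saved)} saved vs {len(marker_ids)} given; "
                    f"first missing {missing}, first unexpected {extra}")
            if len(marker_ids) != encoder.config.n_markers:
                raise ValueError(
                    f"checkpoint expects {encoder.config.n_markers} markers, "
                    f"data has {len(marker_ids)}")
        for i, layer in enumerate(encoder.layers):
            for j, p in enumerate(layer.params()):
                p[...] = data[f"param_{i}_{j}"]
            if isinstance(layer, _BatchNorm):
                layer.running_mean[...] = data[f"running_mean_{i}"]
                layer.running_var[...] = data[f"running_var_{i}"]
    return encoder
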