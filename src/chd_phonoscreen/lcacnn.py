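"""The LCACNN classifier.

Four groups of (convolution -> batch norm -> ReLU -> mixed pooling ->
coordinate attention); the first two groups use standard convolutions,
later groups depthwise-separable ones, then global average pooling and a
sigmoid head give the CHD probability.  Trained with Adam on binary
cross-entropy; the mixed-pooling selector lambda is resampled Bernoulli(0.5)
per layer per training batch and fixed to 0.5 at inference so that
forward passes are deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from chd_phonoscreen.nn import (
    Tensor, Module, Conv2d, DepthwiseSeparableConv2d, BatchNorm2d,
    MixedPool2d, CoordinateAttention, Dense, Adam,
)

BCE_EPS = 1e-12


@dataclass
class LcacnnConfig:
    """Architecture and training settings.

    ``channels`` gives per-group output widths; groups indexed at or
    beyond ``separable_from_group`` use depthwise-separable convolutions.
    """

    n_groups: int = 4
    channels: tuple = (8, 16, 32, 64, 128)
    kernel: int = 3
    ca_reduction: int = 8
    pool: int = 2
    learning_rate: float = 0.001
    batch_size: int = 64
    epochs: int = 100
    seed: int = 0
    input_shape: tuple = (32, 32)
    inference_lam: float = 0.5
    separable_from_group: int = 2

    def validate(self) -> None:
        if not 1 <= self.n_groups <= 5:
            raise ValueError(f"n_groups must be in [1, 5], got {self.n_groups}")
        if len(self.channels) < self.n_groups:
            raise ValueError("channels must list a width per group")
        if self.kernel % 2 == 0:
            raise ValueError("kernel must be odd")


class Lcacnn(Module):
    def __init__(self, config: LcacnnConfig, input_channels: int = 1):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        h, w = config.input_shape
        self.groups = []
        c_in = input_channels
        for g in range(config.n_groups):
            c_out = config.channels[g]
            conv_cls = (Conv2d if g < config.separable_from_group
                        else DepthwiseSeparableConv2d)
            block = [
                conv_cls(c_in, c_out, config.kernel, rng),
                BatchNorm2d(c_out),
                MixedPool2d(config.pool, config.inference_lam),
                CoordinateAttention(c_out, min(config.ca_reduction, c_out), rng),
            ]
            self.groups.append(block)
            c_in = c_out
            h = -(-h // config.pool)
            w = -(-w // config.pool)
            if h < 1 or w < 1:
                raise ValueError(f"feature map collapses to zero size at group {g}")
        self.head = Dense(c_in, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        for conv, bn, pool, ca in self.groups:
            x = ca(pool(bn(conv(x)).relu()))
        x = x.mean(axis=(2, 3))            # global average pooling -> (N, C)
        return self.head(x).sigmoid().reshape(-1)

    def mixed_pools(self) -> list[MixedPool2d]:
        return [m for m in self.modules() if isinstance(m, MixedPool2d)]


def build_model(config: LcacnnConfig, input_channels: int = 1) -> Lcacnn:
    return Lcacnn(config, input_channels)


def mixed_pool(x: np.ndarray, size: int, lam: float) -> np.ndarray:
    """Functional mixed pooling on a (..., H, W) array:
    y = lam * max + (1 - lam) * mean per non-overlapping region."""
    a = np.asarray(x, dtype=np.float64)
    squeeze = a.ndim == 2
    if squeeze:
        a = a[None, None]
    elif a.ndim == 3:
        a = a[None]
    t = Tensor(a)
    n, c, h, w = t.shape
    t = t.pad_edge2d((-h) % size, (-w) % size)
    out = lam * t.max_pool2d(size).data + (1 - lam) * t.avg_pool2d(size).data
    return out[0, 0] if squeeze else out


def bce_loss(y, p) -> float:
    """Binary cross-entropy, batch mean; p clipped to [eps, 1-eps]."""
    y = np.asarray(y, dtype=np.float64)
    p = np.clip(np.asarray(p, dtype=np.float64), BCE_EPS, 1 - BCE_EPS)
    return float(np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p))))


def _bce_tensor(p: Tensor, y: np.ndarray) -> Tensor:
    eps = 1e-7
    pc = p * (1 - 2 * eps) + eps
    yt = Tensor(y)
    return -(yt * pc.log() + (1.0 - yt) * (1.0 - pc).log()).mean()


def train(model: Lcacnn, X: np.ndarray, y: np.ndarray,
          config: LcacnnConfig | None = None, epochs: int | None = None) -> dict:
    """Train on (N, 1, H, W) maps with labels in {0, 1}.

    Returns a history dict with per-epoch mean training loss and accuracy.
    The config seed drives shuffling and the per-batch mixed-pooling
    lambda streams; weight init was already seeded at build time.
    """
    config = config or model.config
    y = np.asarray(y, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    n = len(y)
    epochs = epochs if epochs is not None else config.epochs
    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    pools = model.mixed_pools()
    history = {"loss": [], "accuracy": []}
    model.set_training(True)
    for _ in range(epochs):
        perm = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            for p in pools:
                p.lam = float(rng.integers(0, 2))
            xb = Tensor(X[idx])
            pb = model(xb)
            loss = _bce_tensor(pb, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data) * len(idx))
            correct += int(np.sum((pb.data >= 0.5) == (y[idx] == 1)))
        history["loss"].append(sum(losses) / n)
        history["accuracy"].append(correct / n)
    return history


def predict(model: Lcacnn, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """CHD probabilities; deterministic (eval mode, lambda = inference_lam)."""
    model.set_training(False)
    out = []
    for start in range(0, len(X), batch_size):
        out.append(model(Tensor(X[start:start + batch_size])).data)
    model.set_training(True)
    return np.concatenate(out) if out else np.zeros(0)


def save_model(model: Lcacnn, path) -> None:
    """Checkpoint: npz weight arrays plus a JSON architecture manifest."""
    path = Path(path)
    arrs = model.state_arrays()
    np.savez(path.with_suffix(".npz"), *arrs)
    manifest = asdict(model.config)
    manifest["channels"] = list(manifest["channels"])
    manifest["input_shape"] = list(manifest["input_shape"])
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_model(path) -> Lcacnn:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    manifest["channels"] = tuple(manifest["channels"])
    manifest["input_shape"] = tuple(manifest["input_shape"])
    model = Lcacnn(LcacnnConfig(**manifest))
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_arrays([data[k] for k in data.files])
    return model
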