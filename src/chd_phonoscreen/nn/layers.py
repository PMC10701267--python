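"""Layers for the LCACNN classifier."""

from __future__ import annotations

import numpy as np

from chd_phonoscreen.nn.autodiff import Tensor, concat


class Module:
    """Base class: parameter collection and train/eval mode switching."""

    training: bool = True

    @staticmethod
    def _children(value):
        """Yield Modules/Tensors from a value, recursing through lists."""
        if isinstance(value, (Module, Tensor)):
            yield value
        elif isinstance(value, (list, tuple)):
            for item in value:
                yield from Module._children(item)

    def parameters(self) -> list[Tensor]:
        out = []
        for v in self.__dict__.values():
            for child in self._children(v):
                if isinstance(child, Tensor):
                    if child.requires_grad:
                        out.append(child)
                else:
                    out.extend(child.parameters())
        return out

    def modules(self) -> list["Module"]:
        out = [self]
        for v in self.__dict__.values():
            for child in self._children(v):
                if isinstance(child, Module):
                    out.extend(child.modules())
        return out

    def set_training(self, flag: bool) -> None:
        for m in self.modules():
            m.training = flag

    def n_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    # -- flat state (for checkpointing) ----------------------------------

    def state_arrays(self) -> list[np.ndarray]:
        arrs = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                arrs.extend([m.running_mean, m.running_var])
        return arrs

    def load_state_arrays(self, arrs: list[np.ndarray]) -> None:
        arrs = list(arrs)
        for p in self.parameters():
            a = arrs.pop(0)
            if a.shape != p.data.shape:
                raise ValueError("checkpoint shape mismatch")
            p.data = a.astype(np.float64)
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = arrs.pop(0).astype(np.float64)
                m.running_var = arrs.pop(0).astype(np.float64)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    return Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape), requires_grad=True)


class Conv2d(Module):
    """Standard convolution, stride 1, same padding, odd kernel."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, bias: bool = True):
        if kernel % 2 == 0:
            raise ValueError("kernel must be odd")
        self.w = _he_init(rng, (out_channels, in_channels, kernel, kernel),
                          in_channels * kernel * kernel)
        self.b = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.w, self.b)


class DepthwiseSeparableConv2d(Module):
    """Depthwise k x k per channel followed by a pointwise 1 x 1 mix.

    Parameter count c*k^2 + c*o (+o bias) versus c*o*k^2 for the standard
    convolution of the same receptive field.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, bias: bool = True):
        if kernel % 2 == 0:
            raise ValueError("kernel must be odd")
        self.dw = _he_init(rng, (in_channels, kernel, kernel), kernel * kernel)
        self.pw = _he_init(rng, (out_channels, in_channels, 1, 1), in_channels)
        self.b = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.depthwise_conv2d(self.dw).conv2d(self.pw, self.b)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)
        self.running_mean = np.zeros((1, channels, 1, 1))
        self.running_var = np.ones((1, channels, 1, 1))
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data)
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            xhat = (x - Tensor(self.running_mean)) * ((self.running_var + self.eps) ** -0.5)
        return self.gamma * xhat + self.beta


class MixedPool2d(Module):
    """y = lambda * maxpool(x) + (1 - lambda) * avgpool(x).

    During training ``lam`` is resampled in {0, 1} per batch by the
    trainer (1 = max pooling, 0 = average pooling); at inference it is
    fixed to ``inference_lam`` so forward passes are deterministic.
    """

    def __init__(self, size: int = 2, inference_lam: float = 0.5):
        self.size = size
        self.lam = 1.0
        self.inference_lam = inference_lam

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        s = self.size
        x = x.pad_edge2d((-h) % s, (-w) % s)
        lam = self.lam if self.training else self.inference_lam
        if lam == 1.0:
            return x.max_pool2d(s)
        if lam == 0.0:
            return x.avg_pool2d(s)
        return lam * x.max_pool2d(s) + (1.0 - lam) * x.avg_pool2d(s)


class CoordinateAttention(Module):
    """Coordinate attention: axis-wise pooled context gates the input.

    The input (N, C, H, W) is average-pooled along each spatial axis,
    the two axis profiles are concatenated and squeezed to C/reduction
    channels (1x1 conv + BN + ReLU), split back, re-expanded per axis
    (1x1 conv + sigmoid), and the two gates multiply the input.  Output
    magnitudes never exceed the input's (gates lie in (0, 1)).
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        if reduction > channels:
            raise ValueError(f"reduction {reduction} exceeds channel count {channels}")
        mid = max(1, channels // reduction)
        self.squeeze = Conv2d(channels, mid, 1, rng)
        self.bn = BatchNorm2d(mid)
        self.expand_h = Conv2d(mid, channels, 1, rng)
        self.expand_w = Conv2d(mid, channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        mh = x.mean(axis=3, keepdims=True)                    # (N,C,H,1)
        mw = x.mean(axis=2, keepdims=True)                    # (N,C,1,W)
        mh_flat = mh.transpose((0, 1, 3, 2))                  # (N,C,1,H)
        y = concat([mh_flat, mw], axis=3)                     # (N,C,1,H+W)
        y = self.bn(self.squeeze(y)).relu()
        yh = y[:, :, :, :h].transpose((0, 1, 3, 2))           # (N,mid,H,1)
        yw = y[:, :, :, h:]                                   # (N,mid,1,W)
        gate_h = self.expand_h(yh).sigmoid()                  # (N,C,H,1)
        gate_w = self.expand_w(yw).sigmoid()                  # (N,C,1,W)
        return x * gate_h * gate_w


class Dense(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.w = _he_init(rng, (in_features, out_features), in_features)
        self.b = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x.matmul(self.w) + self.b


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
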