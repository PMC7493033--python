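"""Neural-network layers built on the autodiff ``Tensor``.

Implements the building blocks used by both the B-scan feature extractor and
the volume-level classifiers: same-padded 2-D convolution, batch
normalization, leaky ReLU, 2x2 floor max pooling, fully connected layers, and
the convolutional block attention module (CBAM, channel attention followed by
spatial attention).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concatenate

__all__ = [
    "Module", "Parameter", "Conv2d", "BatchNorm2d", "MaxPool2d", "Linear",
    "ConvBlock", "CBAM", "softmax", "softmax_cross_entropy",
]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter collection, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for v in vars(self).values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # state as a flat dict of arrays (parameters + buffers), for checkpoints
    def state_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, v in vars(self).items():
            if isinstance(v, Parameter):
                state[prefix + name] = v.data
            elif isinstance(v, np.ndarray):
                state[prefix + name] = v
            elif isinstance(v, Module):
                state.update(v.state_arrays(prefix + name + "."))
            elif isinstance(v, (list, tuple)):
                for idx, item in enumerate(v):
                    if isinstance(item, Module):
                        state.update(item.state_arrays(f"{prefix}{name}.{idx}."))
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, v in vars(self).items():
            if isinstance(v, Parameter):
                v.data = np.array(state[prefix + name], dtype=np.float64)
            elif isinstance(v, np.ndarray):
                setattr(self, name, np.array(state[prefix + name]))
            elif isinstance(v, Module):
                v.load_state_arrays(state, prefix + name + ".")
            elif isinstance(v, (list, tuple)):
                for idx, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_arrays(state, f"{prefix}{name}.{idx}.")


class Conv2d(Module):
    """3x3-style convolution with "same" zero padding and stride 1.

    Weight layout is (out_channels, in_channels * kh * kw), applied to im2col
    patch columns; odd kernel sizes only, so the output spatial size equals
    the input's.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for same padding")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        # He initialisation, appropriate for (leaky-)ReLU nonlinearities
        self.weight = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                           size=(out_channels, fan_in)))
        self.bias = Parameter(np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        pad = self.kernel_size // 2
        cols = x.pad2d(pad, pad).im2col(self.kernel_size, self.kernel_size)
        out = self.weight @ cols  # (N, out_channels, H*W) by broadcasting
        out = out.reshape(n, self.out_channels, h, w)
        return out + self.bias.reshape(1, self.out_channels, 1, 1)

    __call__ = forward


class BatchNorm2d(Module):
    """Per-channel batch normalization over (N, H, W) with running statistics."""

    def __init__(self, num_channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_channels = num_channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_channels))
        self.beta = Parameter(np.zeros(num_channels))
        self.running_mean = np.zeros(num_channels)
        self.running_var = np.ones(num_channels)

    def forward(self, x: Tensor) -> Tensor:
        c = self.num_channels
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mu
            var = (centered ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(c))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(c))
            # fold gamma into the inverse sd so only two full-size passes run
            scale = ((var + self.eps) ** -0.5) * self.gamma.reshape(1, c, 1, 1)
            return centered * scale + self.beta.reshape(1, c, 1, 1)
        mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
        scale = Tensor(1.0 / np.sqrt(self.running_var.reshape(1, c, 1, 1) + self.eps)
                       ) * self.gamma.reshape(1, c, 1, 1)
        return (x - mu) * scale + self.beta.reshape(1, c, 1, 1)

    __call__ = forward


class MaxPool2d(Module):
    """2x2 max pooling with stride 2; odd trailing rows/columns are dropped
    (floor semantics, so 25 rows pool to 12)."""

    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        s = self.size
        h2, w2 = h // s, w // s
        if h2 < 1 or w2 < 1:
            raise ValueError(f"spatial dims {h}x{w} too small for {s}x{s} pooling")
        x = x[:, :, : h2 * s, : w2 * s]
        x = x.reshape(n, c, h2, s, w2, s)
        return x.max(axis=5).max(axis=3)

    __call__ = forward


class Linear(Module):
    """Fully connected layer: y = x W + b."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        bound = np.sqrt(1.0 / in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    __call__ = forward


class ConvBlock(Module):
    """conv(3x3, same) -> batch norm -> LeakyReLU -> max-pool(2x2, floor)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 leaky_slope: float, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, kernel_size, rng)
        self.bn = BatchNorm2d(out_channels)
        self.leaky_slope = leaky_slope
        self.pool = MaxPool2d(2)

    def forward(self, x: Tensor) -> Tensor:
        return self.pool(self.bn(self.conv(x)).leaky_relu(self.leaky_slope))

    __call__ = forward


class CBAM(Module):
    """Convolutional block attention module.

    Channel attention first: global average- and max-pooled channel
    descriptors share a two-layer bottleneck MLP (reduction ``r``, ReLU
    between); the two outputs are summed and squashed by a sigmoid into
    per-channel weights in (0, 1), multiplied onto the input. Spatial
    attention second: channel-wise mean and max maps are concatenated and
    convolved with a ``spatial_kernel`` filter, sigmoid-squashed into a
    spatial weight map, multiplied on. Output shape equals input shape.

    The gate output layers start with a positive bias ("open" gates, as in
    highway-style gating): at initialization both attentions are close to 1,
    so the module approximates the identity and does not attenuate
    activations and gradients before it has learned anything.
    """

    OPEN_GATE_BIAS = 2.0

    def __init__(self, channels: int, reduction: int, spatial_kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        if reduction > channels:
            raise ValueError(f"reduction {reduction} exceeds channel count {channels}")
        self.channels = channels
        self.reduction = reduction
        self.fc1 = Linear(channels, channels // reduction, rng)
        self.fc2 = Linear(channels // reduction, channels, rng)
        self.spatial_conv = Conv2d(2, 1, spatial_kernel, rng)
        self.fc2.bias.data[:] = self.OPEN_GATE_BIAS
        self.spatial_conv.bias.data[:] = self.OPEN_GATE_BIAS

    def _mlp(self, v: Tensor) -> Tensor:
        return self.fc2(self.fc1(v).relu())

    def channel_attention(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=(2, 3))            # (N, C)
        mx = x.max(axis=3).max(axis=2)       # (N, C)
        return (self._mlp(avg) + self._mlp(mx)).sigmoid()

    def spatial_attention(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)  # (N, 1, H, W)
        mx = x.max(axis=1, keepdims=True)
        return self.spatial_conv(concatenate([avg, mx], axis=1)).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        x = x * self.channel_attention(x).reshape(n, c, 1, 1)
        return x * self.spatial_attention(x)

    __call__ = forward


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis (plain ndarray)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy loss for integer class targets."""
    n, k = logits.shape
    shift = Tensor(logits.data.max(axis=1, keepdims=True))  # constant shift
    z = logits - shift
    log_norm = z.exp().sum(axis=1, keepdims=True).log()
    onehot = np.zeros((n, k))
    onehot[np.arange(n), np.asarray(targets, dtype=int)] = 1.0
    log_probs = z - log_norm
    return -(log_probs * Tensor(onehot)).sum() * (1.0 / n)
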