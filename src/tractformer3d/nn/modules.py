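"""Layer abstractions over the functional operators.

Parameters are ``Tensor`` objects with ``requires_grad=True``; modules are
discovered by attribute walk, so plain attribute assignment registers both
parameters and sub-modules (lists of modules are also walked).
"""
from __future__ import annotations

from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Tensor


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        def walk(key, val):
            if isinstance(val, Tensor) and val.requires_grad:
                yield key, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{key}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    yield from walk(f"{key}.{i}", item)

        for name, val in vars(self).items():
            yield from walk(f"{prefix}{name}", val)

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for k, v in own.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != v.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {v.data.shape}")
            v.data = arr

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / max(fan_in, 1))
    return rng.normal(0.0, std, size=shape)


class Conv3d(Module):
    """Dense 3D convolution, channels last, weight (k,k,k,Cin,Cout)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 init: str = "he"):
        self.stride, self.padding = stride, padding
        w = _he_normal(rng, (k, k, k, cin, cout), cin * k ** 3)
        if init == "zero":       # residual-branch outputs: start as identity
            w = np.zeros_like(w)
        elif init == "small":    # output heads: keep initial logits near 0
            w *= 0.25
        self.weight = parameter(w)
        self.bias = parameter(np.zeros(cout)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if self.weight.shape[0] == 1 and self.stride == 1:
            w = self.weight.reshape(self.weight.shape[3], self.weight.shape[4])
            return F.pointwise_conv3d(x, w, self.bias)
        return F.conv3d(x, self.weight, self.bias, self.stride, self.padding)


class DepthwiseConv3d(Module):
    """Per-channel 3D convolution, weight (k,k,k,C)."""

    def __init__(self, c: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = False):
        self.stride, self.padding = stride, padding
        self.weight = parameter(_he_normal(rng, (k, k, k, c), k ** 3))
        self.bias = parameter(np.zeros(c)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.depthwise_conv3d(x, self.weight, self.bias, self.stride, self.padding)


class SeparableConv3d(Module):
    """Depthwise k^3 followed by pointwise 1^3 (the projection used throughout the attention and feed-forward maps)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None, bias: bool = False):
        if padding is None:
            padding = k // 2
        self.depthwise = DepthwiseConv3d(cin, k, rng, stride, padding, bias=False)
        self.pointwise = parameter(_he_normal(rng, (cin, cout), cin))
        self.bias = parameter(np.zeros(cout)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = self.depthwise(x)
        B, H, W, D, _ = y.shape
        out = y.reshape(-1, self.pointwise.shape[0]).matmul(self.pointwise)
        if self.bias is not None:
            out = out + self.bias
        return out.reshape(B, H, W, D, self.pointwise.shape[1])


class ConvTranspose3d(Module):
    """Dense transposed conv (exact x2 upsampling with k=4, s=2, p=1).

    Lowered to zero-stuffing + a stride-1 convolution; the stored weight is
    already in the orientation the lowered convolution consumes.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 2, padding: int = 1, bias: bool = False):
        self.k, self.stride, self.padding = k, stride, padding
        self.weight = parameter(_he_normal(rng, (k, k, k, cin, cout), cin * k ** 3))
        self.bias = parameter(np.zeros(cout)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        stuffed = F.zero_stuff(x, self.stride)
        pad = self.k - 1 - self.padding
        return F.conv3d(stuffed, self.weight, self.bias, stride=1, padding=pad)


class SeparableConvTranspose3d(Module):
    """Depthwise transposed k^3 resampling followed by a pointwise channel map."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 2, padding: int = 1, bias: bool = False):
        self.k, self.stride, self.padding = k, stride, padding
        self.depthwise = parameter(_he_normal(rng, (k, k, k, cin), k ** 3))
        self.pointwise = parameter(_he_normal(rng, (cin, cout), cin))
        self.bias = parameter(np.zeros(cout)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        stuffed = F.zero_stuff(x, self.stride)
        pad = self.k - 1 - self.padding
        y = F.depthwise_conv3d(stuffed, self.depthwise, None, stride=1, padding=pad)
        B, H, W, D, _ = y.shape
        out = y.reshape(-1, self.pointwise.shape[0]).matmul(self.pointwise)
        if self.bias is not None:
            out = out + self.bias
        return out.reshape(B, H, W, D, self.pointwise.shape[1])


class ChannelLayerNorm(Module):
    """Layer normalization across channels at every voxel."""

    def __init__(self, c: int, eps: float = 1e-5):
        self.eps = eps
        self.gain = parameter(np.ones(c))
        self.offset = parameter(np.zeros(c))

    def forward(self, x: Tensor) -> Tensor:
        return F.layer_norm(x, self.gain, self.offset, self.eps)


class AdamW:
    """Decoupled weight-decay Adam (the optimizer used for training)."""

    def __init__(self, params: list[Tensor], lr: float = 3e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            if self.weight_decay:
                p.data -= np.float32(self.lr * self.weight_decay) * p.data
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
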