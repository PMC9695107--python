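"""Neural-network building blocks on top of the autodiff tensor.

Conv2d uses an im2col view + tensordot forward with a hand-written backward;
everything else (batch norm, linear, activations) is composed from tensor
primitives so gradients come for free.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .tensor import Tensor

__all__ = [
    "Parameter",
    "Module",
    "ModuleList",
    "Sequential",
    "Conv2d",
    "Linear",
    "BatchNorm2d",
    "ReLU",
    "LeakyReLU",
    "Tanh",
    "Sigmoid",
    "conv2d",
    "upsample_nearest",
]


class Parameter(Tensor):
    """A tensor that is updated by an optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with parameter discovery, train/eval mode and state dicts."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- traversal ------------------------------------------------------------

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, child in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(child, Parameter):
                yield full, child
            elif isinstance(child, Module):
                yield from child.named_parameters(f"{full}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for child in vars(self).values():
            if isinstance(child, Module):
                yield from child.modules()

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, child in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(child, Module):
                yield from child.named_buffers(f"{full}.")
            elif isinstance(child, np.ndarray) and name.startswith("running_"):
                yield full, child

    # -- mode -----------------------------------------------------------------

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- (de)serialization -----------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for name, value in state.items():
            if name in params:
                params[name].data[...] = value
            elif name in buffers:
                buffers[name][...] = value
            else:
                raise KeyError(f"unknown state entry {name!r}")


class ModuleList(Module):
    def __init__(self, mods):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, str(i), m)
        self._n = len(mods)

    def __iter__(self):
        return (getattr(self, str(i)) for i in range(self._n))

    def __getitem__(self, i):
        return getattr(self, str(i))

    def named_parameters(self, prefix: str = ""):
        for i in range(self._n):
            yield from getattr(self, str(i)).named_parameters(f"{prefix}{i}.")

    def named_buffers(self, prefix: str = ""):
        for i in range(self._n):
            yield from getattr(self, str(i)).named_buffers(f"{prefix}{i}.")


class Sequential(ModuleList):
    def __init__(self, *mods):
        super().__init__(list(mods))

    def forward(self, x: Tensor) -> Tensor:
        for m in self:
            x = m(x)
        return x


# -- functional convolution ---------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """View of padded input as (N, C, k, k, Hout, Wout)."""
    n, c, h, w = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    sn, sc, sh, sw = x.strides
    return as_strided(
        x,
        shape=(n, c, k, k, ho, wo),
        strides=(sn, sc, sh, sw, sh * stride, sw * stride),
        writeable=False,
    )


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW input, OIkk weight."""
    k = weight.shape[2]
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    cols = _im2col(xp, k, stride)
    out_data = np.tensordot(weight.data, cols, axes=([1, 2, 3], [1, 2, 3]))
    out_data = out_data.transpose(1, 0, 2, 3)  # (N, O, Ho, Wo)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]
    parents = [x, weight] + ([bias] if bias is not None else [])

    def backward(g: np.ndarray) -> None:
        if weight.requires_grad:
            dw = np.tensordot(g, cols, axes=([0, 2, 3], [0, 4, 5]))
            weight._accum(dw)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            # scatter-add per kernel offset
            dcols = np.tensordot(weight.data, g, axes=([0], [1]))  # (C,k,k,N,Ho,Wo)
            ho, wo = g.shape[2], g.shape[3]
            for ki in range(k):
                for kj in range(k):
                    dxp[:, :,
                        ki:ki + ho * stride:stride,
                        kj:kj + wo * stride:stride] += dcols[:, ki, kj].transpose(1, 0, 2, 3)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)

    return Tensor._make(out_data, parents, backward)


def upsample_nearest(x: Tensor, scale: int) -> Tensor:
    """Nearest-neighbour upsampling of the trailing two axes."""
    out_data = x.data.repeat(scale, axis=-2).repeat(scale, axis=-1)

    def backward(g: np.ndarray) -> None:
        n, c, h, w = x.shape
        x._accum(g.reshape(n, c, h, scale, w, scale).sum(axis=(3, 5)))

    return Tensor._make(out_data, (x,), backward)


# -- layers --------------------------------------------------------------------

class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(
            0.0, std, (out_channels, in_channels, kernel_size, kernel_size)
        ).astype(np.float32))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / in_features)
        self.weight = Parameter(
            rng.normal(0.0, std, (out_features, in_features)).astype(np.float32))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight.transpose(1, 0) + self.bias


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) with running statistics for eval."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features, dtype=np.float32))
        self.beta = Parameter(np.zeros(num_features, dtype=np.float32))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mean) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            xhat = (x - mean) / (var + self.eps).sqrt()
        else:
            dt = x.data.dtype
            rm = self.running_mean[None, :, None, None].astype(dt)
            rv = self.running_var[None, :, None, None].astype(dt)
            xhat = (x - rm) * (1.0 / np.sqrt(rv + self.eps)).astype(dt)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()
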