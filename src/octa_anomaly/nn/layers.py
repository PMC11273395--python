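"""Layer/module abstractions over the autodiff primitives."""

from __future__ import annotations

from typing import Iterable, List

import numpy as np

from . import functional as F
from .tensor import Tensor


class Module:
    """Base class: tracks parameters, submodules and two runtime flags.

    ``dropout_active`` controls stochastic dropout; ``bn_batch_stats``
    controls whether batch-norm uses batch statistics (training) or running
    statistics (inference).  Keeping the two independent is what makes
    Monte-Carlo dropout possible: dropout on, batch statistics off.
    """

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        self.dropout_active = True
        self.bn_batch_stats = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> List[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def modules(self) -> Iterable["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def set_mode(self, dropout_active: bool, bn_batch_stats: bool) -> None:
        for m in self.modules():
            m.dropout_active = dropout_active
            m.bn_batch_stats = bn_batch_stats

    def train(self) -> None:
        self.set_mode(True, True)

    def eval(self) -> None:
        self.set_mode(False, False)

    def mc_mode(self) -> None:
        """Inference with live dropout: the Monte-Carlo sampling regime."""
        self.set_mode(True, False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        state = {}
        for i, p in enumerate(self.parameters()):
            state[f"p{i}"] = p.data
        bufs = [m for m in self.modules() if isinstance(m, BatchNorm2d)]
        for i, m in enumerate(bufs):
            state[f"bn{i}_mean"] = m.running_mean
            state[f"bn{i}_var"] = m.running_var
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = np.asarray(state[f"p{i}"])
        bufs = [m for m in self.modules() if isinstance(m, BatchNorm2d)]
        for i, m in enumerate(bufs):
            m.running_mean = np.asarray(state[f"bn{i}_mean"])
            m.running_var = np.asarray(state[f"bn{i}_var"])

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None,
                 bias: bool = True, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (in_ch * kernel * kernel))
        self.weight = Tensor(
            rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)).astype(dtype),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (in_ch * kernel * kernel))
        self.weight = Tensor(
            rng.normal(0.0, std, (in_ch, out_ch, kernel, kernel)).astype(dtype),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True)
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        super().__init__()
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.eps, self.momentum = eps, momentum

    def forward(self, x: Tensor) -> Tensor:
        C = x.shape[1]
        if self.bn_batch_stats:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mean) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean.data.reshape(C)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(C)
        else:
            mean = Tensor(self.running_mean.reshape(1, C, 1, 1))
            var = Tensor(self.running_var.reshape(1, C, 1, 1))
        xhat = (x - mean) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(1, C, 1, 1) + self.beta.reshape(1, C, 1, 1)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p, self.rng = p, rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.dropout_active or self.p <= 0:
            return x
        return F.dropout(x, self.p, self.rng)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class MaxPool2d(Module):
    def __init__(self, kernel: int = 2):
        super().__init__()
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        return F.max_pool2d(x, self.kernel)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
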