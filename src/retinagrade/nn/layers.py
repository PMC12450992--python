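"""Neural-network building blocks on top of the autodiff tensor.

Initialisation is fully deterministic: every layer draws its weights from a
``numpy.random.Generator`` supplied at construction, so rebuilding a model
from the same seed reproduces bit-identical parameters.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import Tensor, conv2d


class Module:
    """Base class with parameter traversal and train/eval mode."""

    _buffer_names: tuple[str, ...] = ()

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def modules(self) -> Iterator["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Tensor) and v.requires_grad:
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, "Module", str]]:
        """(full name, owning module, attribute name) of every non-trainable
        state array (e.g. batch-norm running statistics)."""
        for attr in self._buffer_names:
            yield f"{prefix}{attr}", self, attr
        for k, v in self.__dict__.items():
            if isinstance(v, Module):
                yield from v.named_buffers(f"{prefix}{k}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{prefix}{k}.{i}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        for name, owner, attr in self.named_buffers():
            state[name] = np.array(getattr(owner, attr), copy=True)
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {name: (owner, attr) for name, owner, attr in self.named_buffers()}
        if set(params) | set(buffers) != set(state):
            missing = (set(params) | set(buffers)) ^ set(state)
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, v in state.items():
            if k in params:
                params[k].data = np.asarray(v).copy()
            else:
                owner, attr = buffers[k]
                setattr(owner, attr, np.asarray(v).copy())


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, zero_init: bool = False):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        if zero_init:
            w = np.zeros((in_features, out_features))
        else:
            bound = np.sqrt(6.0 / (in_features + out_features))
            w = rng.uniform(-bound, bound, size=(in_features, out_features))
        self.weight = Tensor(w.astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0):
        super().__init__()
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        fan_out = out_channels * kernel_size * kernel_size
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        w = rng.uniform(-bound, bound,
                        size=(out_channels, in_channels, kernel_size, kernel_size))
        self.weight = Tensor(w.astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    """Per-channel batch normalisation over (B, H, W); running stats in eval."""

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(num_features, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(-1))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(-1))
            xhat = centered * ((var + self.eps) ** -0.5)
        else:
            mu = self.running_mean[None, :, None, None].astype(np.float32)
            sd = np.sqrt(self.running_var + self.eps)[None, :, None, None].astype(np.float32)
            xhat = (x - Tensor(mu)) * Tensor(1.0 / sd)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class LayerNorm(Module):
    """Normalisation over the last axis (token feature dimension)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(dim, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        xhat = centered * ((var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
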