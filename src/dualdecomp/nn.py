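"""Neural-network layers and the Adam optimizer, built on `dualdecomp.autodiff`.

Layer parameters are `Tensor`s with ``requires_grad=True``; modules track
them in declaration order so parameter vectors, checkpoints and optimizer
state are deterministic.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

DTYPE = np.float32


class Module:
    """Base class: recursive parameter/buffer discovery, train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, key, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[key] = value
        object.__setattr__(self, key, value)

    def register_parameter(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(np.asarray(value, dtype=DTYPE), requires_grad=True, name=name)
        self._params[name] = t
        object.__setattr__(self, name, t)
        return t

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        arr = np.asarray(value, dtype=DTYPE)
        self._buffers[name] = arr
        object.__setattr__(self, name, arr)
        return arr

    def named_parameters(self, prefix: str = ""):
        for n, p in self._params.items():
            yield prefix + n, p
        for mn, m in self._modules.items():
            yield from m.named_parameters(prefix + mn + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for n, b in self._buffers.items():
            yield prefix + n, b
        for mn, m in self._modules.items():
            yield from m.named_buffers(prefix + mn + ".")

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # flat state for checkpoints
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {("param." + n): p.data.copy() for n, p in self.named_parameters()}
        state.update({("buffer." + n): b.copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, arr in state.items():
            kind, name = key.split(".", 1)
            if kind == "param":
                if params[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for parameter {name}")
                params[name].data = arr.astype(DTYPE).copy()
            elif kind == "buffer":
                buffers[name][...] = arr
            else:  # pragma: no cover
                raise ValueError(f"unknown state key {key}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _conv_init(rng: np.random.Generator, shape, std: float = 0.02):
    # normal(0, 0.02) init, the conventional choice for conditional GANs
    return rng.normal(0.0, std, size=shape)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.stride, self.pad = stride, pad
        self.register_parameter("weight", _conv_init(rng, (cout, cin, k, k)))
        self.bias = None
        if bias:
            self.register_parameter("bias", np.zeros(cout))

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, self.stride, self.pad)


class ConvTranspose2d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.stride, self.pad = stride, pad
        self.register_parameter("weight", _conv_init(rng, (cin, cout, k, k)))
        self.bias = None
        if bias:
            self.register_parameter("bias", np.zeros(cout))

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv_transpose2d(x, self.weight, self.bias, self.stride, self.pad)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.register_parameter("gamma", np.ones(c))
        self.register_parameter("beta", np.zeros(c))
        self.register_buffer("running_mean", np.zeros(c))
        self.register_buffer("running_var", np.ones(c))

    def forward(self, x: Tensor) -> Tensor:
        return ad.batchnorm2d(x, self.gamma, self.beta,
                              self.running_mean, self.running_var,
                              self.training, self.momentum, self.eps)


class Adam:
    """Adam with external per-step learning rate (the LR schedule drives it)."""

    def __init__(self, params: list[Tensor], betas=(0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t,
                "m": [a.copy() for a in self.m],
                "v": [a.copy() for a in self.v]}

    def load_state_dict(self, state: dict):
        self.t = int(state["t"])
        for dst, src in zip(self.m, state["m"]):
            dst[...] = src
        for dst, src in zip(self.v, state["v"]):
            dst[...] = src
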