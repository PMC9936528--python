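"""Minimal layer and optimizer abstractions over :mod:`pacdet.autodiff`.

A :class:`Module` owns named parameters (leaf :class:`Tensor` objects with
``requires_grad=True``) and child modules; :meth:`Module.parameters` walks the
tree.  Initialization is fully determined by the ``numpy.random.Generator``
passed at construction, which is how the package delivers seed-reproducible
models.
"""

from __future__ import annotations

import pickle
from pathlib import Path

import numpy as np

from .autodiff import Tensor

__all__ = ["Module", "Conv2d", "Linear", "SGD", "save_checkpoint", "load_checkpoint"]


class Module:
    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        seen: set[int] = set()
        out: list[Tensor] = []
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                out.append(p)
        return out

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield (prefix + name, p)
        for cname, child in self._children.items():
            yield from child.named_parameters(prefix + cname + ".")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr


class Conv2d(Module):
    """2D convolution with He-normal init; 1x1 convolutions double as the
    per-pixel linear transforms used by the attention blocks."""

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 init: str = "he"):
        super().__init__()
        self.stride = stride
        self.padding = padding
        fan_in = cin * kernel * kernel
        if init == "he":
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, kernel, kernel))
        elif init == "zero":
            w = np.zeros((cout, cin, kernel, kernel))
        elif init == "identity":
            if cin != cout or kernel != 1:
                raise ValueError("identity init needs cin == cout and kernel 1")
            w = np.eye(cout).reshape(cout, cin, 1, 1)
        else:
            raise ValueError(f"unknown init {init!r}")
        self.weight = Tensor(w.astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / nin), size=(nin, nout))
        self.weight = Tensor(w.astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(nout, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class SGD:
    """Plain SGD with momentum; the learning rate is mutable so training
    schedules can decay it in place."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0, clip_norm: float | None = None):
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self.clip_norm = clip_norm
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        if self.clip_norm is not None:
            total = np.sqrt(sum(float(np.sum(p.grad ** 2)) for p in self.params
                                if p.grad is not None))
            if total > self.clip_norm:
                factor = self.clip_norm / (total + 1e-12)
                for p in self.params:
                    if p.grad is not None:
                        p.grad *= factor
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def save_checkpoint(path, model: Module, meta: dict | None = None) -> None:
    payload = {"state": model.state_dict(), "meta": meta or {}}
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_checkpoint(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with open(path, "rb") as fh:
        return pickle.load(fh)
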