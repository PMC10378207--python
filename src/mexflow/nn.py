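"""Layer and optimiser primitives on top of the autodiff engine."""

from __future__ import annotations

from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from .autodiff import Tensor

__all__ = ["Module", "Conv2d", "Linear", "Adam"]


class Module:
    """Minimal container with recursive parameter discovery.

    Layers register :class:`Tensor` parameters as attributes; submodules are
    found by attribute walk. ``train()``/``eval()`` toggle a flag for parity
    with the usual deep-learning API (no layer here behaves differently, but
    callers rely on the flag to gate data augmentation).
    """

    def __init__(self) -> None:
        self.training = True

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Tensor]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Tensor):
                        yield f"{full}.{i}", item

    def parameters(self) -> List[Tensor]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def _submodules(self) -> Iterator["Module"]:
        for v in vars(self).values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def train(self) -> "Module":
        self.training = True
        for m in self._submodules():
            m.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for m in self._submodules():
            m.eval()
        return self

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={missing}, extra={extra}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    """Stride-1 convolution with 'same' zero padding by default."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, same: bool = True,
                 relu: bool = False):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(_he_normal(rng, (out_ch, in_ch, kernel, kernel), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)
        self.padding = kernel // 2 if same else 0
        self.relu = relu

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, padding=self.padding,
                        relu=self.relu)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(_he_normal(rng, (in_features, out_features), in_features),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32),
                           requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class Adam:
    """Adam with L2 weight decay added to the gradient (classic style)."""

    def __init__(self, params: List[Tensor], lr: float = 1e-4,
                 betas: Tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
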