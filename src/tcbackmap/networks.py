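"""Dense building blocks and the Adam optimizer for the autodiff engine."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad

__all__ = ["Linear", "ResidualBlock", "MLP", "Adam", "Module"]


class Module:
    """Base class: parameter registry and (de)serialization to flat dicts."""

    def parameters(self) -> list:
        params = []
        for value in self.__dict__.values():
            if isinstance(value, ad.Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_arrays(self) -> list:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch in checkpoint")
        for p, a in zip(params, arrays):
            a = np.asarray(a, dtype=p.data.dtype)
            if a.shape != p.data.shape:
                raise ValueError("parameter shape mismatch in checkpoint")
            p.data = a.copy()


class Linear(Module):
    """Affine map with He-scaled Gaussian initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, scale: float | None = None):
        std = scale if scale is not None else np.sqrt(2.0 / n_in)
        self.W = ad.Tensor(rng.normal(0.0, std, size=(n_in, n_out)), requires_grad=True)
        self.b = ad.Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: ad.Tensor) -> ad.Tensor:
        return x @ self.W + self.b


class ResidualBlock(Module):
    """x + W2 tanh(W1 x): a smooth residual unit of constant width."""

    def __init__(self, width: int, rng: np.random.Generator):
        self.fc1 = Linear(width, width, rng)
        # small-initialized second layer keeps the block near-identity at start
        self.fc2 = Linear(width, width, rng, scale=0.1 / np.sqrt(width))

    def __call__(self, x: ad.Tensor) -> ad.Tensor:
        return x + self.fc2(ad.tanh(self.fc1(x)))


class MLP(Module):
    """Input projection, ``n_blocks`` residual units, linear head."""

    def __init__(self, n_in: int, width: int, n_out: int, n_blocks: int, rng: np.random.Generator):
        self.inp = Linear(n_in, width, rng)
        self.blocks = [ResidualBlock(width, rng) for _ in range(n_blocks)]
        self.out = Linear(width, n_out, rng)

    def hidden(self, x: ad.Tensor) -> ad.Tensor:
        h = ad.tanh(self.inp(x))
        for block in self.blocks:
            h = block(h)
        return h

    def __call__(self, x: ad.Tensor) -> ad.Tensor:
        return self.out(self.hidden(x))


class Adam:
    """Adaptive-moment gradient descent."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        # effective step size with bias correction folded in
        alpha = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            m, v = self.m[i], self.v[i]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            denom = np.sqrt(v)
            denom += self.eps
            p.data -= alpha * m / denom
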