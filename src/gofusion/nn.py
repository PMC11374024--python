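"""Minimal numpy neural-network primitives with explicit backward passes.

Everything here is deliberately small and CPU-oriented: dense linear
layers, 1-d batch normalization, the exact (erf-based) GELU, and an Adam
optimizer.  Layers cache what their backward pass needs during
``forward`` and return input gradients from ``backward``; parameter
gradients accumulate into ``Param.grad`` until ``zero_grad``.

Gradient correctness is established by finite-difference checks in the
test suite rather than by an autodiff engine.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape


def gelu(x: np.ndarray) -> np.ndarray:
    """Gaussian Error Linear Unit, exact form x * Phi(x)."""
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + erf(x / _SQRT2)) + x * _INV_SQRT_2PI * np.exp(-0.5 * x * x)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    shifted = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


class Linear:
    """y = x W + b with Kaiming-normal initialization."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, name: str = "linear") -> None:
        scale = np.sqrt(2.0 / d_in)
        self.W = Param(rng.normal(0.0, scale, size=(d_in, d_out)), f"{name}.W")
        self.b = Param(np.zeros(d_out), f"{name}.b")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[-1] != self.W.shape[0]:
            raise ValueError(
                f"dimension mismatch: input has {x.shape[-1]} features, layer expects {self.W.shape[0]}"
            )
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class BatchNorm1d:
    """Batch normalization over the batch axis.

    Running statistics are used in eval mode, and also in train mode for
    batches of size 1, where batch statistics would be degenerate.
    """

    def __init__(self, d: int, momentum: float = 0.1, eps: float = 1e-5, name: str = "bn") -> None:
        self.gamma = Param(np.ones(d), f"{name}.gamma")
        self.beta = Param(np.zeros(d), f"{name}.beta")
        self.running_mean = np.zeros(d)
        self.running_var = np.ones(d)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        use_batch_stats = train and x.shape[0] > 1
        if use_batch_stats:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std, use_batch_stats)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, use_batch_stats = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=0)
        self.beta.grad += dy.sum(axis=0)
        dxhat = dy * self.gamma.value
        if not use_batch_stats:
            return dxhat * inv_std
        n = dy.shape[0]
        return (inv_std / n) * (
            n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )


class GELU:
    def __init__(self) -> None:
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return gelu(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * gelu_grad(self._x)


class MLPBlock:
    """linear -> batch norm -> GELU, with an optional identity skip.

    The skip connection adds the block input to its output and therefore
    requires matching input/output widths; when the widths differ the
    skip is omitted.  ``use_norm=False`` drops the normalization layer.
    """

    def __init__(
        self,
        d_in: int,
        d_out: int,
        rng: np.random.Generator,
        skip: bool = True,
        use_norm: bool = True,
        name: str = "block",
    ) -> None:
        self.linear = Linear(d_in, d_out, rng, name=f"{name}.linear")
        self.norm = BatchNorm1d(d_out, name=f"{name}.norm") if use_norm else None
        self.act = GELU()
        self.skip = skip and d_in == d_out

    def params(self) -> list[Param]:
        ps = self.linear.params()
        if self.norm is not None:
            ps += self.norm.params()
        return ps

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.linear.forward(x, train)
        if self.norm is not None:
            h = self.norm.forward(h, train)
        h = self.act.forward(h, train)
        return h + x if self.skip else h

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.act.backward(dy)
        if self.norm is not None:
            dh = self.norm.backward(dh)
        dx = self.linear.backward(dh)
        return dx + dy if self.skip else dx


class Adam:
    """Adam optimizer over an explicit parameter list."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad * p.grad
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def state_dict(params: list[Param]) -> dict[str, np.ndarray]:
    return {p.name or f"param_{i}": p.value.copy() for i, p in enumerate(params)}


def load_state(params: list[Param], state: dict[str, np.ndarray]) -> None:
    for i, p in enumerate(params):
        key = p.name or f"param_{i}"
        p.value[...] = state[key]
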