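"""Minimal dense neural-network primitives used by the masked autoencoder.

The networks here are shallow (one or two linear maps each way), so forward
and backward passes are written out analytically on float64 numpy arrays.
Sparsity is enforced with a binary mask on the weight matrix: masked entries
are pinned at exactly 0 — gradients are masked before the optimizer update
and the weights re-masked after it, so the invariant holds bit-exactly at
every step.
"""

from __future__ import annotations

import numpy as np

ACTIVATIONS = ("tanh", "relu", "linear")


def act_forward(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "tanh":
        return np.tanh(z)
    if kind == "relu":
        return np.maximum(z, 0.0)
    if kind == "linear":
        return z
    raise ValueError(f"unknown activation {kind!r}")


def act_backward(z: np.ndarray, kind: str) -> np.ndarray:
    """d activation / d z evaluated at pre-activation z."""
    if kind == "tanh":
        t = np.tanh(z)
        return 1.0 - t * t
    if kind == "relu":
        return (z > 0).astype(z.dtype)
    if kind == "linear":
        return np.ones_like(z)
    raise ValueError(f"unknown activation {kind!r}")


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense:
    """Linear layer ``out = act(x @ (W * mask) + b)`` with optional mask/bias.

    For masked layers the effective fan-in of each output unit is the number
    of unmasked inputs, which is what the initializer uses.
    """

    def __init__(
        self,
        n_in: int,
        n_out: int,
        *,
        mask: np.ndarray | None = None,
        bias: bool = True,
        activation: str = "linear",
        rng: np.random.Generator | None = None,
    ) -> None:
        if activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        self.mask = None if mask is None else np.asarray(mask, dtype=np.float64)
        if self.mask is not None and self.mask.shape != (n_in, n_out):
            raise ValueError(f"mask shape {self.mask.shape} != ({n_in}, {n_out})")
        self.activation = activation
        rng = rng or np.random.default_rng(0)
        if self.mask is None:
            self.W = glorot_uniform(rng, n_in, n_out, (n_in, n_out))
        else:
            # per-column fan-in = number of member genes of the set
            fan_in = np.maximum(self.mask.sum(axis=0), 1.0)
            limit = np.sqrt(6.0 / (fan_in + 1.0))  # each unit reconstructs via one path
            self.W = rng.uniform(-1.0, 1.0, size=(n_in, n_out)) * limit[None, :]
            self.W *= self.mask
        self.b = np.zeros(n_out) if bias else None
        self._x: np.ndarray | None = None
        self._z: np.ndarray | None = None

    @property
    def weight(self) -> np.ndarray:
        return self.W if self.mask is None else self.W * self.mask

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        z = x @ self.weight
        if self.b is not None:
            z = z + self.b
        if cache:
            self._x, self._z = x, z
        return act_forward(z, self.activation)

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
        """Given dL/d(output), return (dL/dx, dL/dW, dL/db)."""
        dz = dout * act_backward(self._z, self.activation)
        dW = self._x.T @ dz
        if self.mask is not None:
            dW *= self.mask
        db = dz.sum(axis=0) if self.b is not None else None
        dx = dz @ self.weight.T
        return dx, dW, db

    def params(self) -> list[np.ndarray]:
        return [self.W] if self.b is None else [self.W, self.b]

    def apply_mask(self) -> None:
        if self.mask is not None:
            self.W *= self.mask


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
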