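"""Minimal feed-forward network kernel with exact manual backpropagation.

Float64 end to end, fully deterministic given a seeded ``numpy.random.Generator``:
two runs from the same seed produce bitwise-identical parameters, activations and
gradients.  That determinism is what makes mask equality and the FedAvg-equivalence
checks meaningful, so it is a design constraint here, not an optimisation detail.

Layers expose ``params`` / ``grads`` dictionaries (insertion order is the canonical
parameter order) and declare which parameter tensors are prunable: weight matrices
of dense and convolutional layers are, biases and normalisation parameters are not.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Dense",
    "Conv",
    "ReLU",
    "MaxPool",
    "GlobalAvgPool",
    "Flatten",
    "LayerNorm",
    "Sequential",
    "softmax",
    "cross_entropy_with_grad",
]


class Layer:
    """Base layer: holds parameter and gradient dicts keyed by tensor name."""

    #: parameter names that count as prunable connections
    prunable: frozenset = frozenset()

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    """Fully connected layer, y = x @ W + b, He-normal init."""

    prunable = frozenset({"W"})

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.n_in, self.n_out = int(n_in), int(n_out)
        scale = np.sqrt(2.0 / self.n_in)
        self.params["W"] = rng.normal(0.0, scale, size=(self.n_in, self.n_out))
        self.params["b"] = np.zeros(self.n_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class Conv(Layer):
    """N-dimensional convolution (2-D or 3-D spatial), stride 1, symmetric padding.

    Input layout is channels-first: ``(N, C, *spatial)``.  The forward pass uses a
    sliding-window view plus einsum; the input gradient is accumulated per kernel
    offset, which is exact and memory-light at desk scale.
    """

    prunable = frozenset({"W"})

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        ndim: int,
        rng: np.random.Generator,
        pad: int | None = None,
    ) -> None:
        super().__init__()
        self.c_in, self.c_out = int(c_in), int(c_out)
        self.k = int(kernel)
        self.ndim = int(ndim)
        if self.ndim not in (2, 3):
            raise ValueError("Conv supports 2 or 3 spatial dimensions")
        self.pad = (self.k // 2) if pad is None else int(pad)
        fan_in = self.c_in * self.k**self.ndim
        shape = (self.c_out, self.c_in) + (self.k,) * self.ndim
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
        self.params["b"] = np.zeros(self.c_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        p, nd = self.pad, self.ndim
        pad_width = [(0, 0), (0, 0)] + [(p, p)] * nd
        xp = np.pad(x, pad_width)
        self._xp_shape = xp.shape
        axes = tuple(range(2, 2 + nd))
        cols = sliding_window_view(xp, (self.k,) * nd, axis=axes)
        # (N, C, *out, *k) -> (N*prod(out), C*k^nd) so the contraction is a GEMM
        out_sp = cols.shape[2 : 2 + nd]
        cols = np.moveaxis(cols, 1, 1 + nd)  # (N, *out, C, *k)
        cols2 = np.ascontiguousarray(cols).reshape(-1, self.c_in * self.k**nd)
        self._cols2 = cols2
        self._out_sp = out_sp
        wmat = self.params["W"].reshape(self.c_out, -1)
        y = cols2 @ wmat.T + self.params["b"]
        y = y.reshape((len(x),) + out_sp + (self.c_out,))
        return np.moveaxis(y, -1, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        nd = self.ndim
        W = self.params["W"]
        dy2 = np.moveaxis(dy, 1, -1).reshape(-1, self.c_out)  # (N*prod(out), F)
        self.grads["W"] = (dy2.T @ self._cols2).reshape(W.shape)
        self.grads["b"] = dy2.sum(axis=0)
        dxp = np.zeros(self._xp_shape)
        out_sp = dy.shape[2:]
        for off in np.ndindex(*(self.k,) * nd):
            sl = (slice(None), slice(None)) + tuple(
                slice(o, o + s) for o, s in zip(off, out_sp)
            )
            woff = W[(slice(None), slice(None)) + off]  # (F, C)
            # (N, *out, C) <- (N, F, *out) x (F, C)
            contrib = np.tensordot(dy, woff, axes=(1, 0))
            dxp[sl] += np.moveaxis(contrib, -1, 1)
        p = self.pad
        crop = (slice(None), slice(None)) + (slice(p, -p) if p else slice(None),) * nd
        return dxp[crop]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class MaxPool(Layer):
    """Non-overlapping max pooling with window = stride = ``size`` on every spatial axis."""

    def __init__(self, size: int, ndim: int) -> None:
        super().__init__()
        self.size, self.ndim = int(size), int(ndim)

    def forward(self, x: np.ndarray) -> np.ndarray:
        p, nd = self.size, self.ndim
        spatial = x.shape[2:]
        if any(s % p for s in spatial):
            raise ValueError(f"spatial dims {spatial} not divisible by pool size {p}")
        self._in_shape = x.shape
        shape = x.shape[:2] + tuple(v for s in spatial for v in (s // p, p))
        xr = x.reshape(shape)
        pool_axes = tuple(range(3, 3 + 2 * nd, 2))
        xm = np.moveaxis(xr, pool_axes, range(-nd, 0))
        out_sp = tuple(s // p for s in spatial)
        flat = xm.reshape(x.shape[:2] + out_sp + (p**nd,))
        self._argmax = flat.argmax(axis=-1)
        return np.take_along_axis(flat, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        p, nd = self.size, self.ndim
        spatial = self._in_shape[2:]
        out_sp = tuple(s // p for s in spatial)
        flat = np.zeros(self._in_shape[:2] + out_sp + (p**nd,))
        np.put_along_axis(flat, self._argmax[..., None], dy[..., None], axis=-1)
        xm = flat.reshape(self._in_shape[:2] + out_sp + (p,) * nd)
        xr = np.moveaxis(xm, range(-nd, 0), tuple(range(3, 3 + 2 * nd, 2)))
        return xr.reshape(self._in_shape)


class GlobalAvgPool(Layer):
    """Average over all spatial axes; output (N, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=tuple(range(2, x.ndim)))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        sp = self._in_shape[2:]
        scale = 1.0 / float(np.prod(sp))
        return np.broadcast_to(
            dy.reshape(dy.shape + (1,) * len(sp)) * scale, self._in_shape
        ).copy()


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._in_shape)


class LayerNorm(Layer):
    """Per-sample normalisation over the feature axis with learnable scale/shift.

    The scale (``gamma``) and shift (``beta``) tensors are normalisation parameters
    and therefore not prunable.
    """

    def __init__(self, n: int, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.params["gamma"] = np.ones(n)
        self.params["beta"] = np.zeros(n)

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.grads["gamma"] = (dy * xhat).sum(axis=0)
        self.grads["beta"] = dy.sum(axis=0)
        n = xhat.shape[-1]
        dxhat = dy * self.params["gamma"]
        return inv / n * (
            n * dxhat
            - dxhat.sum(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True)
        )


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_with_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient with respect to the logits."""
    n = logits.shape[0]
    z = logits - logits.max(axis=-1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    loss = -logp[np.arange(n), y].mean()
    dlogits = softmax(logits)
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), dlogits / n


class Sequential:
    """Plain layer stack with cross-entropy training head."""

    def __init__(self, layers: list[Layer], input_shape: tuple[int, ...]) -> None:
        self.layers = layers
        self.input_shape = tuple(input_shape)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.shape[1:] != self.input_shape:
            x = x.reshape((x.shape[0],) + self.input_shape)
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def loss_and_backward(self, x: np.ndarray, y: np.ndarray) -> float:
        """One forward/backward pass; leaves per-tensor gradients in each layer."""
        logits = self.forward(x)
        loss, dlogits = cross_entropy_with_grad(logits, np.asarray(y))
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return loss

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x).argmax(axis=-1)
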