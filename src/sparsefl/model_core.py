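"""Flat-parameter abstraction, binary masks, and the architecture registry.

Every federated operation in this package works on one currency: a flat float64
vector over all model parameters plus a :class:`ParamLayout` that remembers where
each tensor lives and whether it is prunable.  Prunable positions are the weight
matrices of dense and convolutional layers; biases and normalisation parameters
stay dense, which is the standard convention for saliency pruning and keeps tiny
models trainable at extreme sparsity.

Sparsity accounting: the reported sparsity fraction refers to the prunable set P,
``keep = round((1 - sparsity) * |P|)`` with round-half-away-from-zero; the whole
model density (including dense tensors) is available via :meth:`Mask.density`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "LayoutEntry",
    "ParamLayout",
    "ParamVector",
    "Mask",
    "keep_count",
    "flatten",
    "unflatten",
    "set_model_params",
    "flat_gradients",
    "apply_mask",
    "full_mask",
    "mask_from_prunable_bits",
    "build_model",
    "ARCHITECTURES",
]


@dataclass(frozen=True)
class LayoutEntry:
    name: str
    shape: tuple[int, ...]
    offset: int
    prunable: bool

    @property
    def size(self) -> int:
        return int(np.prod(self.shape)) if self.shape else 1


@dataclass(frozen=True)
class ParamLayout:
    """Ordered tensor layout of a flattened model."""

    entries: tuple[LayoutEntry, ...]

    def __post_init__(self) -> None:
        off = 0
        for e in self.entries:
            if e.offset != off:
                raise ValueError(f"non-contiguous layout at {e.name}")
            off += e.size

    @property
    def size(self) -> int:
        return sum(e.size for e in self.entries)

    @property
    def prunable_mask(self) -> np.ndarray:
        """Boolean vector, True on the prunable index set P."""
        m = np.zeros(self.size, dtype=bool)
        for e in self.entries:
            if e.prunable:
                m[e.offset : e.offset + e.size] = True
        return m

    @property
    def n_prunable(self) -> int:
        return int(self.prunable_mask.sum())

    def hash(self) -> str:
        payload = json.dumps(
            [[e.name, list(e.shape), e.offset, e.prunable] for e in self.entries]
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def tensor_of(self, index: int) -> str:
        """Name of the tensor containing a flat index (error reporting)."""
        for e in self.entries:
            if e.offset <= index < e.offset + e.size:
                return e.name
        raise IndexError(index)


@dataclass
class ParamVector:
    """Flat float64 view of all model parameters with its layout."""

    values: np.ndarray
    layout: ParamLayout

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.layout.size,):
            raise ValueError(
                f"values length {self.values.shape} != layout size {self.layout.size}"
            )

    def copy(self) -> "ParamVector":
        return ParamVector(self.values.copy(), self.layout)

    def __len__(self) -> int:
        return self.layout.size


@dataclass
class Mask:
    """Binary keep/drop vector over all d positions.

    Bits are 1 at every non-prunable position; among prunable positions exactly
    ``keep_count(sparsity, |P|)`` bits are 1.
    """

    bits: np.ndarray
    sparsity: float
    layout_hash: str = ""

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("mask bits must be 0 or 1")
        if not 0.0 <= self.sparsity < 1.0:
            raise ValueError("sparsity must lie in [0, 1)")

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.bits)

    @property
    def n_kept(self) -> int:
        return int(self.bits.sum())

    def density(self) -> float:
        """Whole-model density including non-prunable tensors."""
        return self.n_kept / self.bits.size


def keep_count(sparsity: float, n_prunable: int) -> int:
    """Number of prunable positions kept: round-half-away-from-zero of (1-s)|P|."""
    if not 0.0 <= sparsity < 1.0:
        raise ValueError("sparsity must lie in [0, 1)")
    x = (1.0 - sparsity) * n_prunable
    return int(np.floor(x + 0.5))


def _named_tensors(model: nn.Sequential):
    for i, layer in enumerate(model.layers):
        for pname, tensor in layer.params.items():
            yield f"{i:02d}_{type(layer).__name__}.{pname}", layer, pname, tensor


def layout_of(model: nn.Sequential) -> ParamLayout:
    entries, off = [], 0
    for name, layer, pname, tensor in _named_tensors(model):
        entries.append(
            LayoutEntry(name, tuple(tensor.shape), off, pname in layer.prunable)
        )
        off += tensor.size
    return ParamLayout(tuple(entries))


def flatten(model: nn.Sequential) -> ParamVector:
    """Flatten model parameters in deterministic layer-registration order."""
    layout = layout_of(model)
    values = np.empty(layout.size)
    for e, (_, _, _, tensor) in zip(layout.entries, _named_tensors(model)):
        if not np.isfinite(tensor).all():
            raise ValueError(f"non-finite parameters in tensor {e.name}")
        values[e.offset : e.offset + e.size] = tensor.ravel()
    return ParamVector(values, layout)


def set_model_params(model: nn.Sequential, params: ParamVector) -> None:
    """Write a flat vector back into the model tensors (inverse of flatten)."""
    for e, (_, layer, pname, tensor) in zip(
        params.layout.entries, _named_tensors(model)
    ):
        if tuple(tensor.shape) != e.shape:
            raise ValueError(f"layout mismatch at {e.name}")
        layer.params[pname] = params.values[e.offset : e.offset + e.size].reshape(e.shape)


def unflatten(params: ParamVector, model: nn.Sequential) -> nn.Sequential:
    set_model_params(model, params)
    return model


def flat_gradients(model: nn.Sequential, layout: ParamLayout) -> np.ndarray:
    """Collect per-tensor gradients into a flat vector aligned with ``layout``."""
    g = np.empty(layout.size)
    for e, (_, layer, pname, _) in zip(layout.entries, _named_tensors(model)):
        grad = layer.grads.get(pname)
        if grad is None:
            raise ValueError(f"no gradient available for tensor {e.name}")
        if not np.isfinite(grad).all():
            raise ValueError(f"non-finite gradient in tensor {e.name}")
        g[e.offset : e.offset + e.size] = grad.ravel()
    return g


def apply_mask(params: ParamVector, mask: Mask) -> ParamVector:
    """Elementwise product; positions with bit 0 become exactly 0.0."""
    if mask.bits.size != len(params):
        raise ValueError(
            f"mask length {mask.bits.size} != parameter length {len(params)}"
        )
    return ParamVector(params.values * mask.bits, params.layout)


def full_mask(layout: ParamLayout) -> Mask:
    """All-ones (dense) mask — the 0% sparsity case."""
    return Mask(np.ones(layout.size, dtype=np.uint8), 0.0, layout.hash())


def mask_from_prunable_bits(
    prunable_bits: np.ndarray, sparsity: float, layout: ParamLayout
) -> Mask:
    """Lift a {0,1} vector over P to a full-length mask (ones off P)."""
    pm = layout.prunable_mask
    bits = np.ones(layout.size, dtype=np.uint8)
    bits[pm] = np.asarray(prunable_bits, dtype=np.uint8)
    return Mask(bits, sparsity, layout.hash())


# --------------------------------------------------------------------------
# architecture registry
# --------------------------------------------------------------------------

ALEXNET3D_CHANNELS = (64, 128, 192, 192, 128)


def _build_tiny_mlp(input_shape, n_classes, rng, hidden=16, norm=False):
    n_in = int(np.prod(input_shape))
    layers = [nn.Flatten(), nn.Dense(n_in, hidden, rng), nn.ReLU()]
    if norm:
        layers.append(nn.LayerNorm(hidden))
    layers.append(nn.Dense(hidden, n_classes, rng))
    return nn.Sequential(layers, tuple(input_shape))


def _build_small_cnn_2d(input_shape, n_classes, rng, channels=(8, 16)):
    if len(input_shape) == 2:
        input_shape = (1,) + tuple(input_shape)
    c, h, w = input_shape
    if h % 4 or w % 4:
        raise ValueError("small-cnn-2d needs spatial dims divisible by 4")
    c1, c2 = channels
    layers = [
        nn.Conv(c, c1, 3, ndim=2, rng=rng),
        nn.ReLU(),
        nn.MaxPool(2, ndim=2),
        nn.Conv(c1, c2, 3, ndim=2, rng=rng),
        nn.ReLU(),
        nn.MaxPool(2, ndim=2),
        nn.Flatten(),
        nn.Dense(c2 * (h // 4) * (w // 4), n_classes, rng),
    ]
    return nn.Sequential(layers, tuple(input_shape))


def _build_alexnet3d(input_shape, n_classes, rng):
    # 3-D AlexNet variant: conv channels 64C-128C-192C-192C-128C, 3^3 kernels,
    # three 2^3 max-pools, global average pool head.
    if len(input_shape) == 3:
        input_shape = (1,) + tuple(input_shape)
    c = input_shape[0]
    if any(s % 8 for s in input_shape[1:]):
        raise ValueError("alexnet3d needs spatial dims divisible by 8")
    ch = ALEXNET3D_CHANNELS
    layers = [
        nn.Conv(c, ch[0], 3, ndim=3, rng=rng),
        nn.ReLU(),
        nn.MaxPool(2, ndim=3),
        nn.Conv(ch[0], ch[1], 3, ndim=3, rng=rng),
        nn.ReLU(),
        nn.MaxPool(2, ndim=3),
        nn.Conv(ch[1], ch[2], 3, ndim=3, rng=rng),
        nn.ReLU(),
        nn.Conv(ch[2], ch[3], 3, ndim=3, rng=rng),
        nn.ReLU(),
        nn.Conv(ch[3], ch[4], 3, ndim=3, rng=rng),
        nn.ReLU(),
        nn.MaxPool(2, ndim=3),
        nn.GlobalAvgPool(),
        nn.Dense(ch[4], n_classes, rng),
    ]
    return nn.Sequential(layers, tuple(input_shape))


ARCHITECTURES = {
    "tiny-mlp": _build_tiny_mlp,
    "small-cnn-2d": _build_small_cnn_2d,
    "alexnet3d": _build_alexnet3d,
}


def build_model(
    name: str,
    input_shape: int | tuple[int, ...],
    n_classes: int = 2,
    seed: int = 0,
    **kwargs,
) -> nn.Sequential:
    """Build a freshly initialised registry model; same seed, same parameters."""
    if name not in ARCHITECTURES:
        raise ValueError(
            f"unknown architecture {name!r}; registry: {sorted(ARCHITECTURES)}"
        )
    if isinstance(input_shape, int):
        input_shape = (input_shape,)
    rng = np.random.default_rng(seed)
    return ARCHITECTURES[name](tuple(input_shape), int(n_classes), rng, **kwargs)
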