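"""Connection-saliency scoring and global mask construction.

The importance of connection i at parameters θ is the magnitude of the loss
sensitivity to removing it, s_i = |θ_i · ∂L/∂θ_i| — evaluated at the common
initialisation, before any training.  Keeping the top-q scores yields a
single-shot pruning mask; the iterative variant re-scores along a decreasing
keep-count schedule without ever re-activating a pruned position; and the
federated protocol sums (or n_k-weights) the per-client score vectors once,
so all clients train the same sub-network from the same initialisation.

Tie-breaking at the keep-count boundary is by lowest flat index, which is
deterministic and stable across processes given the canonical layout order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .comms import TrafficLedger
from .model_core import (
    Mask,
    ParamLayout,
    ParamVector,
    flat_gradients,
    flatten,
    keep_count,
    layout_of,
    mask_from_prunable_bits,
    set_model_params,
)

__all__ = [
    "SaliencyScores",
    "PruneSchedule",
    "make_prune_schedule",
    "connection_saliency",
    "topq_mask",
    "aggregate_scores",
    "iterative_mask",
    "global_mask_protocol",
]


@dataclass
class SaliencyScores:
    """Nonnegative per-connection importance over the prunable positions P."""

    values: np.ndarray
    client_id: int | str = 0
    n_samples_used: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.isfinite(self.values).all():
            raise ValueError("saliency scores must be finite")
        if (self.values < 0).any():
            raise ValueError("saliency scores are magnitudes and must be >= 0")


@dataclass
class PruneSchedule:
    """Strictly decreasing keep counts q_1 > ... > q_T = target."""

    steps: tuple[int, ...]
    kind: str = "exponential"

    def __post_init__(self) -> None:
        self.steps = tuple(int(q) for q in self.steps)
        if not self.steps:
            raise ValueError("schedule must contain at least one step")
        if any(a <= b for a, b in zip(self.steps, self.steps[1:])):
            raise ValueError("schedule keep-counts must be strictly decreasing")


def make_prune_schedule(
    n_prunable: int, target_keep: int, n_steps: int, kind: str = "exponential"
) -> PruneSchedule:
    """Interpolate keep counts from |P| down to the target over ``n_steps`` steps.

    Exponential (the FORCE-style default) spaces the counts geometrically; linear
    spaces them arithmetically.  Duplicate counts arising from rounding on tiny
    models are collapsed, so the schedule may end up shorter than requested.
    """
    if not 1 <= target_keep <= n_prunable:
        raise ValueError("target keep-count must lie in [1, |P|]")
    t = np.arange(1, n_steps + 1) / n_steps
    if kind == "exponential":
        qs = n_prunable * (target_keep / n_prunable) ** t
    elif kind == "linear":
        qs = n_prunable + (target_keep - n_prunable) * t
    else:
        raise ValueError(f"unknown schedule kind {kind!r}")
    steps = np.floor(qs + 0.5).astype(int)
    steps[-1] = target_keep
    uniq = [int(steps[0])]
    for q in steps[1:]:
        if q < uniq[-1]:
            uniq.append(int(q))
    if uniq[-1] != target_keep:
        uniq.append(target_keep)
    return PruneSchedule(tuple(uniq), kind)


def connection_saliency(
    model: nn.Sequential,
    params: ParamVector,
    batches: list[tuple[np.ndarray, np.ndarray]],
    client_id: int | str = 0,
) -> SaliencyScores:
    """SNIP scores s_i = |θ_i · g_i| over prunable positions.

    The gradient g is the loss gradient at ``params`` accumulated (summed) over
    the supplied mini-batches; a single batch is the single-shot default.
    """
    if not batches:
        raise ValueError("connection_saliency needs at least one batch")
    if not np.isfinite(params.values).all():
        raise ValueError("parameters must be finite")
    set_model_params(model, params)
    layout = params.layout
    g = np.zeros(layout.size)
    n_used = 0
    for X, y in batches:
        model.loss_and_backward(X, y)
        g += flat_gradients(model, layout)
        n_used += len(X)
    pm = layout.prunable_mask
    scores = np.abs(params.values[pm] * g[pm])
    return SaliencyScores(scores, client_id=client_id, n_samples_used=n_used)


def _top_indices(scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest scores; ties broken by lowest index (stable sort)."""
    order = np.argsort(-scores, kind="stable")
    return order[:k]


def topq_mask(
    scores: SaliencyScores | np.ndarray, sparsity: float, layout: ParamLayout
) -> Mask:
    """Keep the top-q scores among prunable positions; dense tensors stay on."""
    values = scores.values if isinstance(scores, SaliencyScores) else np.asarray(scores)
    if not 0.0 <= sparsity < 1.0:
        raise ValueError("sparsity must lie in [0, 1)")
    n_p = layout.n_prunable
    if values.shape != (n_p,):
        raise ValueError(f"scores length {values.shape} != |P| = {n_p}")
    if not np.isfinite(values).all():
        raise ValueError("scores must be finite")
    k = keep_count(sparsity, n_p)
    bits_p = np.zeros(n_p, dtype=np.uint8)
    bits_p[_top_indices(values, k)] = 1
    return mask_from_prunable_bits(bits_p, sparsity, layout)


def aggregate_scores(
    per_client: list[SaliencyScores],
    weights: np.ndarray | list[float] | None = None,
) -> np.ndarray:
    """Cross-client score aggregation.

    Unweighted mode is the plain elementwise sum Σ_k s_k; weighted mode is the
    n_k-weighted mean Σ w_k s_k / Σ w_k.  (The resulting top-q mask is invariant
    to the positive normalisation either way.)
    """
    if not per_client:
        raise ValueError("no score vectors to aggregate")
    n = per_client[0].values.size
    for s in per_client:
        if s.values.size != n:
            raise ValueError("score vectors have mismatched lengths")
    stacked = np.stack([s.values for s in per_client])
    if weights is None:
        return stacked.sum(axis=0)
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (len(per_client),):
        raise ValueError("need one weight per client")
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    return (w[:, None] * stacked).sum(axis=0) / w.sum()


def iterative_mask(
    model: nn.Sequential,
    params: ParamVector,
    batches: list[tuple[np.ndarray, np.ndarray]],
    sparsity: float,
    schedule: PruneSchedule,
) -> Mask:
    """Iterative saliency pruning along a decreasing keep-count schedule.

    At step t the scores are recomputed with fresh gradients at θ̄ = θ ⊙ c_t and
    the next mask keeps the top q_{t+1} positions *within* supp(c_t), so supports
    are nested and no pruned position is ever re-activated.  A one-step schedule
    recovers single-shot SNIP exactly.
    """
    layout = params.layout
    n_p = layout.n_prunable
    target = keep_count(sparsity, n_p)
    if schedule.steps[-1] != target:
        raise ValueError(
            f"schedule ends at {schedule.steps[-1]} but target keep-count is {target}"
        )
    bits_p = np.ones(n_p, dtype=np.uint8)
    pm = layout.prunable_mask
    for q in schedule.steps:
        masked = params.copy()
        masked.values[pm] *= bits_p
        scores = connection_saliency(model, masked, batches).values
        scores = np.where(bits_p.astype(bool), scores, -np.inf)
        new_bits = np.zeros(n_p, dtype=np.uint8)
        new_bits[_top_indices(scores, q)] = 1
        assert (new_bits <= bits_p).all()  # nested supports by construction
        bits_p = new_bits
    return mask_from_prunable_bits(bits_p, sparsity, layout)


def global_mask_protocol(
    clients: list[tuple[nn.Sequential, list[tuple[np.ndarray, np.ndarray]]]],
    init_params: ParamVector,
    sparsity: float,
    mode: str = "sum",
    seed: int | None = None,
    client_weights: np.ndarray | list[float] | None = None,
    ledger: TrafficLedger | None = None,
    schedule: PruneSchedule | None = None,
) -> list[Mask]:
    """One-time mask construction at the start of a federated run.

    ``clients`` is a list of (model copy, local batches).  All clients must share
    one architecture and start from the same initialisation ``init_params``.
    Modes:

    - ``sum`` — each client scores locally, scores are summed, one top-q mask is
      broadcast to every client (the method's default protocol);
    - ``weighted`` — as ``sum`` but the aggregation is the n_k-weighted mean;
    - ``individual`` — each client keeps the top-q of its *own* scores (baseline);
    - ``random`` — one uniformly random keep-set shared by all clients (baseline).

    When a ledger is supplied, the one-time costs are recorded exactly once per
    run: the dense score exchange (sum/weighted) and the mask broadcast.
    """
    if not clients:
        raise ValueError("protocol needs at least one client")
    layout = init_params.layout
    for model, _ in clients:
        if layout_of(model).hash() != layout.hash():
            raise ValueError("heterogeneous client layouts: all clients must share one architecture")
    n_p = layout.n_prunable
    k = keep_count(sparsity, n_p)

    if mode == "random":
        rng = np.random.default_rng(seed)
        bits_p = np.zeros(n_p, dtype=np.uint8)
        bits_p[rng.choice(n_p, size=k, replace=False)] = 1
        mask = mask_from_prunable_bits(bits_p, sparsity, layout)
        if ledger is not None:
            ledger.log_mask_broadcast(layout.size)
        return [mask] * len(clients)

    pm = layout.prunable_mask

    def _scores_at(bits_p: np.ndarray) -> list[SaliencyScores]:
        masked = init_params.copy()
        masked.values[pm] *= bits_p
        return [
            connection_saliency(model, masked, batches, client_id=i)
            for i, (model, batches) in enumerate(clients)
        ]

    if mode == "individual":
        per_client = _scores_at(np.ones(n_p, dtype=np.uint8))
        return [topq_mask(s, sparsity, layout) for s in per_client]

    if mode in ("sum", "weighted"):
        steps = schedule.steps if schedule is not None else (k,)
        if steps[-1] != k:
            raise ValueError(
                f"schedule ends at {steps[-1]} but target keep-count is {k}"
            )
        bits_p = np.ones(n_p, dtype=np.uint8)
        for q in steps:
            per_client = _scores_at(bits_p)
            if mode == "weighted":
                w = (
                    np.asarray(client_weights, dtype=np.float64)
                    if client_weights is not None
                    else np.array(
                        [s.n_samples_used for s in per_client], dtype=np.float64
                    )
                )
                agg = aggregate_scores(per_client, w)
            else:
                agg = aggregate_scores(per_client)
            agg = np.where(bits_p.astype(bool), agg, -np.inf)
            new_bits = np.zeros(n_p, dtype=np.uint8)
            new_bits[_top_indices(agg, q)] = 1
            bits_p = new_bits
        mask = mask_from_prunable_bits(bits_p, sparsity, layout)
        if ledger is not None:
            # one logical exchange per run even for multi-step schedules: each
            # step re-uses the same already-open exchange, so the one-time cost
            # is logged once with the number of steps folded into n_clients
            n_steps = len(steps)
            ledger.log_score_exchange(n_p, len(clients) * n_steps)
            ledger.log_mask_broadcast(layout.size)
        return [mask] * len(clients)

    raise ValueError(f"unknown mask protocol mode {mode!r}")
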