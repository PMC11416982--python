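"""IID and Dirichlet non-IID client partitions with per-client train/test splits.

The non-IID construction draws, for every client, a class-proportion vector
q ~ Dir(α·p) with a uniform prior p over the C classes, then allocates each
class's samples to clients in proportion to the normalised draws.  Small α
concentrates each client on one class; large α approaches identical class
distributions at every client.  Continuous fractions are turned into integer
counts by largest-remainder apportionment per class, which conserves samples
exactly; the minimum-samples-per-client constraint is enforced by resampling
the whole draw (fresh sub-seed) rather than moving samples post hoc, which
preserves the stated distributional model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Partition",
    "dirichlet_partition",
    "iid_partition",
    "split_train_test",
    "partition_stats",
]


@dataclass
class Partition:
    """Disjoint assignment of sample indices to K clients, optionally split."""

    assignments: dict[int, np.ndarray]
    alpha: float | None  # None marks an IID partition
    seed: int
    train_idx: dict[int, np.ndarray] = field(default_factory=dict)
    test_idx: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.assignments = {
            int(k): np.asarray(v, dtype=np.int64) for k, v in self.assignments.items()
        }
        allidx = np.concatenate(list(self.assignments.values())) if self.assignments else np.array([])
        if len(np.unique(allidx)) != allidx.size:
            raise ValueError("a sample index is assigned to more than one client")

    @property
    def n_clients(self) -> int:
        return len(self.assignments)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(self.assignments[k]) for k in sorted(self.assignments)])

    def to_json(self, path=None) -> str:
        obj = {
            "alpha": self.alpha,
            "seed": self.seed,
            "assignments": {str(k): v.tolist() for k, v in self.assignments.items()},
            "train_idx": {str(k): v.tolist() for k, v in self.train_idx.items()},
            "test_idx": {str(k): v.tolist() for k, v in self.test_idx.items()},
        }
        s = json.dumps(obj)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "Partition":
        if hasattr(source, "read"):
            obj = json.load(source)
        else:
            try:
                obj = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    obj = json.load(fh)
        p = cls(
            {int(k): np.array(v) for k, v in obj["assignments"].items()},
            obj["alpha"],
            obj["seed"],
        )
        p.train_idx = {int(k): np.array(v, dtype=np.int64) for k, v in obj["train_idx"].items()}
        p.test_idx = {int(k): np.array(v, dtype=np.int64) for k, v in obj["test_idx"].items()}
        return p


def _largest_remainder(fractions: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` items to shares ``fractions`` (sum 1), conserving exactly."""
    raw = fractions * total
    counts = np.floor(raw).astype(int)
    rem = total - counts.sum()
    if rem > 0:
        # stable: ties go to the lowest client index
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:rem]] += 1
    return counts


def dirichlet_partition(
    labels: np.ndarray,
    K: int,
    alpha: float,
    min_samples: int = 5,
    seed: int = 0,
    max_attempts: int = 100,
) -> Partition:
    """Label-skewed partition with per-client proportions drawn from Dir(α·p)."""
    labels = np.asarray(labels)
    n = labels.size
    if K < 1:
        raise ValueError("K must be >= 1")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if K * min_samples > n:
        raise ValueError(
            f"cannot give {K} clients >= {min_samples} samples each from n={n}"
        )
    classes = np.unique(labels)
    C = classes.size
    concentration = np.full(C, alpha / C)  # α·p with uniform prior p
    smallest = None
    for attempt in range(max_attempts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        Q = rng.dirichlet(concentration, size=K)  # K x C client proportions
        buckets: list[list[int]] = [[] for _ in range(K)]
        for c_pos, c in enumerate(classes):
            idx_c = np.flatnonzero(labels == c)
            rng.shuffle(idx_c)
            shares = Q[:, c_pos] / Q[:, c_pos].sum()
            counts = _largest_remainder(shares, idx_c.size)
            start = 0
            for k in range(K):
                buckets[k].extend(idx_c[start : start + counts[k]].tolist())
                start += counts[k]
        sizes = np.array([len(b) for b in buckets])
        if sizes.min() >= min_samples:
            return Partition(
                {k: np.sort(np.array(b, dtype=np.int64)) for k, b in enumerate(buckets)},
                float(alpha),
                seed,
            )
        smallest = int(sizes.min())
    raise RuntimeError(
        f"could not satisfy min_samples={min_samples} after {max_attempts} attempts "
        f"(smallest client had {smallest} samples); increase n or alpha"
    )


def iid_partition(labels: np.ndarray, K: int, seed: int = 0) -> Partition:
    """Uniformly random near-equal split; client sizes differ by at most one."""
    labels = np.asarray(labels)
    n = labels.size
    if K > n:
        raise ValueError(f"K={K} exceeds the number of samples n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    chunks = np.array_split(perm, K)
    return Partition(
        {k: np.sort(chunk.astype(np.int64)) for k, chunk in enumerate(chunks)},
        None,
        seed,
    )


def split_train_test(
    partition: Partition, fraction: float = 0.8, seed: int = 0
) -> Partition:
    """Unstratified uniform train/test split within each client.

    Train size is floor(fraction * n_k), nudged so both sides are nonempty.
    Returns the same partition object with ``train_idx`` / ``test_idx`` filled.
    """
    for k, idx in partition.assignments.items():
        if idx.size < 2:
            raise ValueError(f"client {k} has {idx.size} samples; need >= 2 to split")
        rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
        perm = rng.permutation(idx)
        n_train = int(np.floor(fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        partition.train_idx[k] = np.sort(perm[:n_train])
        partition.test_idx[k] = np.sort(perm[n_train:])
    return partition


def partition_stats(partition: Partition, labels: np.ndarray) -> pd.DataFrame:
    """Per-client class histogram, size, and majority-class share."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    rows = []
    for k in sorted(partition.assignments):
        idx = partition.assignments[k]
        counts = {f"class_{c}": int((labels[idx] == c).sum()) for c in classes}
        n_k = idx.size
        maj = max(counts.values()) / n_k if n_k else float("nan")
        rows.append({"client": k, "n": n_k, "majority_share": maj, **counts})
    return pd.DataFrame(rows)
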