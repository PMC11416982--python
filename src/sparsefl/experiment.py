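"""Config-driven experiment grids: method arm x sparsity x seed.

One root seed per replicate fans out to named sub-streams (initialisation,
partition, client sampling, batch order, dataset noise), so every arm of a grid
sees identical data, identical partitions and identical common initialisation —
arms differ only in how the mask is built.  Rerunning a config reproduces the
results table exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .comms import ledger_report
from .federation import FLConfig, evaluate, run_federation
from .model_core import build_model
from .partition import dirichlet_partition, iid_partition, split_train_test
from .synthetic import VolumeDatasetSpec, make_volumes

__all__ = ["ExperimentConfig", "ARM_REGISTRY", "run_experiment", "summarize", "load_config"]

# arm name -> mask protocol settings
ARM_REGISTRY = {
    "neurosfl": {"mask_mode": "sum"},
    "weighted_snip": {"mask_mode": "weighted"},
    "iter_snip": {"mask_mode": "sum", "iterative": True},
    "individual_snip": {"mask_mode": "individual"},
    "random_global": {"mask_mode": "random"},
    "dense_fedavg": {"mask_mode": "dense"},
}


@dataclass
class ExperimentConfig:
    """Full experiment grid specification (YAML-loadable)."""

    arms: tuple[str, ...] = ("neurosfl", "dense_fedavg")
    sparsities: tuple[float, ...] = (0.0, 0.5, 0.8, 0.9, 0.95)
    seeds: tuple[int, ...] = (0,)
    dataset: VolumeDatasetSpec = field(default_factory=VolumeDatasetSpec)
    partition_kind: str = "dirichlet"
    alpha: float = 0.3
    min_samples: int = 5
    train_fraction: float = 0.8
    arch: str = "tiny-mlp"
    hidden: int = 16
    K: int = 10
    K_prime: int | None = None
    rounds: int = 200
    local_epochs: int = 5
    batch_size: int = 32
    lr: float = 0.01
    lr_decay: float = 0.998
    iter_steps: int = 10
    saliency_batches: int = 1
    payload_mode: str = "csr"
    eval_every: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.arms) - set(ARM_REGISTRY)
        if unknown:
            raise ValueError(f"unknown arms {sorted(unknown)}; registry: {sorted(ARM_REGISTRY)}")
        if any(not 0 <= s < 1 for s in self.sparsities):
            raise ValueError("sparsity grid values must lie in [0, 1)")
        if isinstance(self.dataset, dict):
            self.dataset = VolumeDatasetSpec(**self.dataset)

    def fl_config(self, arm: str, sparsity: float, seed: int) -> FLConfig:
        settings = ARM_REGISTRY[arm]
        return FLConfig(
            K=self.K,
            K_prime=self.K_prime,
            rounds=self.rounds,
            local_epochs=self.local_epochs,
            batch_size=self.batch_size,
            lr=self.lr,
            lr_decay=self.lr_decay,
            sparsity=sparsity,
            mask_mode=settings["mask_mode"],
            seed=seed,
            payload_mode=self.payload_mode,
            saliency_batches=self.saliency_batches,
            iter_steps=self.iter_steps if settings.get("iterative") else 1,
            eval_every=self.eval_every,
        )


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        obj = yaml.safe_load(fh) or {}
    for key in ("arms", "sparsities", "seeds"):
        if key in obj:
            obj[key] = tuple(obj[key])
    return ExperimentConfig(**obj)


def _prepare_replicate(cfg: ExperimentConfig, seed: int):
    spec = dataclasses.replace(cfg.dataset, seed=seed)
    vols, labels, _sites = make_volumes(spec)
    X = vols.reshape(len(vols), -1)
    if cfg.partition_kind == "dirichlet":
        part = dirichlet_partition(labels, cfg.K, cfg.alpha, cfg.min_samples, seed)
    elif cfg.partition_kind == "iid":
        part = iid_partition(labels, cfg.K, seed)
    else:
        raise ValueError("partition_kind must be 'iid' or 'dirichlet'")
    split_train_test(part, cfg.train_fraction, seed)
    test_sets = [
        (X[part.test_idx[k]], labels[part.test_idx[k]]) for k in sorted(part.assignments)
    ]
    return X, labels, part, test_sets


def run_experiment(cfg: ExperimentConfig, progress: bool = False) -> pd.DataFrame:
    """One row per (arm, sparsity, seed): pooled metrics + exact byte accounting."""
    rows = []
    n_classes = cfg.dataset.n_classes
    for seed in cfg.seeds:
        X, labels, part, test_sets = _prepare_replicate(cfg, seed)

        kw = {"hidden": cfg.hidden} if cfg.arch == "tiny-mlp" else {}

        def factory(s, _nf=X.shape[1]):
            return build_model(cfg.arch, _nf, n_classes, seed=s, **kw)

        for arm in cfg.arms:
            for sparsity in cfg.sparsities:
                fl = cfg.fl_config(arm, sparsity, seed)
                result = run_federation(fl, part, X, labels, factory, test_sets)
                model = factory([fl.seed, 0])
                shared = fl.mask_mode in ("sum", "weighted", "random", "dense")
                metrics = evaluate(
                    model, result.params, result.mask if shared else None, test_sets
                )
                report = ledger_report(
                    result.ledger, result.params.layout.size, fl.value_bytes
                )
                if progress:  # pragma: no cover - console feedback only
                    print(
                        f"[seed {seed}] {arm} s={sparsity:.2f}: "
                        f"acc={metrics['pooled_accuracy']:.3f}"
                    )
                rows.append(
                    {
                        "arm": arm,
                        "sparsity": sparsity,
                        "seed": seed,
                        "pooled_accuracy": metrics["pooled_accuracy"],
                        "pooled_macro_f1": metrics["pooled_macro_f1"],
                        "total_bytes": report["payload_bytes"],
                        "one_time_bytes": report["one_time_bytes"],
                        "ratio_vs_dense": report["ratio_vs_dense"],
                        "per_client": json.dumps(metrics["per_client"]),
                    }
                )
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Per-(arm, sparsity) mean +/- sd across seeds; exact aggregation."""
    if results.empty:
        raise ValueError("no results to summarize")
    g = results.groupby(["arm", "sparsity"], sort=True)
    out = g.agg(
        accuracy_mean=("pooled_accuracy", "mean"),
        accuracy_sd=("pooled_accuracy", lambda s: s.std(ddof=0)),
        macro_f1_mean=("pooled_macro_f1", "mean"),
        macro_f1_sd=("pooled_macro_f1", lambda s: s.std(ddof=0)),
        bytes_mean=("total_bytes", "mean"),
        ratio_vs_dense_mean=("ratio_vs_dense", "mean"),
        n_seeds=("seed", "nunique"),
    ).reset_index()
    return out


def per_site_table(results_row: pd.Series) -> pd.DataFrame:
    """Expand one results row's per-client metrics into a table."""
    return pd.DataFrame(json.loads(results_row["per_client"]))


def summary_markdown(summary: pd.DataFrame) -> str:
    cols = ["arm", "sparsity", "accuracy_mean", "accuracy_sd", "macro_f1_mean", "ratio_vs_dense_mean"]
    lines = ["| " + " | ".join(cols) + " |", "|" + "---|" * len(cols)]
    for _, row in summary.iterrows():
        cells = [
            str(row[c]) if isinstance(row[c], str) else f"{row[c]:.4g}" for c in cols
        ]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)
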