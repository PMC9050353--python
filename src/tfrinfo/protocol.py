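"""Repeated-split evaluation harness.

Information content of a feature set is scored as the mean best validation
accuracy of MLP classifiers over many repetitions of random 60/40
train/validation splitting, weight initialization, and training.  Chance
level -- crucial for unbalanced designs -- is estimated by rerunning the
identical protocol with labels randomly permuted each run, which converges
to the majority-class fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import LabeledDataset
from .mlp import MLPConfig, RpropParams, TrainResult, init_model, train_irprop_plus

__all__ = [
    "ProtocolConfig",
    "ProtocolResult",
    "split_dataset",
    "run_protocol",
    "compare_methods",
    "train_best_model",
]


@dataclass(frozen=True)
class ProtocolConfig:
    train_fraction: float = 0.6
    n_runs: int = 100
    shuffle_labels: bool = False
    base_seed: int = 0
    fixed_split: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass
class ProtocolResult:
    best_val_accuracy: np.ndarray  # per run
    mean_accuracy: float
    sem_accuracy: float
    mean_val_accuracy_curve: np.ndarray
    mean_val_mse_curve: np.ndarray
    mean_train_accuracy_curve: np.ndarray
    mean_train_mse_curve: np.ndarray
    run_seeds: np.ndarray
    split_indices: list[tuple[np.ndarray, np.ndarray]]

    @property
    def n_runs(self) -> int:
        return self.best_val_accuracy.size


def split_dataset(
    ds: LabeledDataset,
    train_fraction: float = 0.6,
    seed: int | np.random.Generator | None = 0,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Uniform random split without replacement (not class-stratified).

    The training side gets ``round(fraction * N)`` samples, the validation
    side the remainder; deterministic given the seed.
    """
    train_idx, val_idx = split_indices(ds.n_samples, train_fraction, seed)
    return ds.subset(train_idx), ds.subset(val_idx)


def split_indices(
    n: int, train_fraction: float, seed: int | np.random.Generator | None
) -> tuple[np.ndarray, np.ndarray]:
    n_train = int(round(train_fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"split of {n} samples at fraction {train_fraction} leaves one side empty"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _run_streams(base_seed: int, run: int) -> list[np.random.Generator]:
    """Independent substreams (split, shuffle, init, dropout) for one run."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(run,))
    return [np.random.default_rng(child) for child in ss.spawn(4)]


def run_protocol(
    ds: LabeledDataset,
    mlp_config: MLPConfig,
    rprop: RpropParams = RpropParams(),
    protocol: ProtocolConfig = ProtocolConfig(),
    keep_curves: bool = True,
) -> ProtocolResult:
    """Repeat split -> (optional label shuffle) -> init -> train, aggregate.

    When ``shuffle_labels`` is set, labels are permuted across the whole
    dataset before splitting, preserving the class priors so the resulting
    accuracy estimates the chance level.  With ``fixed_split`` every run
    reuses the run-0 split (isolating initialization variability).
    """
    if mlp_config.input_size != ds.n_features:
        raise ValueError("MLP input size does not match the dataset")
    accs = np.zeros(protocol.n_runs)
    seeds = np.zeros(protocol.n_runs, dtype=np.int64)
    splits: list[tuple[np.ndarray, np.ndarray]] = []
    curve_sums: dict[str, np.ndarray] | None = None

    for r in range(protocol.n_runs):
        try:
            split_rng, shuffle_rng, init_rng, dropout_rng = _run_streams(
                protocol.base_seed, 0 if protocol.fixed_split else r
            )
            if protocol.fixed_split:
                # only the split stream is pinned to run 0
                _, shuffle_rng, init_rng, dropout_rng = _run_streams(
                    protocol.base_seed, r
                )
            labels = ds.labels
            if protocol.shuffle_labels:
                labels = labels[shuffle_rng.permutation(ds.n_samples)]
            train_idx, val_idx = split_indices(
                ds.n_samples, protocol.train_fraction, split_rng
            )
            model = init_model(mlp_config, init_rng)
            result: TrainResult = train_irprop_plus(
                model,
                ds.features[train_idx],
                labels[train_idx],
                ds.features[val_idx],
                labels[val_idx],
                rprop,
                seed=dropout_rng,
            )
        except Exception as exc:
            raise RuntimeError(f"protocol run {r} failed: {exc}") from exc

        accs[r] = result.best_val_accuracy
        seeds[r] = protocol.base_seed + r
        splits.append((train_idx, val_idx))
        if keep_curves:
            if curve_sums is None:
                curve_sums = {
                    "va": np.zeros_like(result.val_accuracy),
                    "vm": np.zeros_like(result.val_mse),
                    "ta": np.zeros_like(result.train_accuracy),
                    "tm": np.zeros_like(result.train_mse),
                }
            curve_sums["va"] += result.val_accuracy
            curve_sums["vm"] += result.val_mse
            curve_sums["ta"] += result.train_accuracy
            curve_sums["tm"] += result.train_mse

    n = protocol.n_runs
    empty = np.empty(0)
    return ProtocolResult(
        best_val_accuracy=accs,
        mean_accuracy=float(accs.mean()),
        sem_accuracy=float(accs.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        mean_val_accuracy_curve=curve_sums["va"] / n if curve_sums else empty,
        mean_val_mse_curve=curve_sums["vm"] / n if curve_sums else empty,
        mean_train_accuracy_curve=curve_sums["ta"] / n if curve_sums else empty,
        mean_train_mse_curve=curve_sums["tm"] / n if curve_sums else empty,
        run_seeds=seeds,
        split_indices=splits,
    )


def train_best_model(
    ds: LabeledDataset,
    mlp_config: MLPConfig,
    rprop: RpropParams = RpropParams(),
    train_fraction: float = 0.6,
    base_seed: int = 0,
    n_candidates: int = 5,
) -> tuple[TrainResult, np.ndarray, np.ndarray]:
    """Fix one random split, train several networks, keep the most accurate.

    This is the setup used before feature-importance analysis: a fixed split
    removes split variability, and selecting the best of ``n_candidates``
    initializations gives a model worth explaining.  Returns
    ``(best TrainResult, train indices, validation indices)``.
    """
    split_rng = _run_streams(base_seed, 0)[0]
    train_idx, val_idx = split_indices(ds.n_samples, train_fraction, split_rng)
    best: TrainResult | None = None
    for r in range(n_candidates):
        _, _, init_rng, dropout_rng = _run_streams(base_seed, r)
        model = init_model(mlp_config, init_rng)
        result = train_irprop_plus(
            model,
            ds.features[train_idx],
            ds.labels[train_idx],
            ds.features[val_idx],
            ds.labels[val_idx],
            rprop,
            seed=dropout_rng,
        )
        if best is None or result.best_val_accuracy > best.best_val_accuracy:
            best = result
    return best, train_idx, val_idx


def compare_methods(
    datasets: dict[str, LabeledDataset],
    mlp_config: MLPConfig,
    rprop: RpropParams = RpropParams(),
    protocol: ProtocolConfig = ProtocolConfig(),
    chance: bool = True,
) -> pd.DataFrame:
    """Run the protocol per method on identically seeded splits.

    ``datasets`` maps method name -> feature dataset built from the same
    trials.  Returns a table with one row per (method, label mode):
    columns ``method``, ``labels`` ('true' or 'shuffled'), ``mean_accuracy``,
    ``sem_accuracy``, ``n_runs``.
    """
    if len(datasets) < 1:
        raise ValueError("need at least one method dataset")
    rows = []
    results: dict[tuple[str, str], ProtocolResult] = {}
    modes = [("true", False)] + ([("shuffled", True)] if chance else [])
    for name, ds in datasets.items():
        cfg = (
            mlp_config
            if mlp_config.input_size == ds.n_features
            else MLPConfig(
                input_size=ds.n_features,
                output_size=mlp_config.output_size,
                activation=mlp_config.activation,
                init_range=mlp_config.init_range,
                dropout_p=mlp_config.dropout_p,
            )
        )
        for mode_name, shuffle in modes:
            pc = ProtocolConfig(
                train_fraction=protocol.train_fraction,
                n_runs=protocol.n_runs,
                shuffle_labels=shuffle,
                base_seed=protocol.base_seed,
                fixed_split=protocol.fixed_split,
            )
            res = run_protocol(ds, cfg, rprop, pc, keep_curves=False)
            results[(name, mode_name)] = res
            rows.append(
                {
                    "method": name,
                    "labels": mode_name,
                    "mean_accuracy": res.mean_accuracy,
                    "sem_accuracy": res.sem_accuracy,
                    "n_runs": pc.n_runs,
                }
            )
    table = pd.DataFrame(rows)
    table.attrs["results"] = results
    return table
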