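"""Trial-matrix readers/writers, run configuration, and the full pipeline.

Trials are stored as a trials x samples numeric matrix -- tab-delimited
text (``.tsv``) or flat float64 binary (``.bin``) -- with a JSON sidecar
(``<stem>.json``) holding the sampling rate, time origin, per-trial labels,
class names, and provenance.  The pipeline runner executes
synthesize/read -> TFR -> features -> protocol -> importance from one
validated configuration and writes every artifact with the config hash and
base seed embedded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import importance as imp
from . import mlp as mlpmod
from . import protocol as proto
from . import synthetic as synth
from .tfr import Signal

logger = logging.getLogger("tfrinfo")

__all__ = [
    "read_trials",
    "write_trials",
    "write_grid",
    "RunConfig",
    "load_config",
    "run_pipeline",
]


def write_trials(
    path: str | Path,
    signals: Sequence[Signal],
    labels: Sequence[int],
    class_names: Sequence[str] | None = None,
    provenance: dict | None = None,
) -> None:
    """Write a trial matrix plus its JSON sidecar.

    The format follows the extension: ``.bin`` is flat float64
    (row-major trials x samples), anything else tab-delimited text.
    """
    path = Path(path)
    if len(signals) != len(labels):
        raise ValueError("one label per trial required")
    fs = signals[0].sampling_rate
    t0 = signals[0].t0
    if any(s.sampling_rate != fs or s.n_samples != signals[0].n_samples for s in signals):
        raise ValueError("all trials must share sampling rate and length")
    matrix = np.vstack([s.samples for s in signals])
    if path.suffix == ".bin":
        matrix.astype("<f8").tofile(path)
    else:
        np.savetxt(path, matrix, delimiter="\t", fmt="%.10g")
    meta = {
        "sampling_rate": fs,
        "t0": t0,
        "n_trials": int(matrix.shape[0]),
        "n_samples": int(matrix.shape[1]),
        "labels": [int(x) for x in labels],
        "class_names": list(class_names) if class_names is not None else None,
        "provenance": provenance or {},
    }
    sidecar(path).write_text(json.dumps(meta, indent=2))


def sidecar(path: str | Path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".json")


def read_trials(path: str | Path) -> tuple[list[Signal], np.ndarray, dict]:
    """Read a trial matrix and its sidecar -> (signals, labels, metadata)."""
    path = Path(path)
    meta_path = sidecar(path)
    if not path.exists():
        raise FileNotFoundError(f"trial matrix {path} not found")
    if not meta_path.exists():
        raise FileNotFoundError(f"sidecar metadata {meta_path} not found")
    meta = json.loads(meta_path.read_text())
    for key in ("sampling_rate", "labels", "n_trials", "n_samples"):
        if key not in meta:
            raise ValueError(f"sidecar {meta_path} is missing required key {key!r}")
    if meta["sampling_rate"] <= 0:
        raise ValueError("sampling_rate must be positive")
    n_trials, n_samples = meta["n_trials"], meta["n_samples"]
    if path.suffix == ".bin":
        matrix = np.fromfile(path, dtype="<f8")
        if matrix.size != n_trials * n_samples:
            raise ValueError(
                f"binary matrix has {matrix.size} values, expected "
                f"{n_trials} x {n_samples}"
            )
        matrix = matrix.reshape(n_trials, n_samples)
    else:
        matrix = np.loadtxt(path, delimiter="\t", ndmin=2)
        if matrix.shape != (n_trials, n_samples):
            raise ValueError(
                f"text matrix shape {matrix.shape} does not match sidecar "
                f"({n_trials}, {n_samples})"
            )
    labels = np.asarray(meta["labels"], dtype=int)
    if labels.size != n_trials:
        raise ValueError(
            f"sidecar lists {labels.size} labels for {n_trials} trial rows"
        )
    t0 = float(meta.get("t0", 0.0))
    signals = [Signal(row, float(meta["sampling_rate"]), t0) for row in matrix]
    return signals, labels, meta


def write_grid(path: str | Path, grid) -> None:
    """Write a TFR grid as a TSV matrix with axes in a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, grid.values, delimiter="\t", fmt="%.10g")
    meta = {
        "method": grid.method,
        "params": _jsonable(grid.params),
        "freq_axis": grid.freq_axis.tolist(),
        "time_axis": grid.time_axis.tolist(),
    }
    sidecar(path).write_text(json.dumps(meta))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_PROTOCOL_DEFAULT_NORMALIZE = {
    "rf_like": ("global_minmax", *feat.LFP_MINMAX_RANGE),
    "srcs_like": ("global_minmax", *feat.LFP_MINMAX_RANGE),
    "eeg_like": "per_sample_zscore",
}
_PROTOCOL_GRID_KEY = {"rf_like": "rf", "srcs_like": "srcs1", "eeg_like": "eeg"}


@dataclasses.dataclass
class RunConfig:
    """Validated nested configuration for one end-to-end run.

    Unknown keys anywhere in the mapping are rejected.  Defaults follow the
    canonical analysis geometry of each protocol.
    """

    protocol_kind: str = "eeg_like"
    seed: int = 0
    effect_size: float = 1.0
    trials_path: str | None = None  # read instead of synthesize when set
    methods: tuple[str, ...] = ("stft", "cwt", "slt", "choiw")
    method_kwargs: dict = dataclasses.field(default_factory=dict)
    n_runs: int = 100
    train_fraction: float = 0.6
    epochs: int = 1000
    dropout_p: float = 0.1
    chance: bool = True
    importance_method: str | None = "slt"
    importance_threshold: float = 0.5
    importance_n_permutations: int = 10
    transient_rate: float = 0.0
    noise_power: float = 0.1
    one_over_f_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.protocol_kind not in _PROTOCOL_GRID_KEY:
            raise ValueError(f"unknown protocol_kind {self.protocol_kind!r}")
        unknown = set(self.method_kwargs) - set(self.methods)
        if unknown:
            raise ValueError(f"method_kwargs given for unknown methods {sorted(unknown)}")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - allowed
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = dict(mapping)
        if "methods" in cfg:
            cfg["methods"] = tuple(cfg["methods"])
        return cls(**cfg)

    def config_hash(self) -> str:
        payload = json.dumps(_jsonable(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration file."""
    mapping = yaml.safe_load(Path(path).read_text())
    if not isinstance(mapping, dict):
        raise ValueError(f"configuration file {path} must hold a mapping")
    return RunConfig.from_mapping(mapping)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _mlp_config_for(kind: str, n_features: int, n_classes: int, dropout_p: float):
    init_range = (-0.01, 0.01) if kind == "eeg_like" else (-0.1, 0.1)
    return mlpmod.MLPConfig(
        input_size=n_features,
        output_size=n_classes,
        init_range=init_range,
        dropout_p=dropout_p,
    )


def _rprop_for(kind: str, epochs: int) -> mlpmod.RpropParams:
    delta_max = 0.001 if kind == "eeg_like" else 0.01
    return mlpmod.RpropParams(delta_max=delta_max, epochs=epochs)


def build_method_datasets(
    signals: Sequence[Signal],
    labels: Sequence[int],
    kind: str,
    methods: Sequence[str],
    method_kwargs: dict | None = None,
    grid_spec: feat.StandardGridSpec | None = None,
    tiles: feat.TileSpec | None = None,
) -> dict[str, feat.LabeledDataset]:
    """Feature datasets for several estimators over the same trials."""
    default_grid, default_tiles = feat.PROTOCOL_GRIDS[_PROTOCOL_GRID_KEY[kind]]
    grid_spec = grid_spec or default_grid
    tiles = tiles or default_tiles
    normalize = _PROTOCOL_DEFAULT_NORMALIZE[kind]
    method_kwargs = method_kwargs or {}
    out = {}
    for method in methods:
        logger.info("building %s features for %d trials", method, len(signals))
        out[method] = feat.build_dataset(
            signals,
            labels,
            method,
            grid_spec,
            tiles,
            normalize_mode=normalize,
            method_kwargs=method_kwargs.get(method),
        )
    return out


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline and write artifacts under ``out_dir``.

    Stages: synthesize (or read) trials -> per-method feature datasets ->
    repeated-split protocol with true and shuffled labels -> grouped
    permutation importance on a fixed split for one method.  Returns a dict
    of artifact paths.  Deterministic given (config, seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "base_seed": config.seed}
    kind = config.protocol_kind

    logger.info("stage 1: trials (%s)", "read" if config.trials_path else "synthesize")
    if config.trials_path:
        signals, labels, _ = read_trials(config.trials_path)
    else:
        spec = synth.ProtocolSpec.default(
            kind,
            effect_size=config.effect_size,
            noise=synth.NoiseSpec(
                one_over_f_exponent=config.one_over_f_exponent,
                noise_power=config.noise_power,
                transient_rate=config.transient_rate,
            ),
        )
        signals, labels = synth.make_dataset(spec, seed=config.seed)
        write_trials(
            out_dir / "trials.tsv", signals, labels, provenance=dict(stamp)
        )

    logger.info("stage 2: feature datasets for %s", list(config.methods))
    datasets = build_method_datasets(
        signals, labels, kind, config.methods, config.method_kwargs
    )
    for method, ds in datasets.items():
        table = pd.DataFrame(ds.features)
        table.insert(0, "label", ds.labels)
        table.to_csv(out_dir / f"dataset_{method}.tsv", sep="\t", index=False)

    n_classes = int(np.max(labels)) + 1
    any_ds = next(iter(datasets.values()))
    mlp_cfg = _mlp_config_for(kind, any_ds.n_features, n_classes, config.dropout_p)
    rprop = _rprop_for(kind, config.epochs)
    pc = proto.ProtocolConfig(
        train_fraction=config.train_fraction,
        n_runs=config.n_runs,
        base_seed=config.seed,
    )

    logger.info("stage 3: protocol over %d runs x %d methods", pc.n_runs, len(datasets))
    table = proto.compare_methods(datasets, mlp_cfg, rprop, pc, chance=config.chance)
    for key, value in stamp.items():
        table[key] = value
    table.to_csv(out_dir / "comparison.tsv", sep="\t", index=False)

    artifacts = {
        "comparison": out_dir / "comparison.tsv",
        "datasets": {m: out_dir / f"dataset_{m}.tsv" for m in datasets},
    }

    if config.importance_method:
        method = config.importance_method
        if method not in datasets:
            raise ValueError(
                f"importance_method {method!r} is not among the computed methods"
            )
        logger.info("stage 4: permutation importance on %s", method)
        ds = datasets[method]
        cfg = _mlp_config_for(kind, ds.n_features, n_classes, config.dropout_p)
        result, train_idx, val_idx = proto.train_best_model(
            ds,
            cfg,
            rprop,
            train_fraction=config.train_fraction,
            base_seed=config.seed,
        )
        imap = imp.permute_importance(
            result.best_model,
            ds.subset(val_idx),
            imp.ImportanceConfig(
                correlation_threshold=config.importance_threshold,
                n_permutations=config.importance_n_permutations,
                seed=config.seed,
            ),
        )
        mse_map, pacc_map = imp.reshape_to_map(imap)
        np.savetxt(out_dir / "importance_dmse.tsv", mse_map, delimiter="\t")
        np.savetxt(out_dir / "importance_neg_dpacc.tsv", pacc_map, delimiter="\t")
        per_feature = pd.DataFrame(
            {
                "feature": np.arange(ds.n_features),
                "freq_tile": np.arange(ds.n_features) // ds.tile_spec.n_time_tiles,
                "time_tile": np.arange(ds.n_features) % ds.tile_spec.n_time_tiles,
                "set_size": imap.set_sizes,
                "delta_mse": imap.delta_mse,
                "delta_pacc": imap.delta_pacc,
            }
        )
        for key, value in stamp.items():
            per_feature[key] = value
        per_feature.to_csv(out_dir / "importance.tsv", sep="\t", index=False)
        artifacts["importance"] = out_dir / "importance.tsv"
        artifacts["importance_maps"] = (
            out_dir / "importance_dmse.tsv",
            out_dir / "importance_neg_dpacc.tsv",
        )

    (out_dir / "run.json").write_text(json.dumps(stamp, indent=2))
    return artifacts
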