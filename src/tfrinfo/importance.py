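"""Correlated-feature-set permutation importance on the validation split.

Permuting one feature across validation samples breaks its link to the
labels; the resulting change in classifier error measures that feature's
contribution.  Strongly correlated features carry redundant information, so
permuting one alone may leave performance intact.  Each focal feature is
therefore permuted jointly with its correlation neighborhood (all features
whose absolute Pearson correlation with it exceeds a threshold, default
0.5), using one shared row permutation per repetition so within-set joint
structure is preserved while the link to the labels is severed.

Outputs per feature: the increase in mean squared error (dMSE) and the
change in prediction accuracy (dPAcc, negative when permutation hurts).
Features whose permutation *improves* performance are flagged as
distractors.  Both quantities reshape onto the time-frequency tile grid for
visualization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import LabeledDataset, TileSpec
from .mlp import MLPModel, evaluate

__all__ = [
    "ImportanceConfig",
    "ImportanceMap",
    "feature_correlation",
    "correlated_set",
    "permute_importance",
    "reshape_to_map",
]


@dataclass(frozen=True)
class ImportanceConfig:
    """Grouping threshold (on |r|; values > 1 disable grouping entirely),
    permutation count per feature set, and the permutation seed."""

    correlation_threshold: float = 0.5
    n_permutations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.correlation_threshold < 0.0:
            raise ValueError("correlation_threshold must be non-negative")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class ImportanceMap:
    """Per-feature importance with the geometry needed to re-grid it."""

    delta_mse: np.ndarray
    delta_pacc: np.ndarray
    set_sizes: np.ndarray
    reference_accuracy: float
    reference_mse: float
    tile_spec: TileSpec
    config: ImportanceConfig = field(default_factory=ImportanceConfig)

    @property
    def distractors(self) -> np.ndarray:
        """Features whose permutation improved accuracy (misleading inputs)."""
        return np.where(self.delta_pacc > 0)[0]


def feature_correlation(features: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation between feature columns.

    Constant features get correlation 0 with everything (unit diagonal is
    kept); requires at least 3 rows for the estimate to be meaningful.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a 2-D matrix with at least 3 samples")
    constant = np.ptp(X, axis=0) == 0  # exact range test; std can round to ~1e-16
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.atleast_2d(corr)
    corr = 0.5 * (corr + corr.T)  # exact symmetry (corrcoef is only close)
    corr[np.isnan(corr)] = 0.0
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def correlated_set(
    corr: np.ndarray, feature: int, threshold: float = 0.5
) -> np.ndarray:
    """Direct correlation neighborhood of one feature (no transitive closure).

    Returns the sorted indices ``{j : |r(feature, j)| > threshold}`` plus the
    feature itself.
    """
    if not 0 <= feature < corr.shape[0]:
        raise IndexError(f"feature index {feature} out of range")
    members = np.where(np.abs(corr[feature]) > threshold)[0]
    return np.union1d(members, [feature])


def permute_importance(
    model: MLPModel,
    validation: LabeledDataset,
    config: ImportanceConfig = ImportanceConfig(),
) -> ImportanceMap:
    """Grouped permutation importance of every feature on the validation set.

    The reference accuracy/MSE is computed once on the intact set.  For each
    feature, its correlated set is co-permuted (one shared row permutation
    per repetition) ``n_permutations`` times and the mean perturbed
    performance recorded.  ``delta_mse = perturbed - reference`` and
    ``delta_pacc = perturbed_accuracy - reference_accuracy`` (so informative
    features have positive dMSE and negative dPAcc; positive dPAcc marks a
    distractor).
    """
    X, y = validation.features, validation.labels
    if X.shape[1] != model.config.input_size:
        raise ValueError("validation features do not match the model input size")
    rng = np.random.default_rng(config.seed)
    ref_acc, ref_mse = evaluate(model, X, y)
    corr = feature_correlation(X)

    n_feat = X.shape[1]
    d_mse = np.zeros(n_feat)
    d_acc = np.zeros(n_feat)
    sizes = np.zeros(n_feat, dtype=int)
    n = X.shape[0]
    for j in range(n_feat):
        members = correlated_set(corr, j, config.correlation_threshold)
        sizes[j] = members.size
        acc_sum = 0.0
        mse_sum = 0.0
        for _ in range(config.n_permutations):
            perm = rng.permutation(n)
            Xp = X.copy()
            Xp[:, members] = X[np.ix_(perm, members)]
            acc, mse = evaluate(model, Xp, y)
            # accumulate per-permutation deltas: a feature the model provably
            # ignores then reports exactly zero, with no averaging round-off
            acc_sum += acc - ref_acc
            mse_sum += mse - ref_mse
        d_mse[j] = mse_sum / config.n_permutations
        d_acc[j] = acc_sum / config.n_permutations

    return ImportanceMap(
        delta_mse=d_mse,
        delta_pacc=d_acc,
        set_sizes=sizes,
        reference_accuracy=ref_acc,
        reference_mse=ref_mse,
        tile_spec=validation.tile_spec,
        config=config,
    )


def reshape_to_map(imp: ImportanceMap) -> tuple[np.ndarray, np.ndarray]:
    """Reshape per-feature values onto the (freq tiles x time tiles) grid.

    Inverts the frequency-major linearization of the tiling step.  Returns
    ``(dMSE map, -dPAcc map)``; in both, larger positive values mark more
    important time-frequency components, and negative entries in the second
    mark distractors.
    """
    ts = imp.tile_spec
    if imp.delta_mse.size != ts.n_features:
        raise ValueError(
            f"importance length {imp.delta_mse.size} does not match tiling "
            f"{ts.n_freq_tiles} x {ts.n_time_tiles}"
        )
    shape = (ts.n_freq_tiles, ts.n_time_tiles)
    return imp.delta_mse.reshape(shape), -imp.delta_pacc.reshape(shape)
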