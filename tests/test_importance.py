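"""Correlated-feature permutation importance and its maps."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from tfrinfo import LabeledDataset, TileSpec
from tfrinfo.importance import (
    ImportanceConfig,
    correlated_set,
    feature_correlation,
    permute_importance,
    reshape_to_map,
)
from tfrinfo.mlp import MLPConfig, RpropParams, init_model, train_irprop_plus


def tiny_dataset(X, y, n_time=None):
    n_time = n_time or X.shape[1]
    return LabeledDataset(X, y, TileSpec(n_time, X.shape[1] // n_time))


class TestFeatureCorrelation:
    def test_duplicated_feature_has_unit_correlation(self, rng):
        X = rng.standard_normal((30, 3))
        X = np.column_stack([X, X[:, 0]])
        corr = feature_correlation(X)
        assert corr[0, 3] == pytest.approx(1.0)

    def test_symmetric_with_unit_diagonal(self, rng):
        corr = feature_correlation(rng.standard_normal((25, 6)))
        np.testing.assert_array_equal(corr, corr.T)
        np.testing.assert_allclose(np.diag(corr), 1.0)

    def test_independent_features_stay_below_null_bound(self, rng):
        # analytic null: for n = 200, P(|r| > 0.3) < 1e-4 per pair
        corr = feature_correlation(rng.standard_normal((200, 15)))
        off = corr[~np.eye(15, dtype=bool)]
        assert np.all(np.abs(off) < 0.3)

    def test_constant_feature_flagged_as_zero(self, rng):
        X = rng.standard_normal((20, 3))
        X[:, 1] = 4.2
        corr = feature_correlation(X)
        assert np.all(corr[1, [0, 2]] == 0.0)
        assert corr[1, 1] == 1.0

    def test_needs_three_samples(self):
        with pytest.raises(ValueError, match="3 samples"):
            feature_correlation(np.ones((2, 4)))


class TestCorrelatedSet:
    def test_isolated_feature_gives_singleton(self):
        corr = np.eye(4)
        assert list(correlated_set(corr, 2, 0.5)) == [2]

    def test_duplicated_pair_grouped(self):
        corr = np.eye(3)
        corr[0, 1] = corr[1, 0] = 1.0
        assert list(correlated_set(corr, 0, 0.5)) == [0, 1]

    def test_neighborhood_not_transitive(self):
        # r(a,b) = 0.6, r(b,c) = 0.6, r(a,c) = 0.2: the set of a excludes c
        corr = np.array([[1.0, 0.6, 0.2], [0.6, 1.0, 0.6], [0.2, 0.6, 1.0]])
        assert list(correlated_set(corr, 0, 0.5)) == [0, 1]
        assert list(correlated_set(corr, 1, 0.5)) == [0, 1, 2]

    def test_negative_correlation_counts(self):
        corr = np.eye(2)
        corr[0, 1] = corr[1, 0] = -0.8
        assert list(correlated_set(corr, 0, 0.5)) == [0, 1]


def _mean_readout_model(n_feat, copies):
    """Hand-built net classifying by the mean of the listed feature columns.

    Class 1 wins exactly when that mean exceeds 1 (the midpoint of the
    planted 0/2 class values); the other features are ignored.
    """
    cfg = MLPConfig(
        input_size=n_feat, output_size=2, hidden_sizes=(1, 1),
        init_range=(-0.5, 0.5), dropout_p=0.0,
    )
    model = init_model(cfg, 0)
    model.weights[0][:] = 0.0
    model.weights[0][0, copies] = 0.2 / len(copies)
    model.biases[0][:] = -0.2  # zero crossing at mean == 1
    model.weights[1][:] = 1.0
    model.biases[1][:] = 0.0
    model.weights[2][:] = np.array([[-20.0], [20.0]])
    model.biases[2][:] = 0.0
    return model


def _toy_split(n):
    # interleaves class pairs so both halves carry both classes
    return np.arange(n) % 4 < 2


def _train_toy(X, y, seed=0, epochs=300):
    cfg = MLPConfig(
        input_size=X.shape[1], output_size=int(y.max()) + 1,
        hidden_sizes=(8, 4), init_range=(-0.5, 0.5), dropout_p=0.0,
    )
    tr = _toy_split(len(y))
    res = train_irprop_plus(
        init_model(cfg, seed), X[tr], y[tr], X[~tr], y[~tr],
        RpropParams(epochs=epochs), seed=seed,
    )
    return res.best_model, X[~tr], y[~tr]


class TestPermuteImportance:
    def test_ignored_feature_has_exactly_zero_importance(self, rng):
        # zero first-layer weights from feature 3 make the network output
        # invariant to it; with no correlated partners both deltas vanish
        X = rng.standard_normal((200, 6))
        y = (X[:, 0] > 0).astype(int)
        model, Xv, yv = _train_toy(X, y, epochs=100)
        model.weights[0][:, 3] = 0.0
        imp = permute_importance(
            model, tiny_dataset(Xv, yv), ImportanceConfig(seed=0)
        )
        assert imp.delta_mse[3] == 0.0
        assert imp.delta_pacc[3] == 0.0

    def test_single_informative_feature_drops_to_chance(self, rng):
        # permuting the only informative feature must push accuracy to the
        # majority-class fraction (0.5 here) within 5 points
        n = 120
        y = np.arange(n) % 2
        X = rng.standard_normal((n, 8)) * 0.3
        X[:, 2] += 2.0 * y
        model, Xv, yv = _train_toy(X, y, epochs=400)
        imp = permute_importance(
            model, tiny_dataset(Xv, yv), ImportanceConfig(seed=1)
        )
        assert imp.reference_accuracy > 0.9
        permuted_acc = imp.reference_accuracy + imp.delta_pacc[2]
        assert abs(permuted_acc - 0.5) <= 0.05

    def test_redundant_group_needs_grouped_permutation(self, rng):
        # a redundant group of near-copies read out through their mean:
        # permuting any single member perturbs the mean by at most 1/6 of
        # the class margin, so only the grouped (threshold 0.5)
        # co-permutation reveals the shared effect
        n = 120
        n_feat, copies = 12, [1, 3, 5, 7, 9, 11]
        y = rng.integers(0, 2, n)
        X = rng.standard_normal((n, n_feat)) * 0.3
        for j in copies:
            X[:, j] = 2.0 * y + 0.05 * rng.standard_normal(n)
        model = _mean_readout_model(n_feat, copies)

        ungrouped = permute_importance(
            model, tiny_dataset(X, y),
            ImportanceConfig(correlation_threshold=1.01, seed=2),
        )
        grouped = permute_importance(
            model, tiny_dataset(X, y),
            ImportanceConfig(correlation_threshold=0.5, seed=2),
        )
        assert ungrouped.reference_accuracy == 1.0
        for j in copies:
            assert abs(ungrouped.delta_pacc[j]) <= 0.05
            assert grouped.delta_pacc[j] < -0.3

    def test_distractor_yields_negative_importance(self, rng):
        # the one feature the model learned from is anti-aligned with the
        # labels on the held-out validation split: permuting it *helps*
        n = 120
        y = np.arange(n) % 2
        X = rng.standard_normal((n, 6)) * 0.3
        tr = _toy_split(n)
        X[tr, 3] = 1.0 * y[tr] + 0.1 * rng.standard_normal(tr.sum())
        X[~tr, 3] = 1.0 * (1 - y[~tr]) + 0.1 * rng.standard_normal((~tr).sum())
        cfg = MLPConfig(
            input_size=6, output_size=2, hidden_sizes=(8, 4),
            init_range=(-0.5, 0.5), dropout_p=0.0,
        )
        # monitor on the training set so best-state selection cannot
        # early-stop its way around the planted train/validation flip
        res = train_irprop_plus(
            init_model(cfg, 0), X[tr], y[tr], X[tr], y[tr],
            RpropParams(epochs=400), seed=0,
        )
        imp = permute_importance(
            res.best_model, tiny_dataset(X[~tr], y[~tr]), ImportanceConfig(seed=3)
        )
        assert imp.reference_accuracy < 0.5  # the distractor misleads
        assert imp.delta_pacc[3] > 0  # accuracy increases -> -dPAcc negative
        assert 3 in imp.distractors

    def test_importance_ranking_follows_planted_effect_sizes(self, rng):
        # hand-built linear readout over 20 orthogonal features with graded
        # weights; mean dMSE rank over 100 permutation repetitions must track
        # the planted ranking (Spearman >= 0.8)
        n_feat, n = 20, 100
        weights = np.linspace(0.1, 2.0, n_feat)
        cfg = MLPConfig(
            input_size=n_feat, output_size=2, hidden_sizes=(n_feat, 2),
            init_range=(-0.5, 0.5), dropout_p=0.0,
        )
        model = init_model(cfg, 0)
        # layer 1: identity pass-through (Soft++ is approx linear near 0)
        model.weights[0][:] = np.eye(n_feat) * 0.1
        model.biases[0][:] = 0.0
        # layer 2: weighted sum into two mirrored units
        model.weights[1][:] = np.vstack([weights, -weights])
        model.weights[2][:] = np.array([[4.0, -4.0], [-4.0, 4.0]])
        X = rng.standard_normal((n, n_feat))
        logits = X @ weights
        y = (logits < 0).astype(int)  # unit 0 wins when the weighted sum > 0
        imp = permute_importance(
            model, tiny_dataset(X, y),
            ImportanceConfig(n_permutations=100, seed=4),
        )
        rho = spearmanr(imp.delta_mse, weights).statistic
        assert rho >= 0.8


class TestReshapeToMap:
    def test_roundtrip_inverts_linearization(self, rng):
        ts = TileSpec(n_time_tiles=5, n_freq_tiles=4)
        vals = rng.standard_normal(20)
        imp = _map_with(vals, ts)
        mse_map, pacc_map = reshape_to_map(imp)
        assert mse_map.shape == (4, 5)
        np.testing.assert_array_equal(mse_map.reshape(-1), vals)
        np.testing.assert_array_equal(pacc_map, -imp.delta_pacc.reshape(4, 5))

    def test_eeg_geometry_map_shape(self, rng):
        imp = _map_with(rng.standard_normal(350), TileSpec(14, 25))
        mse_map, _ = reshape_to_map(imp)
        assert mse_map.shape == (25, 14)

    def test_geometry_mismatch_errors(self, rng):
        imp = _map_with(rng.standard_normal(10), TileSpec(5, 2))
        imp.delta_mse = imp.delta_mse[:8]
        with pytest.raises(ValueError, match="does not match"):
            reshape_to_map(imp)


def _map_with(vals, ts):
    from tfrinfo.importance import ImportanceMap

    return ImportanceMap(
        delta_mse=vals.copy(),
        delta_pacc=vals.copy(),
        set_sizes=np.ones(vals.size, dtype=int),
        reference_accuracy=1.0,
        reference_mse=0.0,
        tile_spec=ts,
    )
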