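"""Quantile forest: weights, quantile inversion, calibration, importances."""

import numpy as np
import pytest

from senspi.qrf import PredictionInterval, QuantileForest, QuantileForestResults, _Tree


def _one_leaf_results(y, X):
    """Forest of a single one-leaf tree over the full sample (no bootstrap)."""
    n = len(y)
    model = QuantileForest(y, X, n_trees=1, min_node_size=n, seed=0)
    tree = _Tree(
        children_left=np.array([-1]), children_right=np.array([-1]),
        feature=np.array([-2]), threshold=np.array([-2.0]),
        value=np.array([float(np.mean(y))]),
        bootstrap_idx=np.arange(n), oob_idx=np.array([], dtype=int),
    )
    tree.leaf_of_bootstrap = np.zeros(n, dtype=np.int64)
    tree.leaf_of_train = np.zeros(n, dtype=np.int64)
    return QuantileForestResults(model, [tree])


def _empirical_inf_quantile(y, tau):
    """inf{y_(i) : i/n >= tau} — the independent oracle."""
    ys = np.sort(y)
    n = len(ys)
    return ys[int(np.ceil(tau * n)) - 1]


class TestQuantileMachinery:
    def test_one_leaf_tree_equals_empirical_quantiles(self, rng):
        y = rng.standard_normal(97)
        X = rng.standard_normal((97, 2))
        res = _one_leaf_results(y, X)
        for tau in (0.05, 0.25, 0.5, 0.9, 0.95):
            assert res.conditional_quantile(X[0], tau) == _empirical_inf_quantile(y, tau)

    def test_weights_sum_to_one(self, rng):
        y = rng.standard_normal(120)
        X = rng.standard_normal((120, 4))
        res = QuantileForest(y, X, n_trees=30, seed=3).fit()
        W = res.weights(rng.standard_normal((15, 4)))
        assert np.allclose(W.sum(axis=1), 1.0, atol=1e-10)
        assert (W >= 0).all()

    def test_quantiles_monotone_in_tau(self, rng):
        y = rng.standard_normal(150)
        X = rng.standard_normal((150, 3))
        res = QuantileForest(y, X, n_trees=40, seed=4).fit()
        q = res.predict_quantiles(rng.standard_normal((20, 3)), [0.05, 0.5, 0.95])
        assert (np.diff(q, axis=1) >= 0).all()

    def test_quantiles_are_training_responses(self, rng):
        y = rng.standard_normal(80)
        X = rng.standard_normal((80, 2))
        res = QuantileForest(y, X, n_trees=25, seed=5).fit()
        q = res.predict_quantiles(X[:10], [0.1, 0.5, 0.9])
        assert np.isin(q, y).all()

    def test_invalid_tau_rejected(self, rng):
        y = rng.standard_normal(50)
        X = rng.standard_normal((50, 2))
        res = QuantileForest(y, X, n_trees=5, seed=6).fit()
        with pytest.raises(ValueError):
            res.predict_quantiles(X[:2], [0.0])

    def test_conditional_median_tracks_gaussian_mean(self):
        # y ~ N(x, 1); closed-form conditional median is x itself. Leaves
        # must be large for 1-D distributional estimation.
        rng = np.random.default_rng(0)
        n = 10000
        x = rng.uniform(-3, 3, n)[:, None]
        y = x[:, 0] + rng.standard_normal(n)
        res = QuantileForest(y, x, n_trees=300, min_node_size=200, seed=1).fit()
        grid = np.linspace(-1.5, 1.5, 31)[:, None]
        med = res.predict_quantiles(grid, [0.5])[:, 0]
        assert np.mean(np.abs(med - grid[:, 0])) < 0.15


class TestForestFitting:
    def test_same_seed_identical_forests(self, rng):
        y = rng.standard_normal(100)
        X = rng.standard_normal((100, 3))
        q1 = QuantileForest(y, X, n_trees=20, seed=9).fit().predict_quantiles(X[:5])
        q2 = QuantileForest(y, X, n_trees=20, seed=9).fit().predict_quantiles(X[:5])
        assert np.array_equal(q1, q2)

    def test_min_node_size_at_n_gives_single_leaf_trees(self, rng):
        y = rng.standard_normal(60)
        X = rng.standard_normal((60, 2))
        res = QuantileForest(y, X, n_trees=10, min_node_size=60, seed=10).fit()
        assert all(len(t.children_left) == 1 for t in res.trees)

    def test_informative_binary_feature_splits_first(self, rng):
        n = 200
        X = np.column_stack([
            (rng.random(n) > 0.5).astype(float),
            rng.standard_normal(n),
            rng.standard_normal(n),
        ])
        y = 5.0 * X[:, 0]  # deterministic step function
        res = QuantileForest(y, X, n_trees=100, mtry=3, seed=11).fit()
        root_feature = np.array([t.feature[0] for t in res.trees])
        assert (root_feature == 0).mean() >= 0.95

    def test_constant_response_warns(self, rng):
        X = rng.standard_normal((30, 2))
        with pytest.warns(UserWarning):
            QuantileForest(np.ones(30), X, n_trees=3, seed=12).fit()

    def test_missing_values_rejected(self, rng):
        X = rng.standard_normal((30, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            QuantileForest(rng.standard_normal(30), X)


class TestPredictionIntervals:
    def test_constant_response_zero_width_interval(self, rng):
        import warnings
        X = rng.standard_normal((40, 2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = QuantileForest(np.full(40, 3.5), X, n_trees=5, seed=13).fit()
        pi = res.prediction_interval(X[0], 0.10)
        assert isinstance(pi, PredictionInterval)
        assert pi.lower == pi.upper == 3.5

    def test_heteroscedastic_widths_grow_with_x(self):
        from scipy.stats import spearmanr
        rng = np.random.default_rng(2)
        n = 4000
        x = rng.uniform(0.5, 3.0, n)[:, None]
        y = rng.standard_normal(n) * x[:, 0]
        res = QuantileForest(y, x, n_trees=200, min_node_size=40, seed=14).fit()
        grid = np.linspace(0.8, 2.7, 25)[:, None]
        q = res.prediction_interval(grid, 0.10)
        widths = q[:, 1] - q[:, 0]
        assert spearmanr(grid[:, 0], widths).statistic > 0.8

    def test_coverage_calibrated_on_held_out_data(self):
        # iid homoscedastic cohorts; nominal 90% interval
        from senspi.synth import (SynthConfig, assign_latent_classes,
                                  generate_exposures, generate_traits)
        covs = []
        for seed in (0, 1, 2):
            cfg = SynthConfig(n_subjects=5000, n_exposures=10,
                              prop_sensitive=0.0, prop_resilient=0.0, seed=seed)
            r = np.random.default_rng(seed)
            X, _ = generate_exposures(cfg, r)
            latent = assign_latent_classes(cfg, r)
            y = generate_traits(X, latent, cfg, r)
            res = QuantileForest(y[:2500], X[:2500], n_trees=300, seed=seed).fit()
            pis = res.prediction_interval(X[2500:], 0.10)
            covs.append(((y[2500:] >= pis[:, 0]) & (y[2500:] <= pis[:, 1])).mean())
        assert all(0.87 <= c <= 0.93 for c in covs)


class TestImportance:
    def _forest(self, rng, informative=True):
        n = 400
        X = rng.standard_normal((n, 4))
        y = (2.0 * X[:, 0] if informative else np.zeros(n)) + rng.standard_normal(n)
        return QuantileForest(y, X, n_trees=80, seed=15).fit()

    def test_informative_feature_ranks_first_on_both_measures(self, rng):
        imp = self._forest(rng).variable_importance(seed=0)
        assert imp["pct_inc_mse"].idxmax() == "x0"
        assert imp["inc_node_purity"].idxmax() == "x0"

    def test_noise_features_near_zero_pct_inc_mse(self, rng):
        vals = []
        for s in range(5):
            imp = self._forest(rng).variable_importance(seed=s)
            vals.extend(imp.loc[["x1", "x2", "x3"], "pct_inc_mse"])
        assert abs(np.mean(vals)) < 2.0

    def test_permuted_response_kills_all_importances(self, rng):
        res = self._forest(rng, informative=False)
        imp = res.variable_importance(seed=1)
        assert np.abs(imp["pct_inc_mse"]).max() < 5.0

    def test_node_purity_nonnegative(self, rng):
        imp = self._forest(rng).variable_importance(seed=2)
        assert (imp["inc_node_purity"] >= 0).all()


class TestSerialization:
    def test_json_roundtrip_preserves_quantiles(self, rng, tmp_path):
        y = rng.standard_normal(90)
        X = rng.standard_normal((90, 3))
        res = QuantileForest(y, X, n_trees=15, seed=16).fit()
        path = tmp_path / "forest.json"
        res.to_json(path)
        res2 = QuantileForestResults.from_json(path, X)
        Xq = rng.standard_normal((12, 3))
        assert np.array_equal(res.predict_quantiles(Xq), res2.predict_quantiles(Xq))
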