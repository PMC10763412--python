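"""Splits, R^2, the MLP estimator and repeated/ablation evaluation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.preprocessing import StandardScaler

from polyutr import (
    AbundanceRegressor,
    Dataset,
    ablation_evaluation,
    cross_validate,
    load_bundle,
    make_split,
    r_squared,
    repeated_evaluation,
    save_bundle,
    train_mlp,
)
from polyutr.features import FEATURE_NAMES

SMALL_NET = dict(hidden_layer_sizes=(30,), max_iter=400, n_iter_no_change=20)


def _linear_data(n=500, m=15, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, m))
    w = rng.normal(size=m)
    y = X @ w + noise * rng.normal(size=n)
    return X, 2.0 ** y  # positive abundance, log2-linear


class TestMakeSplit:
    def test_full_library_split_sizes(self):
        s = make_split(241, 0.2, seed=0)
        assert (s.train.size, s.test.size) == (193, 48)

    def test_small_split(self):
        s = make_split(10, 0.2, seed=1)
        assert (s.train.size, s.test.size) == (8, 2)

    def test_disjoint_exhaustive_deterministic(self):
        a, b = make_split(100, 0.2, seed=5), make_split(100, 0.2, seed=5)
        assert np.array_equal(a.train, b.train) and np.array_equal(a.test, b.test)
        assert np.array_equal(np.sort(np.concatenate([a.train, a.test])), np.arange(100))
        c = make_split(100, 0.2, seed=6)
        assert not np.array_equal(a.test, c.test)


class TestRSquared:
    def test_reference_values(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, y) == pytest.approx(1.0)
        assert r_squared(y, np.full(3, y.mean())) == pytest.approx(0.0)
        assert r_squared(y, np.array([1.0, 2.0, 4.0])) == pytest.approx(0.5)

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError):
            r_squared(np.ones(5), np.arange(5.0))


class TestAbundanceRegressor:
    def test_noiseless_linear_signal_is_learned(self):
        X, y = _linear_data(n=500, seed=3)
        split = make_split(500, 0.2, seed=0)
        est = AbundanceRegressor(random_state=0, **SMALL_NET)
        est.fit(X[split.train], y[split.train])
        assert est.score(X[split.test], y[split.test]) > 0.95

    def test_same_seed_identical_predictions(self):
        X, y = _linear_data(n=100, seed=4)
        p1 = AbundanceRegressor(random_state=9, **SMALL_NET).fit(X, y).predict(X)
        p2 = AbundanceRegressor(random_state=9, **SMALL_NET).fit(X, y).predict(X)
        assert np.array_equal(p1, p2)

    def test_scaler_fitted_on_training_rows_only(self):
        X, y = _linear_data(n=100, seed=5)
        split = make_split(100, 0.2, seed=0)
        est = AbundanceRegressor(random_state=0, **SMALL_NET)
        est.fit(X[split.train], y[split.train])
        assert est._scaler_fit_rows == split.train.size
        leaky = StandardScaler().fit(X)  # refit including test rows
        assert not np.allclose(leaky.mean_, est.scaler_.mean_)

    def test_predict_rejects_column_mismatch(self):
        X, y = _linear_data(n=50, m=15, seed=6)
        est = AbundanceRegressor(random_state=0, **SMALL_NET).fit(X, y)
        with pytest.raises(ValueError):
            est.predict(X[:, :14])

    def test_constant_rows_give_constant_output(self):
        X, y = _linear_data(n=50, seed=7)
        est = AbundanceRegressor(random_state=0, **SMALL_NET).fit(X, y)
        batch = np.tile(X[0], (8, 1))
        assert np.unique(est.predict(batch)).size == 1

    def test_row_permutation_permutes_outputs(self):
        X, y = _linear_data(n=50, seed=8)
        est = AbundanceRegressor(random_state=0, **SMALL_NET).fit(X, y)
        perm = np.random.default_rng(0).permutation(50)
        assert np.allclose(est.predict(X)[perm], est.predict(X[perm]))

    def test_log_target_requires_positive_abundance(self):
        X, _ = _linear_data(n=20, seed=9)
        with pytest.raises(ValueError):
            AbundanceRegressor(**SMALL_NET).fit(X, np.linspace(-1, 1, 20))

    def test_bundle_round_trip(self, tmp_path):
        X, y = _linear_data(n=80, seed=10)
        df = pd.DataFrame(X, columns=list(FEATURE_NAMES))
        ds = Dataset(X=df, y=y, ids=[str(i) for i in range(80)])
        split = make_split(80, 0.2, seed=2)
        est = train_mlp(ds, split, hidden_layer_sizes=(30,), seed=2, max_iter=300)
        save_bundle(est, tmp_path)
        loaded = load_bundle(tmp_path)
        assert np.allclose(loaded.predict(X), est.predict(X))
        assert np.array_equal(loaded.split_.test, split.test)


class TestCrossValidate:
    def test_single_point_grid_returned(self):
        X, y = _linear_data(n=60, seed=11)
        res = cross_validate(
            X, y, grid={"n_layers": [1], "units_per_layer": [20]},
            k=3, seed=0, max_iter=200,
        )
        assert res["best"]["n_layers"] == 1 and res["best"]["units_per_layer"] == 20

    def test_linear_ground_truth_beats_chance(self):
        X, y = _linear_data(n=80, seed=12)
        res = cross_validate(
            X, y, grid={"n_layers": [1], "units_per_layer": [30]},
            k=5, seed=1, max_iter=300,
        )
        assert res["best"]["mean_val_r2"] > 0

    def test_too_small_folds_rejected(self):
        X, y = _linear_data(n=8, seed=13)
        with pytest.raises(ValueError):
            cross_validate(X, y, grid={"n_layers": [1], "units_per_layer": [5]}, k=5)


class TestRepeatedEvaluation:
    def _dataset(self, n=90, seed=14):
        X, y = _linear_data(n=n, seed=seed, noise=0.3)
        df = pd.DataFrame(X, columns=list(FEATURE_NAMES))
        return Dataset(X=df, y=y, ids=[str(i) for i in range(n)])

    def test_repeated_seeds_identical_means_single_value(self):
        ds = self._dataset()
        rep = repeated_evaluation(ds, n_splits=2, seeds=[3, 3],
                                  hidden_layer_sizes=(20,), max_iter=200)
        assert rep.per_split[0]["r2_test"] == rep.per_split[1]["r2_test"]
        assert rep.mean_test_r2 == pytest.approx(rep.per_split[0]["r2_test"])

    def test_mean_invariant_under_seed_order(self):
        ds = self._dataset()
        a = repeated_evaluation(ds, seeds=[1, 2], hidden_layer_sizes=(20,), max_iter=200)
        b = repeated_evaluation(ds, seeds=[2, 1], hidden_layer_sizes=(20,), max_iter=200)
        assert a.mean_test_r2 == pytest.approx(b.mean_test_r2)

    def test_empty_ablation_matches_full_run(self):
        ds = self._dataset()
        full = repeated_evaluation(ds, seeds=[0], hidden_layer_sizes=(20,), max_iter=200)
        abl = ablation_evaluation(ds, dropped=(), seeds=[0],
                                  hidden_layer_sizes=(20,), max_iter=200)
        assert abl.mean_test_r2 == pytest.approx(full.mean_test_r2)

    def test_dropping_all_features_rejected(self):
        ds = self._dataset()
        with pytest.raises(ValueError):
            ablation_evaluation(ds, dropped=tuple(FEATURE_NAMES), seeds=[0])
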