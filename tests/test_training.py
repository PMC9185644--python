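"""Feature selection, grid search and side-model training."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import propgest as pg
from propgest.training import (
    GRID,
    TrainingConfig,
    _grid_points,
    grid_search,
    load_model,
    save_model,
    select_features,
    sweep_window_params,
    train_side,
)
from propgest.windowing import WindowParams


def _blobs(n_per_class=40, n_noise=10, seed=0):
    """3 well-separated classes on one informative feature + noise columns."""
    rng = np.random.default_rng(seed)
    y = np.repeat(["forward", "backward", "dance"], n_per_class)
    informative = np.concatenate(
        [rng.normal(mu, 0.3, n_per_class) for mu in (0.0, 5.0, 10.0)]
    )
    X = pd.DataFrame(
        {"signal__good": informative}
        | {f"signal__noise{i:02d}": rng.standard_normal(3 * n_per_class) for i in range(n_noise)}
    )
    return X, y


class TestSelectFeatures:
    def test_informative_feature_ranks_first(self):
        X, y = _blobs()
        ranked = select_features(X, y, 3)
        assert ranked[0] == "signal__good"
        # independent oracle: one-way ANOVA F computed directly
        groups = [X["signal__good"][y == c] for c in np.unique(y)]
        f_good = stats.f_oneway(*groups).statistic
        groups_noise = [X["signal__noise00"][y == c] for c in np.unique(y)]
        assert f_good > stats.f_oneway(*groups_noise).statistic

    def test_k_equal_to_total_keeps_everything(self):
        X, y = _blobs()
        assert set(select_features(X, y, X.shape[1])) == set(X.columns)

    def test_k_too_large_raises(self):
        X, y = _blobs()
        with pytest.raises(ValueError):
            select_features(X, y, X.shape[1] + 1)

    def test_duplicate_columns_break_ties_by_name(self):
        X, y = _blobs(n_noise=1)
        X = X.copy()
        X["signal__gooe"] = X["signal__good"]  # identical scores, later name
        ranked = select_features(X, y, 2)
        assert ranked == ["signal__good", "signal__gooe"]


class TestGridSearch:
    @pytest.mark.parametrize("algo,size", [("svm", 14), ("knn", 48), ("random_forest", 72)])
    def test_grid_sizes_are_products_of_value_lists(self, algo, size):
        assert len(_grid_points(algo)) == size

    def test_separable_blobs_reach_perfect_cv(self):
        X, y = _blobs()
        cfg = TrainingConfig(seed=0, nf_max=5)
        params, acc = grid_search(X, y, "svm", cfg)
        assert acc == 1.0
        assert set(params) == {"C", "kernel"}

    def test_result_invariant_to_grid_enumeration_order(self, monkeypatch):
        X, y = _blobs(seed=3)
        cfg = TrainingConfig(seed=0, nf_max=5)
        ref = grid_search(X, y, "svm", cfg)
        reversed_grid = {k: list(reversed(v)) for k, v in reversed(GRID["svm"].items())}
        monkeypatch.setitem(GRID, "svm", reversed_grid)
        assert grid_search(X, y, "svm", cfg) == ref

    def test_class_smaller_than_folds_is_configuration_error(self):
        X, y = _blobs(n_per_class=5)
        with pytest.raises(ValueError, match="fold"):
            grid_search(X, y, "svm", TrainingConfig(seed=0, nf_max=5))


class TestTrainSide:
    def test_training_is_deterministic(self, small_corpus):
        ds = pg.build_dataset(small_corpus, "right", "two-sensor", WindowParams(30, 5), seed=0)
        cfg = TrainingConfig(seed=0)
        a = train_side(ds, cfg, algos=("svm",))
        b = train_side(ds, cfg, algos=("svm",))
        assert (a.algorithm, a.params, a.selected_features) == (
            b.algorithm, b.params, b.selected_features
        )
        assert a.cv_accuracy == b.cv_accuracy
        X = ds.X.iloc[:20]
        assert np.array_equal(a.predict(X), b.predict(X))

    def test_model_metadata_and_selection_contract(self, small_corpus):
        ds = pg.build_dataset(small_corpus, "left", "two-sensor", WindowParams(30, 5), seed=0)
        model = train_side(ds, TrainingConfig(seed=0), algos=("svm",))
        assert model.side == "left"
        assert len(model.selected_features) == 30
        assert set(model.selected_features) <= set(ds.X.columns)
        assert 0 <= model.cv_accuracy <= 1
        assert 0 <= model.cv_accuracy_pooled <= 1

    def test_capping_features_at_30_costs_little_accuracy(self, small_corpus):
        # relative property: 30 univariate-selected features retain the
        # full feature set's accuracy within 5 percentage points
        ds = pg.build_dataset(small_corpus, "right", "two-sensor", WindowParams(30, 5), seed=0)
        full = train_side(ds, TrainingConfig(seed=0, nf_max=152), algos=("svm",))
        capped = train_side(ds, TrainingConfig(seed=0, nf_max=30), algos=("svm",))
        assert abs(full.cv_accuracy - capped.cv_accuracy) < 0.05

    def test_save_load_roundtrip_verifies_hash(self, small_corpus, tmp_path):
        ds = pg.build_dataset(small_corpus, "right", "two-sensor", WindowParams(30, 5), seed=0)
        model = train_side(ds, TrainingConfig(seed=0), algos=("svm",))
        path = tmp_path / "m.joblib"
        save_model(model, path)
        back = load_model(path)
        assert back.params == model.params
        assert back.selected_features == model.selected_features
        assert np.array_equal(back.predict(ds.X.iloc[:10]), model.predict(ds.X.iloc[:10]))

    def test_tampered_model_rejected(self, small_corpus, tmp_path):
        import joblib

        ds = pg.build_dataset(small_corpus, "right", "two-sensor", WindowParams(30, 5), seed=0)
        model = train_side(ds, TrainingConfig(seed=0), algos=("svm",))
        path = tmp_path / "m.joblib"
        save_model(model, path)
        payload = joblib.load(path)
        payload["meta"]["cv_accuracy"] = 1.0
        joblib.dump(payload, path)
        with pytest.raises(ValueError, match="hash"):
            load_model(path)


def test_window_sweep_has_one_row_per_combination(small_corpus):
    cfg = TrainingConfig(seed=0, window_sweep_w=(20, 30), window_sweep_s=(5,))
    table = sweep_window_params(small_corpus[:2], "right", "two-sensor", cfg, algos=("svm",))
    assert len(table) == 2  # 2 w values x 1 s value x 1 algorithm
    assert set(table.columns) >= {"algo", "w", "s", "cv_accuracy"}
    assert table["cv_accuracy"].between(0, 1).all()
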