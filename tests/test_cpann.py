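"""Tests for the counter-propagation network and its validation metrics."""

import numpy as np
import pandas as pd
import pytest

from fdbind import (
    GridSpec,
    InputError,
    TrainConfig,
    fit_metrics,
    fold_seed,
    loo_cv,
    predict,
    train_cpann,
    winner,
)


class TestTrainPredict:
    def test_single_object_lookup(self):
        X = pd.DataFrame([[0.4, 0.6]])
        y = pd.Series([0.3])
        model = train_cpann(X, y, GridSpec(2, 2), TrainConfig(epochs=60, seed=0))
        assert predict(model, [0.4, 0.6])[0] == pytest.approx(0.3, abs=1e-3)

    def test_single_neuron_absorbs_mean(self, rng):
        X = pd.DataFrame(rng.random((100, 3)))
        y = pd.Series(rng.random(100))
        model = train_cpann(X, y, GridSpec(1, 1), TrainConfig(epochs=100, seed=1))
        assert model.output_weights[0, 0] == pytest.approx(y.mean(), abs=0.05)

    def test_lookup_table_limit(self):
        # well-separated objects <= neurons, radius shrunk to 0: near recall
        X = pd.DataFrame(np.eye(8) * 0.9 + 0.05)
        y = pd.Series(np.linspace(0.1, 0.9, 8))
        model = train_cpann(
            X, y, GridSpec(3, 3),
            TrainConfig(epochs=1000, seed=2, radius_start=1, radius_end=0),
        )
        pred = predict(model, X).iloc[:, 0]
        assert fit_metrics(y, pred).r2 >= 0.99

    def test_predict_is_output_weight_of_winner(self, rng):
        X = pd.DataFrame(rng.random((20, 3)))
        y = pd.Series(rng.random(20))
        model = train_cpann(X, y, GridSpec(3, 3), TrainConfig(epochs=30, seed=3))
        for _ in range(25):
            x = rng.random(3)
            res = winner(model.som, x)
            expected = model.output_weights[model.som.grid.index(res.neuron), 0]
            assert predict(model, x)[0] == expected

    def test_predictions_take_at_most_n_neuron_values(self, rng):
        X = pd.DataFrame(rng.random((50, 3)))
        y = pd.Series(rng.random(50))
        model = train_cpann(X, y, GridSpec(2, 2), TrainConfig(epochs=20, seed=4))
        queries = pd.DataFrame(rng.random((200, 3)))
        assert predict(model, queries).iloc[:, 0].nunique() <= 4

    def test_predict_is_pure(self, rng):
        X = pd.DataFrame(rng.random((10, 3)))
        y = pd.Series(rng.random(10))
        model = train_cpann(X, y, GridSpec(2, 2), TrainConfig(epochs=10, seed=5))
        x = rng.random(3)
        assert predict(model, x)[0] == predict(model, x)[0]

    def test_row_mismatch_and_unnormalized_targets_error(self, rng):
        X = pd.DataFrame(rng.random((5, 2)))
        with pytest.raises(InputError):
            train_cpann(X, pd.Series(np.ones(4)), GridSpec(2, 2), TrainConfig())
        with pytest.raises(InputError, match="normaliz"):
            train_cpann(X, pd.Series([0.1, 0.5, 3.0, 0.2, 0.4]), GridSpec(2, 2), TrainConfig())


class TestFitMetrics:
    def test_perfect_fit(self):
        m = fit_metrics([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert m.r2 == pytest.approx(1.0)
        assert m.rmse == pytest.approx(0.0)

    def test_hand_computed_values(self):
        # obs [0,1,2], pred [0,1,5]: CC = 5/sqrt(2*14), RMSE = sqrt(3)
        m = fit_metrics([0, 1, 2], [0, 1, 5])
        assert m.r2 == pytest.approx(25.0 / 28.0, abs=1e-12)
        assert m.rmse == pytest.approx(np.sqrt(3.0), abs=1e-12)

    def test_r2_affine_invariant_rmse_not(self, rng):
        obs = rng.random(20)
        pred = obs + rng.normal(0, 0.1, 20)
        m1 = fit_metrics(obs, pred)
        m2 = fit_metrics(obs, 2.0 * pred + 1.0)
        assert m1.r2 == pytest.approx(m2.r2, abs=1e-12)
        assert m1.rmse != pytest.approx(m2.rmse)

    def test_constant_observed_errors(self):
        with pytest.raises(InputError):
            fit_metrics([1.0, 1.0, 1.0], [0.0, 0.5, 1.0])

    def test_too_few_pairs_error(self):
        with pytest.raises(InputError):
            fit_metrics([0.0, 1.0], [0.0, 1.0])


class TestLooCv:
    def test_equals_naive_fold_by_fold_oracle(self, rng):
        X = pd.DataFrame(rng.random((10, 3)), index=[f"c{i}" for i in range(10)])
        y = pd.Series(rng.random(10), index=X.index)
        grid = GridSpec(3, 3)
        cfg = TrainConfig(epochs=15, seed=21)
        cv = loo_cv(X, y, grid, cfg)
        for k in range(10):
            mask = np.ones(10, dtype=bool)
            mask[k] = False
            fold_cfg = TrainConfig(epochs=15, seed=fold_seed(21, k))
            model = train_cpann(X.iloc[mask], y.iloc[mask], grid, fold_cfg)
            expected = predict(model, X.iloc[k].to_numpy())[0]
            assert cv.predictions["predicted"].iloc[k] == expected

    def test_q2_not_optimistic_vs_training_r2(self):
        # held-out performance should not beat training fit on noisy data
        wins = 0
        for s in range(10):
            r = np.random.default_rng(3000 + s)
            X = pd.DataFrame(r.random((15, 2)))
            y = pd.Series(
                np.clip(X.iloc[:, 0] * 0.8 + r.normal(0, 0.15, 15), 0, 1)
            )
            grid, cfg = GridSpec(3, 3), TrainConfig(epochs=25, seed=s)
            model = train_cpann(X, y, grid, cfg)
            r2 = fit_metrics(y, predict(model, X).iloc[:, 0]).r2
            if loo_cv(X, y, grid, cfg).q2_cv <= r2:
                wins += 1
        assert wins >= 8

    def test_duplicated_dataset_has_twin_for_each_fold(self, rng):
        X0 = pd.DataFrame(rng.random((6, 3)))
        y0 = pd.Series(rng.random(6))
        X = pd.concat([X0, X0], ignore_index=True)
        y = pd.concat([y0, y0], ignore_index=True)
        grid, cfg = GridSpec(4, 4), TrainConfig(epochs=120, seed=8, radius_end=0)
        model = train_cpann(X, y, grid, cfg)
        r2 = fit_metrics(y, predict(model, X).iloc[:, 0]).r2
        cv = loo_cv(X, y, grid, cfg)
        assert cv.q2_cv >= r2 - 0.15

    def test_too_few_objects(self, rng):
        with pytest.raises(InputError):
            loo_cv(
                pd.DataFrame(rng.random((2, 2))),
                pd.Series([0.1, 0.9]),
                GridSpec(2, 2),
                TrainConfig(),
            )


class TestRegressionPower:
    def test_noiseless_monotone_function_is_learned(self, rng):
        n = 80
        X = pd.DataFrame(rng.random((n, 2)))
        y = X.iloc[:, 0] ** 2  # noiseless monotone function of one column
        model = train_cpann(X, y, GridSpec(10, 10), TrainConfig(epochs=100, seed=13))
        pred = predict(model, X).iloc[:, 0]
        assert fit_metrics(y, pred).r2 >= 0.95
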