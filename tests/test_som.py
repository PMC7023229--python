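"""Unit and property tests for the Kohonen map engine."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fdbind import (
    GridSpec,
    InputError,
    SOMModel,
    TrainConfig,
    map_objects,
    neighborhood_weight,
    normalize_columns,
    quantization_error,
    topo_distance,
    train_som,
    winner,
)


class TestNormalizeColumns:
    def test_min_max_endpoints(self):
        normed, _ = normalize_columns(pd.DataFrame({"a": [0.0, 5.0, 10.0]}))
        assert normed["a"].tolist() == [0.0, 0.5, 1.0]

    def test_constant_column_maps_to_half_and_is_flagged(self):
        normed, scaler = normalize_columns(pd.DataFrame({"a": [7.0, 7.0, 7.0]}))
        assert normed["a"].tolist() == [0.5, 0.5, 0.5]
        assert bool(scaler.constant["a"])

    def test_missing_cell_error_names_location(self):
        df = pd.DataFrame({"a": [1.0, np.nan]}, index=["r1", "r2"])
        with pytest.raises(InputError, match=r"r2.*'a'"):
            normalize_columns(df)

    def test_non_numeric_cell_error(self):
        df = pd.DataFrame({"a": [1.0, "x"]}, index=["r1", "r2"])
        with pytest.raises(InputError, match="non-numeric"):
            normalize_columns(df)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_round_trip_recovers_original(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.normal(0, 10, (6, 4)), columns=list("abcd"))
        df["const"] = 3.5
        normed, scaler = normalize_columns(df)
        back = scaler.inverse_transform(normed)
        pd.testing.assert_frame_equal(back, df, check_exact=False, atol=1e-12)


class TestGridAndNeighborhood:
    def test_topo_distance_values(self):
        g = GridSpec(5, 5)
        assert topo_distance(g, (2, 2), (2, 2)) == 0
        assert topo_distance(g, (0, 0), (2, 3)) == 3

    def test_topo_distance_symmetry(self, rng):
        g = GridSpec(6, 4)
        for _ in range(20):
            a = (int(rng.integers(6)), int(rng.integers(4)))
            b = (int(rng.integers(6)), int(rng.integers(4)))
            assert topo_distance(g, a, b) == topo_distance(g, b, a)

    def test_out_of_grid_errors(self):
        with pytest.raises(InputError):
            topo_distance(GridSpec(2, 2), (0, 0), (2, 0))

    @pytest.mark.parametrize(
        "d,r,expected", [(0, 2, 1.0), (3, 2, 0.0), (1, 1, 0.5)]
    )
    def test_neighborhood_weight_values(self, d, r, expected):
        assert neighborhood_weight(d, r) == pytest.approx(expected)

    @given(
        st.integers(0, 10),
        st.integers(0, 10),
        st.floats(0, 10, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_neighborhood_weight_monotonic(self, d1, d2, r):
        lo, hi = sorted((d1, d2))
        assert neighborhood_weight(hi, r) <= neighborhood_weight(lo, r)
        # non-decreasing in radius at fixed distance
        assert neighborhood_weight(d1, r + 1) >= neighborhood_weight(d1, r)

    def test_negative_inputs_error(self):
        with pytest.raises(InputError):
            neighborhood_weight(-1, 2)


def _random_model(rng, nx=4, ny=5, nf=3):
    return SOMModel(
        grid=GridSpec(nx, ny),
        weights=rng.random((nx * ny, nf)),
        feature_names=[f"f{i}" for i in range(nf)],
        train_config=TrainConfig(),
        trained=True,
    )


class TestWinner:
    def test_exact_weight_match(self, rng):
        model = _random_model(rng)
        flat = model.grid.index((2, 3))
        res = winner(model, model.weights[flat])
        assert res.neuron == (2, 3)
        assert res.distance == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle_on_100_instances(self, rng):
        for _ in range(100):
            model = _random_model(rng)
            x = rng.random(3)
            best = min(
                range(model.grid.n_neurons),
                key=lambda f: (np.linalg.norm(x - model.weights[f]), f),
            )
            assert model.grid.index(winner(model, x).neuron) == best

    def test_tie_breaks_to_smallest_row_major_index(self, rng):
        model = _random_model(rng)
        model.weights[model.grid.index((1, 1))] = model.weights[
            model.grid.index((3, 2))
        ] = np.array([0.5, 0.5, 0.5])
        res = winner(model, [0.5, 0.5, 0.5])
        assert res.neuron == (1, 1)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(InputError):
            winner(_random_model(rng), [0.1, 0.2])


class TestTraining:
    def test_single_point_single_neuron_converges(self):
        data = pd.DataFrame(np.tile([0.3, 0.7], (20, 1)))
        model = train_som(data, GridSpec(1, 1), TrainConfig(epochs=50, seed=0))
        assert np.allclose(model.weights[0], [0.3, 0.7], atol=1e-3)

    def test_two_clusters_two_neurons(self, rng):
        a = rng.normal(0.2, 0.02, (15, 3))
        b = rng.normal(0.8, 0.02, (15, 3))
        data = pd.DataFrame(np.clip(np.vstack([a, b]), 0, 1))
        model = train_som(
            data, GridSpec(2, 1), TrainConfig(epochs=80, seed=5, radius_start=1)
        )
        means = sorted(model.weights.mean(axis=1))
        assert means[0] == pytest.approx(0.2, abs=0.05)
        assert means[1] == pytest.approx(0.8, abs=0.05)
        neurons = {r.neuron for r in map_objects(model, data.iloc[:15])}
        neurons_b = {r.neuron for r in map_objects(model, data.iloc[15:])}
        assert neurons.isdisjoint(neurons_b)

    def test_seed_determinism(self, rng):
        data = pd.DataFrame(rng.random((30, 4)))
        g, cfg = GridSpec(3, 3), TrainConfig(epochs=20, seed=9)
        w1 = train_som(data, g, cfg).weights
        w2 = train_som(data, g, cfg).weights
        assert np.array_equal(w1, w2)
        w3 = train_som(data, g, TrainConfig(epochs=20, seed=10)).weights
        assert not np.array_equal(w1, w3)

    def test_unnormalized_data_rejected(self):
        with pytest.raises(InputError, match="normalize_columns"):
            train_som(pd.DataFrame([[0.1, 5.0]]), GridSpec(2, 2), TrainConfig())

    def test_objects_sharing_neurons_are_closer_than_cross_pairs(self, rng):
        # topology preservation on clustered data, averaged over 10 seeds
        wins = 0
        for s in range(10):
            r = np.random.default_rng(s)
            centers = r.random((4, 5)) * 0.8 + 0.1
            pts = np.clip(
                np.repeat(centers, 10, axis=0) + r.normal(0, 0.03, (40, 5)), 0, 1
            )
            data = pd.DataFrame(pts)
            model = train_som(data, GridSpec(3, 3), TrainConfig(epochs=40, seed=s))
            res = map_objects(model, data)
            same, cross = [], []
            for i in range(40):
                for j in range(i + 1, 40):
                    d = np.linalg.norm(pts[i] - pts[j])
                    (same if res[i].neuron == res[j].neuron else cross).append(d)
            if same and cross and np.mean(same) < np.mean(cross):
                wins += 1
        assert wins >= 9


class TestMappingAndQuantization:
    def test_own_weights_map_to_own_neurons(self, rng):
        model = _random_model(rng)
        res = map_objects(model, pd.DataFrame(model.weights))
        for k, r in enumerate(res):
            assert model.grid.index(r.neuron) == k
            assert r.distance == pytest.approx(0.0, abs=1e-12)

    def test_permutation_invariance(self, rng):
        model = _random_model(rng)
        data = pd.DataFrame(rng.random((12, 3)), index=[f"o{i}" for i in range(12)])
        first = {r.object_id: r.neuron for r in map_objects(model, data)}
        shuffled = data.sample(frac=1, random_state=1)
        second = {r.object_id: r.neuron for r in map_objects(model, shuffled)}
        assert first == second

    def test_quantization_error_is_mean_winner_distance(self, rng):
        model = _random_model(rng)
        data = pd.DataFrame(rng.random((15, 3)))
        res = map_objects(model, data)
        assert quantization_error(model, data) == pytest.approx(
            np.mean([r.distance for r in res])
        )

    def test_training_reduces_quantization_error(self):
        improved = 0
        for s in range(20):
            r = np.random.default_rng(1000 + s)
            centers = r.random((3, 4))
            pts = np.clip(
                np.repeat(centers, 12, axis=0) + r.normal(0, 0.05, (36, 4)), 0, 1
            )
            data = pd.DataFrame(pts)
            cfg = TrainConfig(epochs=30, seed=s)
            trained = train_som(data, GridSpec(3, 3), cfg)
            untrained = SOMModel(
                grid=GridSpec(3, 3),
                weights=np.random.default_rng(cfg.seed).random((9, 4)),
                feature_names=list(map(str, range(4))),
                train_config=cfg,
                trained=True,
            )
            if quantization_error(trained, data) <= quantization_error(untrained, data):
                improved += 1
        assert improved >= 18  # >= 90% of seeds

    def test_empty_data_errors(self, rng):
        with pytest.raises(InputError):
            quantization_error(_random_model(rng), pd.DataFrame(columns=[0, 1, 2]))
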