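import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uaeopt.anfis import (
    AnfisRegressor,
    AnfisState,
    TrainingConfig,
    firing_strengths,
    gaussian_membership,
    init_grid_partition,
    lse_consequents,
    predict_state,
    split_train_check,
    train,
)
from uaeopt.metrics import r_squared


def layer_by_layer_predict(state: AnfisState, x: np.ndarray) -> float:
    """Independent oracle: explicit five-layer evaluation with plain loops
    (fuzzify, product firing, normalize, weighted consequents, sum)."""
    d, n_rules = state.n_inputs, state.n_rules
    w = []
    for r in range(n_rules):
        strength = 1.0
        for j in range(d):
            i = state.rule_index[r, j]
            c, s = state.centers[j, i], state.sigmas[j, i]
            strength *= math.exp(-((x[j] - c) ** 2) / (2.0 * s**2))
        w.append(strength)
    total = sum(w)
    out = 0.0
    for r in range(n_rules):
        f = state.consequents[r, d]
        for j in range(d):
            f += state.consequents[r, j] * x[j]
        out += (w[r] / total) * f
    return out


def random_state_model(rng, d=None, m=None) -> AnfisState:
    d = d or rng.integers(1, 4)
    m = m or rng.integers(2, 4)
    centers = np.sort(rng.uniform(-2, 2, size=(d, m)), axis=1)
    sigmas = rng.uniform(0.3, 2.0, size=(d, m))
    rule_index = np.array(list(itertools.product(range(m), repeat=d)))
    consequents = rng.normal(size=(len(rule_index), d + 1))
    return AnfisState(centers, sigmas, rule_index, consequents)


class TestGridPartition:
    @pytest.mark.parametrize("d, m, n_rules", [(4, 3, 81), (1, 2, 2), (2, 3, 9)])
    def test_rule_count(self, d, m, n_rules):
        state = init_grid_partition([(-2.0, 2.0)] * d, m)
        assert state.n_rules == n_rules

    def test_centers_evenly_spaced(self):
        state = init_grid_partition([(0.0, 10.0)] * 2, 3)
        np.testing.assert_allclose(state.centers[0], [0.0, 5.0, 10.0])

    def test_m_below_two_rejected(self):
        with pytest.raises(ValueError):
            init_grid_partition([(-2.0, 2.0)], 1)

    def test_degenerate_domain_rejected(self):
        with pytest.raises(ValueError):
            init_grid_partition([(1.0, 1.0)], 3)


class TestMembership:
    def test_peak_is_one(self):
        assert gaussian_membership(1.5, 1.5, 0.7) == 1.0

    def test_one_sigma_value(self):
        assert gaussian_membership(2.0, 1.0, 1.0) == pytest.approx(
            math.exp(-0.5)
        )

    def test_monotone_tails(self):
        vals = gaussian_membership(np.array([0.0, 0.5, 1.0, 2.0]), 0.0, 1.0)
        assert np.all(np.diff(vals) < 0)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_membership(0.0, 0.0, 0.0)


class TestFiringStrengths:
    @given(st.lists(st.floats(-2, 2), min_size=2, max_size=2))
    @settings(max_examples=50, deadline=None)
    def test_normalized_weights_sum_to_one(self, x):
        state = init_grid_partition([(-2.0, 2.0)] * 2, 3)
        _, wbar = firing_strengths(state, np.array([x]))
        assert wbar.sum() == pytest.approx(1.0, abs=1e-12)

    def test_peak_rule_dominates_at_grid_node(self):
        state = init_grid_partition([(-2.0, 2.0)] * 2, 3)
        # grid node (center MF of each input) -> rule (1, 1) is maximal
        w, _ = firing_strengths(state, np.array([[0.0, 0.0]]))
        best = state.rule_index[np.argmax(w[0])]
        assert list(best) == [1, 1]

    def test_matches_per_rule_loop(self):
        rng = np.random.default_rng(0)
        state = random_state_model(rng, d=2, m=2)
        x = rng.uniform(-2, 2, size=2)
        w, _ = firing_strengths(state, x[None, :])
        for r in range(state.n_rules):
            expected = np.prod([
                math.exp(-((x[j] - state.centers[j, state.rule_index[r, j]]) ** 2)
                         / (2 * state.sigmas[j, state.rule_index[r, j]] ** 2))
                for j in range(2)
            ])
            assert w[0, r] == pytest.approx(expected, rel=1e-12)


class TestPredict:
    def test_single_rule_model_is_exactly_linear(self):
        # normalization forces the lone rule's weight to 1 everywhere
        state = AnfisState(
            centers=[[0.0]], sigmas=[[1.0]],
            rule_index=[[0]], consequents=[[2.0, 1.0]],
        )
        for x in (-5.0, 0.0, 1.7, 42.0):
            assert predict_state(state, [[x]])[0] == pytest.approx(2 * x + 1)

    def test_symmetric_model_predicts_symmetrically(self):
        state = init_grid_partition([(-2.0, 2.0)], 3)
        # even consequents: constant per rule, mirror-symmetric rule values
        state.consequents = np.array([[0.0, 1.0], [0.0, 5.0], [0.0, 1.0]])
        left = predict_state(state, [[-1.3]])[0]
        right = predict_state(state, [[1.3]])[0]
        assert left == pytest.approx(right, rel=1e-12)

    def test_oracle_equivalence_on_random_models(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            state = random_state_model(rng)
            x = rng.uniform(-2.5, 2.5, size=state.n_inputs)
            fast = predict_state(state, x[None, :])[0]
            slow = layer_by_layer_predict(state, x)
            assert fast == pytest.approx(slow, abs=1e-10)


class TestLseConsequents:
    def test_recovers_known_consequents(self):
        rng = np.random.default_rng(3)
        state = random_state_model(rng, d=2, m=2)
        true_consequents = state.consequents.copy()
        X = rng.uniform(-2, 2, size=(200, 2))
        y = predict_state(state, X)
        state.consequents = np.zeros_like(true_consequents)
        recovered = lse_consequents(state, X, y)
        np.testing.assert_allclose(recovered, true_consequents, atol=1e-8)

    def test_constant_targets_fit_exactly(self):
        state = init_grid_partition([(-2.0, 2.0)] * 2, 2)
        rng = np.random.default_rng(5)
        X = rng.uniform(-2, 2, size=(40, 2))
        state.consequents = lse_consequents(state, X, np.full(40, 3.25))
        np.testing.assert_allclose(predict_state(state, X), 3.25, atol=1e-9)

    def test_underdetermined_min_norm_interpolates(self):
        # 21 records, 81 rules -> 405 unknowns: the plain minimum-norm
        # solution has zero training residual but finite checking error
        state = init_grid_partition([(-2.0, 2.0)] * 4, 3)
        rng = np.random.default_rng(7)
        X = rng.uniform(-2, 2, size=(21, 4))
        y = rng.normal(size=21)
        state.consequents = lse_consequents(state, X, y, rcond=None)
        np.testing.assert_allclose(predict_state(state, X), y, atol=1e-8)
        check = predict_state(state, rng.uniform(-2, 2, size=(10, 4)))
        assert np.all(np.isfinite(check))

    def test_post_solve_optimality(self):
        # no random perturbation of the consequents lowers training SSE
        state = init_grid_partition([(-2.0, 2.0)] * 2, 2)
        rng = np.random.default_rng(11)
        X = rng.uniform(-2, 2, size=(50, 2))
        y = np.sin(X[:, 0]) + X[:, 1] ** 2
        state.consequents = lse_consequents(state, X, y)
        sse = np.sum((predict_state(state, X) - y) ** 2)
        for _ in range(20):
            trial = state.copy()
            trial.consequents = state.consequents + rng.normal(
                scale=1e-3, size=state.consequents.shape
            )
            assert np.sum((predict_state(trial, X) - y) ** 2) >= sse - 1e-12

    def test_non_finite_inputs_rejected(self):
        state = init_grid_partition([(-2.0, 2.0)], 2)
        with pytest.raises(ValueError):
            lse_consequents(state, [[np.nan]], [1.0])


class TestSplit:
    def test_30_rows_split_21_9(self):
        tr, ck = split_train_check(30, 0.7, seed=0)
        assert len(tr) == 21 and len(ck) == 9

    def test_disjoint_union(self):
        tr, ck = split_train_check(17, 0.7, seed=3)
        assert sorted(np.concatenate([tr, ck])) == list(range(17))

    def test_minimum_checking_size(self):
        tr, ck = split_train_check(2, 0.99, seed=0)
        assert len(tr) == 1 and len(ck) == 1

    def test_same_seed_same_partition(self):
        assert all(
            np.array_equal(a, b)
            for a, b in zip(split_train_check(30, 0.7, 5),
                            split_train_check(30, 0.7, 5))
        )

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_train_check(10, 1.5)


class TestTraining:
    def test_self_generated_surface_fit_after_first_epoch(self):
        # data sampled from a Sugeno surface the network can represent:
        # the hybrid LSE recovers it immediately
        rng = np.random.default_rng(21)
        teacher = random_state_model(rng, d=2, m=2)
        X = rng.uniform(-2, 2, size=(120, 2))
        y = predict_state(teacher, X)
        student = init_grid_partition([(-2.0, 2.0)] * 2, 2)
        student.centers = teacher.centers.copy()
        student.sigmas = teacher.sigmas.copy()
        trained, history = train(
            student, X, y, TrainingConfig(epochs=1, method="hybrid", seed=0)
        )
        assert history.train_rmse[0] < 1e-8

    def test_history_lengths_match_epochs(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(-2, 2, size=(30, 2))
        y = X[:, 0] - X[:, 1] ** 2
        state = init_grid_partition([(-2.0, 2.0)] * 2, 2)
        _, history = train(state, X, y, TrainingConfig(epochs=25, seed=0))
        assert len(history.train_rmse) == len(history.check_rmse) == 25

    def test_same_seed_reproduces_model(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(-2, 2, size=(30, 2))
        y = np.cos(X[:, 0]) * X[:, 1]
        runs = []
        for _ in range(2):
            state = init_grid_partition([(-2.0, 2.0)] * 2, 2)
            trained, _ = train(state, X, y, TrainingConfig(epochs=15, seed=9))
            runs.append(trained)
        np.testing.assert_array_equal(runs[0].consequents, runs[1].consequents)
        np.testing.assert_array_equal(runs[0].centers, runs[1].centers)

    def test_backprop_reduces_error(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(-2, 2, size=(60, 2))
        y = X[:, 0] + 0.5 * X[:, 1]
        state = init_grid_partition([(-2.0, 2.0)] * 2, 2)
        _, history = train(
            state, X, y, TrainingConfig(epochs=200, method="backprop", seed=0)
        )
        assert min(history.train_rmse) < history.train_rmse[0]

    def test_empty_table_rejected(self):
        state = init_grid_partition([(-2.0, 2.0)], 2)
        with pytest.raises(ValueError):
            train(state, np.empty((0, 1)), np.empty(0))


class TestRegressor:
    def test_parameter_recovery_two_input_surface(self):
        # noise-free samples of a representable Sugeno surface: held-out
        # RMSE far below the response scale
        rng = np.random.default_rng(8)
        teacher = init_grid_partition([(-2.0, 2.0)] * 2, 2)
        teacher.consequents = rng.normal(size=teacher.consequents.shape)
        X = rng.uniform(-2, 2, size=(500, 2))
        y = predict_state(teacher, X)
        est = AnfisRegressor(n_mfs=2, epochs=50,
                             domain=[(-2, 2), (-2, 2)], random_state=0)
        est.fit(X, y)
        Xh = rng.uniform(-2, 2, size=(200, 2))
        yh = predict_state(teacher, Xh)
        held_rmse = np.sqrt(np.mean((est.predict(Xh) - yh) ** 2))
        assert held_rmse < 1e-3

    def test_predict_before_fit_raises(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            AnfisRegressor().predict([[0.0, 0.0]])

    def test_sklearn_param_round_trip(self):
        est = AnfisRegressor(n_mfs=2, epochs=7)
        clone_params = est.get_params()
        est2 = AnfisRegressor(**clone_params)
        assert est2.get_params() == clone_params

    def test_auto_method_selects_by_checking_rmse(self):
        rng = np.random.default_rng(10)
        X = rng.uniform(-2, 2, size=(40, 2))
        y = X[:, 0] * X[:, 1]
        est = AnfisRegressor(n_mfs=2, epochs=20, method=None,
                             domain=[(-2, 2), (-2, 2)], random_state=1)
        est.fit(X, y)
        assert est.method_ in ("hybrid", "backprop")

    def test_json_round_trip_is_bit_faithful(self, tmp_path):
        rng = np.random.default_rng(12)
        X = rng.uniform(-2, 2, size=(30, 2))
        y = X[:, 0] - X[:, 1]
        est = AnfisRegressor(n_mfs=2, epochs=10,
                             domain=[(-2, 2), (-2, 2)], random_state=0)
        est.fit(X, y)
        path = tmp_path / "model.json"
        est.save(path)
        back = AnfisRegressor.load(path)
        np.testing.assert_array_equal(back.state_.consequents,
                                      est.state_.consequents)
        np.testing.assert_array_equal(back.state_.centers, est.state_.centers)
        np.testing.assert_array_equal(back.state_.sigmas, est.state_.sigmas)
        Xq = rng.uniform(-2, 2, size=(20, 2))
        np.testing.assert_array_equal(back.predict(Xq), est.predict(Xq))

    def test_surrogate_quality_on_quadratic_surface(
        self, trained_models, heldout_points
    ):
        # trained on the noise-free CCD + 3^4 augmentation grid, every
        # response surrogate explains >= 99 % of held-out variance
        from conftest import coded_to_actual

        coded, Yh = heldout_points
        Xh = coded_to_actual(coded)
        for k, (name, est) in enumerate(trained_models.items()):
            assert r_squared(est.predict(Xh), Yh[:, k]) >= 0.99
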