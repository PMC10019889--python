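"""Core network: SR retrieval, steady-state operations, learning rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import srnn
from srnn.envs import Walk
from srnn.model import RNNState, UnstableDynamicsError


class TestSRFromT:
    def test_zero_discount_identity(self):
        T = np.full((4, 4), 0.25)
        assert np.allclose(srnn.sr_from_T(T, 0.0).M, np.eye(4))

    def test_two_state_uniform_closed_form(self):
        T = np.array([[0.5, 0.5], [0.5, 0.5]])
        M = srnn.sr_from_T(T, 0.5).M
        assert np.allclose(M, [[1.5, 0.5], [0.5, 1.5]])

    def test_row_sums_geometric_series(self, ring20, forward_actions):
        T = srnn.true_transition_matrix(ring20, forward_actions)
        M = srnn.sr_from_T(T, 0.6).M
        assert np.allclose(M.sum(axis=1), 1 / (1 - 0.6))


class TestSteadyStates:
    def test_zero_gain_returns_input(self, rng):
        J = rng.normal(size=(5, 5))
        phi = rng.random(5)
        assert np.array_equal(srnn.steady_state_linear(J, 0.0, phi), phi)

    def test_retrieves_sr_row_from_transposed_T(self):
        T = np.array([[0.5, 0.5], [0.5, 0.5]])
        x = srnn.steady_state_linear(T.T, 0.5, np.array([1.0, 0.0]))
        assert np.allclose(x, [1.5, 0.5])

    def test_supercritical_gain_raises(self):
        J = 2 * np.eye(3)
        with pytest.raises(UnstableDynamicsError):
            srnn.steady_state_linear(J, 0.6, np.ones(3))

    def test_truncated_zero_terms_and_zero_J(self, rng):
        phi = rng.random(4)
        assert np.array_equal(srnn.steady_state_truncated(rng.normal(size=(4, 4)), 0.5, phi, 0), phi)
        assert np.array_equal(srnn.steady_state_truncated(np.zeros((4, 4)), 0.5, phi, 30), phi)

    @pytest.mark.parametrize("gamma", [0.3, 0.6, 0.9])
    def test_truncated_matches_closed_form_at_chosen_tmax(self, rng, gamma):
        J = rng.normal(0, 0.1, (12, 12))
        J *= 0.95 / np.abs(np.linalg.eigvals(J)).max()
        phi = rng.random(12)
        phi /= np.abs(phi).max()
        xc = srnn.steady_state_linear(J, gamma, phi)
        xt = srnn.steady_state_truncated(J, gamma, phi, srnn.choose_tmax(gamma))
        assert np.abs(xc - xt).max() < 1e-3

    def test_tanh_zero_J_returns_input(self, rng):
        phi = rng.random(6)
        assert np.allclose(srnn.steady_state_tanh(np.zeros((6, 6)), 0.8, phi, 1), phi)

    def test_tanh_matches_linear_in_small_activity_regime(self, rng):
        J = rng.normal(0, 0.05, (10, 10))
        phi = 0.01 * rng.random(10)
        xt = srnn.steady_state_tanh(J, 0.5, phi, 60)
        xl = srnn.steady_state_truncated(J, 0.5, phi, 60)
        assert np.abs(xt - xl).max() < 1e-3


class TestChooseTmax:
    @pytest.mark.parametrize(
        "gamma,tol,expected",
        [(0.5, 1e-4, 14), (0.9, 1e-4, 88), (0.5, 1.0, 1), (0.0, 1e-4, 1)],
    )
    def test_boundary_and_examples(self, gamma, tol, expected):
        assert srnn.choose_tmax(gamma, tol) == expected

    def test_gamma_one_rejected(self):
        with pytest.raises(ValueError):
            srnn.choose_tmax(1.0)


class TestWeightUpdate:
    def test_zero_previous_activity_no_change(self, rng):
        J = rng.normal(size=(5, 5))
        dJ = srnn.weight_update(J, rng.random(5), np.zeros(5), np.ones(5))
        assert np.all(dJ == 0)

    def test_single_one_hot_transition_writes_one_entry(self):
        n = 4
        dJ = srnn.weight_update(np.zeros((n, n)), np.eye(n)[2], np.eye(n)[1], np.ones(n))
        expected = np.zeros((n, n))
        expected[2, 1] = 1.0
        assert np.array_equal(dJ, expected)

    def test_fixed_point_at_empirical_distribution(self, ring20, forward_actions):
        # when column j already equals the conditional next-state distribution,
        # the expected update for that column vanishes
        T = srnn.true_transition_matrix(ring20, forward_actions).T
        J = T.T.copy()
        j = 3
        expected_dJ = np.zeros(20)
        for i in range(20):
            dJ = srnn.weight_update(J, np.eye(20)[i], np.eye(20)[j], 1.0)
            expected_dJ += T[j, i] * dJ[:, j]
        assert np.abs(expected_dJ).max() < 1e-12

    def test_eta_scales_columns(self, rng):
        J = rng.normal(size=(3, 3))
        x_t, x_p = rng.random(3), rng.random(3)
        eta = np.array([0.1, 0.5, 1.0])
        dJ = srnn.weight_update(J, x_t, x_p, eta)
        base = srnn.weight_update(J, x_t, x_p, 1.0)
        assert np.allclose(dJ, base * eta)


class TestUpdateTrace:
    def test_first_activation_full_rate(self):
        n_new, eta = srnn.update_trace(np.zeros(3), np.eye(3)[1], 1.0)
        assert eta[1] == 1.0
        assert eta[0] == 1.0  # zero-trace neurons keep the cap
        assert n_new[1] == 1.0

    def test_k_activations_give_inverse_count(self):
        n = np.zeros(2)
        for _ in range(5):
            n, eta = srnn.update_trace(n, np.array([1.0, 0.0]), 1.0)
        assert eta[0] == pytest.approx(1 / 5)

    def test_inactive_neuron_trace_unchanged(self):
        n = np.array([3.0, 2.0])
        n_new, _ = srnn.update_trace(n, np.array([0.0, 1.0]), 1.0)
        assert n_new[0] == 3.0


class TestStepLearn:
    def test_single_transition_one_shot(self):
        cfg = srnn.RNNConfig(gamma_B=0.0)
        state = RNNState.zeros(3)
        srnn.step_learn(state, np.eye(3)[0], cfg)
        srnn.step_learn(state, np.eye(3)[1], cfg)
        expected = np.zeros((3, 3))
        expected[1, 0] = 1.0
        assert np.allclose(state.J, expected)

    def test_zero_input_no_learning(self):
        cfg = srnn.RNNConfig(gamma_B=0.0)
        state = RNNState.zeros(3)
        srnn.step_learn(state, np.eye(3)[0], cfg)
        _, x = srnn.step_learn(state, np.zeros(3), cfg)
        assert np.all(state.J == 0) and np.all(x == 0)

    def test_learned_J_matches_empirical_T(self, ring20, forward_actions):
        walk = srnn.simulate_walk(ring20, forward_actions, 5400, seed=11)
        res = srnn.run_session(srnn.walk_inputs(walk), srnn.RNNConfig(gamma_B=0.0))
        emp = srnn.empirical_transition_matrix(walk)
        assert srnn.mae_matrix(res.state.J.T, emp.T) < 0.01


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    states=st.lists(st.integers(min_value=0, max_value=5), min_size=2, max_size=120),
)
def test_one_hot_learning_equals_empirical_T_exactly(states):
    """Strongest oracle: adaptive-rate learning at zero gain reproduces the
    empirical transition matrix exactly, stays included."""
    states = np.asarray(states)
    env = srnn.ring(6)
    walk = Walk(states, env)
    res = srnn.run_session(srnn.walk_inputs(walk), srnn.RNNConfig(gamma_B=0.0, lambda_=1.0))
    emp = srnn.empirical_transition_matrix(walk)
    assert np.abs(res.state.J.T - emp.T).max() <= 1e-9


class TestTraceCounting:
    def test_trace_counts_visits_one_hot(self, ring20, forward_actions):
        walk = srnn.simulate_walk(ring20, forward_actions, 300, seed=5)
        res = srnn.run_session(srnn.walk_inputs(walk), srnn.RNNConfig(gamma_B=0.0, lambda_=1.0))
        counts = np.bincount(walk.states, minlength=20)
        assert np.array_equal(res.state.n, counts)

    def test_column_sums_reach_one_after_departures(self, ring20, forward_actions):
        walk = srnn.simulate_walk(ring20, forward_actions, 600, seed=3)
        res = srnn.run_session(srnn.walk_inputs(walk), srnn.RNNConfig(gamma_B=0.0))
        departed = np.zeros(20, dtype=bool)
        departed[walk.states[:-1]] = True
        col_sums = res.state.J.sum(axis=0)
        assert np.allclose(col_sums[departed], 1.0)


class TestRetrieval:
    def test_exact_T_retrieves_sr_rows_at_any_gamma(self, ring20, forward_actions):
        T = srnn.true_transition_matrix(ring20, forward_actions)
        state = RNNState.zeros(20)
        state.J = np.asarray(T.T).T.copy()
        cfg = srnn.RNNConfig(gamma_B=0.0)
        for gamma_R in np.arange(0.1, 0.95, 0.1):
            M = srnn.sr_from_T(T, gamma_R).M
            for j in (0, 7, 19):
                x = srnn.step_retrieve(state, np.eye(20)[j], cfg, gamma_R=gamma_R)
                assert np.abs(x - M[j]).max() < 1e-6

    def test_zero_gain_identity_and_purity(self, rng):
        state = RNNState.zeros(4)
        state.J = rng.normal(0, 0.1, (4, 4))
        J_before = state.J.copy()
        phi = rng.random(4)
        x = srnn.step_retrieve(state, phi, srnn.RNNConfig(), gamma_R=0.0)
        assert np.array_equal(x, phi)
        srnn.step_retrieve(state, phi, srnn.RNNConfig(gamma_R=0.5))
        assert np.array_equal(state.J, J_before)


class TestRunSession:
    def test_all_retrieval_schedule_leaves_J_unchanged(self, ring20, forward_actions):
        walk = srnn.simulate_walk(ring20, forward_actions, 100, seed=1)
        X = srnn.walk_inputs(walk)
        res = srnn.run_session(X, srnn.RNNConfig(gamma_R=0.5), schedule=np.ones(len(X), dtype=int))
        assert np.all(res.state.J == 0)

    def test_empty_schedule_empty_outputs(self):
        res = srnn.run_session(np.zeros((0, 5)), srnn.RNNConfig())
        assert res.activity.shape[0] == 0
        assert res.log.empty

    def test_learn_then_retrieve_matches_high_gamma_sr(self, ring20, forward_actions):
        # learn at low gain for half the session, then read out the SR at 0.9;
        # the oracle is the SR of the learning phase's empirical T (the true-T
        # comparison is dominated by walk sampling noise, not the network)
        maes = []
        for seed in (0, 1, 2):
            walk = srnn.simulate_walk(ring20, forward_actions, 5400, seed=seed)
            X = srnn.walk_inputs(walk)
            half = len(X) // 2
            schedule = np.zeros(len(X), dtype=int)
            schedule[half:] = 1
            cfg = srnn.RNNConfig(gamma_B=0.4, gamma_R=0.9, trace_convention="include_current")
            res = srnn.run_session(X, cfg, schedule=schedule)
            emp = srnn.empirical_transition_matrix(Walk(walk.states[: half + 1], ring20))
            M = srnn.sr_from_T(emp, 0.9).M
            maes.append(np.abs(res.activity[half:] - M[walk.states[half:]]).mean())
        assert max(maes) < 0.05

    def test_mismatched_schedule_rejected(self):
        with pytest.raises(ValueError):
            srnn.run_session(np.zeros((10, 3)), srnn.RNNConfig(), schedule=np.zeros(5, dtype=int))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"gamma_B": 1.0},
            {"lambda_": 0.0},
            {"eta_static": 0.0},
            {"nonlinearity": "tanh", "dynamics": "closed_form"},
            {"lr_mode": "other"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            srnn.RNNConfig(**kwargs)
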