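import numpy as np
import pytest

from pcmotion import (
    DivergenceError,
    LearningParams,
    NetworkState,
    compute_errors,
    generate_rdk,
    objective,
    observed_velocity,
    predict_velocity,
    update_activities,
    update_weights,
)
from pcmotion.coding import init_state


def random_instance(seed, n=4, m=3, m2=None):
    """Small random network state + observation for oracle tests."""
    rng = np.random.default_rng(seed)
    m2 = m if m2 is None else m2
    mask = rng.random((n, m)) < 0.8
    mask[:, 0] = True  # keep at least one connection per object
    state = NetworkState(
        r1=rng.normal(size=(m, 2)),
        r2=rng.normal(size=(m2, 2)),
        U1=np.where(mask, rng.uniform(0.05, 0.95, size=(n, m)), 0.0),
        U2=rng.normal(size=(m, m2)),
        mask=mask,
    )
    v_obs = rng.normal(size=(n, 2))
    return state, v_obs


def numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp = x.copy(); xp[idx] += eps
        xm = x.copy(); xm[idx] -= eps
        g[idx] = (f(xp) - f(xm)) / (2 * eps)
    return g


class TestBasicOps:
    def test_observed_velocity_of_coherent_dots(self):
        stim = generate_rdk(n_dots=8, signal_ratio=1.0, duration=1.0, seed=0)
        v = observed_velocity(stim, 3)
        assert np.allclose(v, [[0.01, 0.0]] * 8)

    def test_observed_velocity_requires_previous_frame(self, rdk_small):
        with pytest.raises(ValueError):
            observed_velocity(rdk_small, 0)

    def test_predict_velocity_identity_weight(self):
        state = NetworkState(
            r1=np.array([[0.3, -0.1]]), r2=np.zeros((1, 2)),
            U1=np.array([[1.0]]), U2=np.eye(1), mask=np.ones((1, 1), bool),
        )
        assert np.allclose(predict_velocity(state), [[0.3, -0.1]])

    def test_predict_velocity_matches_hand_product(self):
        state = NetworkState(
            r1=np.array([[1.0, 2.0], [3.0, -1.0]]), r2=np.zeros((2, 2)),
            U1=np.array([[0.5, 0.25], [1.0, 0.0]]), U2=np.eye(2),
            mask=np.ones((2, 2), bool),
        )
        expected = np.array([[0.5 * 1 + 0.25 * 3, 0.5 * 2 + 0.25 * -1],
                             [1.0, 2.0]])
        assert np.allclose(predict_velocity(state), expected)

    def test_errors_vanish_at_fixed_point(self):
        state, _ = random_instance(0)
        state.r1 = state.U2 @ state.r2  # e1 = 0
        v_obs = predict_velocity(state)  # e0 = 0
        err = compute_errors(v_obs, state)
        assert np.allclose(err.e0, 0) and np.allclose(err.e1, 0)
        assert objective(v_obs, state) == pytest.approx(0.0)

    def test_objective_matches_direct_summation(self):
        state, v_obs = random_instance(1)
        err = compute_errors(v_obs, state)
        direct = 0.5 * (np.sum(err.e0 ** 2) + np.sum(err.e1 ** 2))
        assert objective(v_obs, state) == pytest.approx(direct, rel=1e-12)

    def test_objective_is_quadratic_in_e0(self):
        state, _ = random_instance(2)
        state.r1 = state.U2 @ state.r2
        v_hat = predict_velocity(state)
        e = np.ones_like(v_hat)
        assert objective(v_hat + 2 * e, state) == pytest.approx(
            4 * objective(v_hat + e, state))


class TestGradientOracles:
    """Analytic update directions vs central finite differences of E."""

    @pytest.mark.parametrize("seed", range(100))
    def test_activity_updates_descend_the_exact_gradient(self, seed):
        state, v_obs = random_instance(seed)
        params = LearningParams(gamma=1.0, eta=0.0, dt_int=1.0)
        new = update_activities(state, v_obs, params)
        step_r1 = new.r1 - state.r1
        step_r2 = new.r2 - state.r2

        def E_r1(r1):
            s = state.copy(); s.r1 = r1
            return objective(v_obs, s)

        def E_r2(r2):
            s = state.copy(); s.r2 = r2
            return objective(v_obs, s)

        g1 = numeric_grad(E_r1, state.r1)
        g2 = numeric_grad(E_r2, state.r2)
        assert np.allclose(step_r1, -g1, rtol=1e-5, atol=1e-7)
        assert np.allclose(step_r2, -g2, rtol=1e-5, atol=1e-7)

    @pytest.mark.parametrize("seed", range(100))
    def test_weight_update_descends_the_exact_gradient(self, seed):
        state, v_obs = random_instance(seed)
        err = compute_errors(v_obs, state)
        # Hebbian term before clipping/masking
        dU1 = err.e0 @ state.r1.T

        def E_U1(U1):
            s = state.copy()
            s.U1 = U1
            s.mask = np.ones_like(U1, dtype=bool)  # bypass mask validation
            return objective(v_obs, s)

        g = numeric_grad(E_U1, state.U1)
        assert np.allclose(dU1, -g, rtol=1e-5, atol=1e-7)

    def test_energy_descends_with_frozen_weights(self):
        # small-step activity relaxation must not increase E (100 instances)
        for seed in range(100):
            state, v_obs = random_instance(seed)
            params = LearningParams(gamma=1.0, eta=0.0, dt_int=1e-3)
            e_prev = objective(v_obs, state)
            for _ in range(20):
                state = update_activities(state, v_obs, params)
                e = objective(v_obs, state)
                assert e <= e_prev + 1e-12
                e_prev = e


class TestScalarRelaxationOracle:
    def test_matches_closed_form_linear_ode(self):
        # N = M = 1, u = 1, U2 = 0 freezes r2 and yields
        # dr1/dt = gamma((v - r1) - r1), so r1(t) = v/2 (1 - exp(-2 gamma t)).
        v = np.array([[0.8, -0.4]])
        gamma, dt = 3.0, 1e-4
        state = NetworkState(
            r1=np.zeros((1, 2)), r2=np.zeros((1, 2)),
            U1=np.array([[1.0]]), U2=np.zeros((1, 1)),
            mask=np.ones((1, 1), bool),
        )
        params = LearningParams(gamma=gamma, eta=0.0, dt_int=dt)
        steps = 5000
        for _ in range(steps):
            state = update_activities(state, v, params)
        t = steps * dt
        expected = v / 2 * (1 - np.exp(-2 * gamma * t))
        assert np.allclose(state.r1, expected, rtol=1e-3)


class TestWeightBoxing:
    def test_weights_stay_in_unit_box_and_on_mask(self, rng):
        state, v_obs = random_instance(11)
        params = LearningParams(gamma=0.5, eta=5.0, dt_int=0.05)
        for k in range(200):
            state = update_activities(state, v_obs, params)
            err = compute_errors(v_obs, state)
            state = update_weights(state, err, params)
            if k % 17 == 0:
                v_obs = rng.normal(size=v_obs.shape)
        assert np.all(state.U1 >= 0) and np.all(state.U1 <= 1)
        assert np.all(state.U1[~state.mask] == 0)

    def test_saturated_weight_stays_clipped(self):
        state = NetworkState(
            r1=np.array([[1.0, 0.0]]), r2=np.zeros((1, 2)),
            U1=np.array([[1.0]]), U2=np.eye(1), mask=np.ones((1, 1), bool),
        )
        err = compute_errors(np.array([[5.0, 0.0]]), state)  # positive gradient
        new = update_weights(state, err, LearningParams(gamma=1.0, eta=10.0, dt_int=1.0))
        assert new.U1[0, 0] == 1.0

    def test_zero_error_leaves_weights_unchanged(self):
        state, _ = random_instance(3)
        state.r1 = state.U2 @ state.r2
        v_obs = predict_velocity(state)
        err = compute_errors(v_obs, state)
        new = update_weights(state, err, LearningParams(gamma=1.0, eta=10.0, dt_int=1.0))
        assert np.array_equal(new.U1, state.U1)


class TestConvergenceOnCoherentInput:
    def test_shared_source_learns_common_velocity(self):
        # single shared source, all objects share one velocity
        n = 6
        mask = np.ones((n, 1), dtype=bool)
        state = init_state(mask, np.random.default_rng(0), weight_init=(0.2, 0.4))
        v = np.tile([0.5, -0.25], (n, 1))
        params = LearningParams(gamma=2.0, eta=2.0, dt_int=0.01)
        for _ in range(4000):
            state = update_activities(state, v, params)
            state = update_weights(state, compute_errors(v, state), params)
        assert np.allclose(predict_velocity(state), v, atol=1e-3)
        assert np.ptp(state.U1) < 1e-3  # weights agree across objects


def test_divergence_raises_named_error():
    state, v_obs = random_instance(5)
    params = LearningParams(gamma=1e12, eta=0.0, dt_int=1.0)
    with pytest.raises((DivergenceError, FloatingPointError)):
        for _ in range(50):
            state = update_activities(state, v_obs, params)
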