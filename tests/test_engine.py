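import numpy as np
import pandas as pd
import pytest

from pcmotion import (
    CoherentMotionModel,
    DivergenceError,
    LearningParams,
    ModelConfig,
    Stimulus,
    build_architecture,
    compute_errors,
    detected_direction,
    generate_rdk,
    run,
    update_activities,
    update_weights,
)


def tiny_stimulus(n=4, frames=6, dt=0.05, seed=0, common=(0.3, 0.1)):
    """n dots drifting with a common velocity plus small private offsets."""
    rng = np.random.default_rng(seed)
    start = rng.uniform(-1, 1, size=(n, 2))
    vel = np.tile(common, (n, 1)) + rng.normal(scale=0.02, size=(n, 2))
    t = np.arange(frames)[:, None, None] * dt
    positions = start[None] + vel[None] * t
    return Stimulus(positions, dt, ["dot"] * n, np.tile(common, (n, 1)),
                    meta={"generator": "tiny"})


class TestArchitecture:
    def test_three_object_mask_structure(self):
        mask, state = build_architecture(3)
        assert mask.shape == (3, 4)
        assert np.all(mask[:, 0])
        assert np.array_equal(mask[:, 1:], np.eye(3, dtype=bool))
        assert np.array_equal(state.mask, mask)

    def test_single_object(self):
        mask, _ = build_architecture(1)
        assert np.array_equal(mask, [[True, True]])

    @pytest.mark.parametrize("n", [1, 2, 5, 17])
    def test_row_sums_are_two(self, n):
        mask, _ = build_architecture(n)
        assert np.all(mask.sum(axis=1) == 2)

    def test_initial_state_respects_mask_and_box(self):
        _, state = build_architecture(5, ModelConfig(seed=3))
        assert np.all(state.U1 >= 0) and np.all(state.U1 <= 1)
        assert np.all(state.U1[~state.mask] == 0)
        assert np.allclose(state.r1, 0) and np.allclose(state.r2, 0)


class TestRunLoop:
    def test_determinism_bit_identical(self):
        stim = generate_rdk(n_dots=25, duration=3.0, seed=5)
        cfg = ModelConfig(seed=5)
        a, b = run(stim, cfg), run(stim, cfg)
        for field in ("shared_strength", "individual_strength", "activations",
                      "residual", "r_shared", "energy"):
            assert np.array_equal(getattr(a, field), getattr(b, field))

    def test_gate_off_equals_pure_predictive_coding(self):
        """With theta1 -> inf the structured engine must reproduce, step for
        step, a reference loop built from the dense network operations."""
        stim = tiny_stimulus(n=4, frames=6)
        cfg = ModelConfig(theta1=1e12, seed=9, inner_iters=10)
        trace = run(stim, cfg)

        learning, _ = cfg.resolve(stim)
        _, state = build_architecture(stim.n_dots, cfg)
        params = LearningParams(gamma=learning.gamma, eta=learning.eta,
                                inner_iters=cfg.inner_iters, dt_int=learning.dt_int)
        shared, individual = [], []
        for t in range(1, stim.n_frames):
            v_obs = (stim.positions[t] - stim.positions[t - 1]) / stim.dt
            for _ in range(params.inner_iters):
                state = update_activities(state, v_obs, params)
            state = update_weights(state, compute_errors(v_obs, state), params)
            shared.append(state.U1[:, 0].copy())
            individual.append(np.diag(state.U1[:, 1:]).copy())
        assert np.allclose(trace.shared_strength, shared, atol=1e-10)
        assert np.allclose(trace.individual_strength, individual, atol=1e-10)
        assert np.all(trace.activations == 0)

    def test_mirror_equivariance(self):
        stim = generate_rdk(n_dots=30, signal_ratio=0.6, duration=3.0, seed=2)
        mirrored = Stimulus(
            stim.positions * np.array([-1.0, 1.0]), stim.dt, stim.labels,
            stim.truth * np.array([-1.0, 1.0]), meta=dict(stim.meta),
        )
        cfg = ModelConfig(seed=2)
        a, b = run(stim, cfg), run(mirrored, cfg)
        assert np.allclose(a.r_shared[:, 0], -b.r_shared[:, 0], atol=1e-12)
        assert np.allclose(a.r_shared[:, 1], b.r_shared[:, 1], atol=1e-12)
        assert np.allclose(a.shared_strength, b.shared_strength, atol=1e-12)

    def test_static_stimulus_leaves_state_near_initialisation(self):
        positions = np.tile(np.array([[0.0, 0.0], [1.0, 0.0]]), (8, 1, 1))
        stim = Stimulus(positions, 0.05, ["a", "b"], np.zeros((2, 2)))
        trace = run(stim, ModelConfig(seed=1))
        assert np.abs(trace.residual).max() < 1e-9
        assert np.allclose(trace.shared_strength[-1], trace.shared_strength[0])

    def test_max_frames_caps_processing(self):
        stim = generate_rdk(n_dots=10, duration=5.0, seed=0)
        trace = run(stim, ModelConfig(max_frames=7))
        assert trace.n_frames == 7

    def test_divergence_names_frame(self):
        stim = tiny_stimulus()
        with pytest.raises((DivergenceError, FloatingPointError), match="frame"):
            run(stim, ModelConfig(gamma=1e15))

    def test_trace_schema_and_bounds(self, rdk_small):
        trace = run(rdk_small, ModelConfig(seed=0))
        assert trace.n_frames == rdk_small.n_frames - 1
        assert np.all(trace.shared_strength >= 0) and np.all(trace.shared_strength <= 1)
        assert np.all(trace.individual_strength >= 0) and np.all(trace.individual_strength <= 1)
        df = trace.to_frame()
        assert list(df.columns) == ["frame", "object", "label", "shared_strength",
                                    "individual_strength", "f", "residual",
                                    "r_shared_x", "r_shared_y"]
        assert len(df) == trace.n_frames * trace.n_objects


class TestDetectedDirection:
    def test_rightward_coherence_detected(self):
        stim = generate_rdk(n_dots=60, signal_ratio=0.8, duration=5.0, seed=4)
        trace = run(stim, ModelConfig(seed=4))
        d = detected_direction(trace)
        angle = np.degrees(np.arctan2(d[1], d[0]))
        assert abs(angle) < 15.0

    def test_mirrored_stimulus_detects_antiparallel(self):
        stim = generate_rdk(n_dots=60, signal_ratio=0.8, duration=5.0, seed=4)
        mirrored = Stimulus(stim.positions * np.array([-1.0, 1.0]), stim.dt,
                            stim.labels, stim.truth * np.array([-1.0, 1.0]))
        trace = run(mirrored, ModelConfig(seed=4))
        d = detected_direction(trace)
        assert d[0] < -0.9

    def test_zero_shared_source_is_undefined(self):
        positions = np.tile(np.array([[0.0, 0.0]]), (8, 1, 1))
        stim = Stimulus(positions, 0.05, ["a"], np.zeros((1, 2)))
        trace = run(stim, ModelConfig(seed=0, weight_init=(0.0, 0.0),
                                      weight_init_individual=(0.0, 0.0)))
        assert np.all(np.isnan(detected_direction(trace)))


class TestFullCoherence:
    def test_all_dots_share_and_individuals_vanish(self):
        stim = generate_rdk(n_dots=50, signal_ratio=1.0, duration=8.0, seed=2)
        res = CoherentMotionModel(stim, ModelConfig(seed=2)).fit()
        assert np.ptp(res.final_shared_strength) < 0.05
        assert res.final_individual_strength.max() < 0.05
        assert res.direction_error_deg() < 5.0


class TestModelResultsAPI:
    def test_fit_returns_results_with_summary(self, rdk_small):
        res = CoherentMotionModel(rdk_small, ModelConfig(seed=0)).fit()
        text = res.summary()
        assert "signal" in text and "noise" in text
        assert res.shared_strength.shape == res.individual_strength.shape
        conv = res.convergence(sustain_frames=5)
        assert conv.time_ms == conv.steps * rdk_small.dt * 1000.0

    def test_from_dataframe_matches_direct_run(self, rdk_small):
        T, N, _ = rdk_small.positions.shape
        df = pd.DataFrame({
            "frame": np.repeat(np.arange(T), N),
            "dot_id": np.tile(np.arange(N), T),
            "x": rdk_small.positions[..., 0].ravel(),
            "y": rdk_small.positions[..., 1].ravel(),
            "label": np.tile(np.asarray(rdk_small.labels, dtype=object), T),
        })
        model = CoherentMotionModel.from_dataframe(df, dt=rdk_small.dt,
                                                   config=ModelConfig(seed=0))
        res = model.fit()
        direct = CoherentMotionModel(rdk_small, ModelConfig(seed=0)).fit()
        assert np.allclose(res.shared_strength, direct.shared_strength)

    def test_config_echo_carries_resolved_parameters(self, rdk_small):
        trace = run(rdk_small, ModelConfig(seed=0))
        assert trace.config["resolved_theta1"] == pytest.approx(0.005, rel=1e-6)
        assert trace.config["dt_int"] == pytest.approx(0.001)
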