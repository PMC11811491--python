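"""Transition dynamics: attention, novelty gate, one-step update, fitting."""

import numpy as np
import pytest

from adaptint import (TransitionModel, TransitionParams, context_decay,
                      fit_transition, smoothness_penalty, transition_attention,
                      transition_step)


def random_params(d=3, m=4, seed=0, **kw):
    rng = np.random.default_rng(seed)
    return TransitionParams(
        state_map=rng.normal(size=(d, d)) * 0.5,
        state_bias=rng.normal(size=d) * 0.5,
        input_map=rng.normal(size=(d, m)) * 0.5,
        input_bias=rng.normal(size=d) * 0.5,
        attn_weights=rng.normal(size=(d, d + m)) * 0.5,
        attn_bias=rng.normal(size=d) * 0.5, **kw)


class TestTransitionAttention:
    def test_zero_params_uniform(self):
        p = TransitionParams.zeros(4, 3)
        np.testing.assert_allclose(
            transition_attention(np.ones(4), np.ones(3), p), 0.25)

    def test_bias_closed_form(self):
        p = TransitionParams.zeros(2, 3)
        p.attn_bias = np.array([np.log(2), 0.0])
        np.testing.assert_allclose(
            transition_attention(np.zeros(2), np.zeros(3), p), [2 / 3, 1 / 3])

    def test_stabilized_equals_naive_oracle(self):
        rng = np.random.default_rng(19)
        p = random_params(seed=19)
        for _ in range(50):
            z, x = rng.normal(size=3), rng.uniform(0, 1, 4)
            u = p.attn_weights @ np.concatenate([z, x]) + p.attn_bias
            naive = np.exp(u) / np.exp(u).sum()
            np.testing.assert_allclose(transition_attention(z, x, p), naive,
                                       atol=1e-12)

    def test_simplex_and_bias_shift_invariance(self):
        rng = np.random.default_rng(2)
        p = random_params(seed=2)
        z, x = rng.normal(size=3), rng.uniform(0, 1, 4)
        a = transition_attention(z, x, p)
        assert abs(a.sum() - 1.0) < 1e-9
        p2 = random_params(seed=2)
        p2.attn_bias = p.attn_bias + 7.5
        np.testing.assert_allclose(a, transition_attention(z, x, p2), atol=1e-9)


class TestContextDecay:
    def test_neutral_params_give_half(self):
        p = TransitionParams.zeros(2, 3, decay_c0=0.0, decay_c1=0.0)
        assert context_decay(np.ones(3), p) == pytest.approx(0.5)

    def test_large_c0_saturates_to_persistence(self):
        p = TransitionParams.zeros(2, 3, decay_c0=50.0)
        assert context_decay(np.ones(3), p, x_mean=np.zeros(3)) == pytest.approx(1.0)

    def test_strictly_decreasing_in_novelty(self):
        p = TransitionParams.zeros(2, 3, decay_c0=0.0, decay_c1=1.0)
        mean = np.zeros(3)
        vals = [context_decay(np.full(3, d), p, x_mean=mean)
                for d in np.linspace(0, 3, 20)]
        assert all(b < a for a, b in zip(vals, vals[1:]))
        assert all(0 < v < 1 for v in vals)


class TestTransitionStep:
    def test_full_persistence_reduces_to_state_map(self):
        p = random_params(seed=5, noise_scale=0.0)
        z, x = np.array([0.1, -0.2, 0.3]), np.full(4, 0.5)
        out = transition_step(z, x, p, delta=1.0, attention_override=np.ones(3))
        np.testing.assert_allclose(out, np.tanh(p.state_map @ z + p.state_bias),
                                   atol=1e-15)

    def test_zero_persistence_reduces_to_input_map(self):
        p = random_params(seed=5, noise_scale=0.0)
        z, x = np.array([0.1, -0.2, 0.3]), np.full(4, 0.5)
        out = transition_step(z, x, p, delta=0.0, attention_override=np.ones(3))
        np.testing.assert_allclose(out, p.input_map @ x + p.input_bias,
                                   atol=1e-15)

    def test_matches_straight_line_oracle(self):
        rng = np.random.default_rng(23)
        p = random_params(seed=23, noise_scale=0.0)
        z, x = rng.normal(size=3), rng.uniform(0, 1, 4)
        x_mean = rng.uniform(0, 1, 4)
        # independent one-expression re-derivation of the update
        dist = np.sqrt(((x - x_mean) ** 2).sum())
        delta = 1 / (1 + np.exp(-(p.decay_c0 - p.decay_c1 * dist)))
        u = p.attn_weights @ np.concatenate([z, x]) + p.attn_bias
        a = np.exp(u) / np.exp(u).sum()
        expected = a * (delta * np.tanh(p.state_map @ z + p.state_bias)
                        + (1 - delta) * (p.input_map @ x + p.input_bias))
        np.testing.assert_allclose(transition_step(z, x, p, x_mean=x_mean),
                                   expected, atol=1e-12)

    def test_pure_function_without_noise(self):
        p = random_params(seed=7, noise_scale=0.0)
        z, x = np.ones(3) * 0.2, np.ones(4) * 0.3
        np.testing.assert_array_equal(transition_step(z, x, p),
                                      transition_step(z, x, p))

    def test_long_run_bounded(self):
        # tanh-squashed state map keeps trajectories finite over 1e4 steps
        p = random_params(seed=9, noise_scale=0.0, attention_renorm="sum_to_D")
        rng = np.random.default_rng(9)
        z = np.zeros(3)
        for _ in range(10_000):
            z = transition_step(z, rng.uniform(0, 1, 4), p)
        assert np.all(np.isfinite(z)) and np.linalg.norm(z) < 1e3


class TestSmoothnessPenalty:
    def test_constant_trajectory_zero(self):
        assert smoothness_penalty([np.ones(3)] * 5, 2.0) == 0.0
        assert smoothness_penalty([np.ones(3)], 2.0) == 0.0

    def test_single_unit_jump(self):
        traj = [np.zeros(3), np.array([1.0, 0, 0])]
        assert smoothness_penalty(traj, 2.0) == pytest.approx(2.0)

    def test_loop_oracle(self):
        rng = np.random.default_rng(29)
        traj = rng.normal(size=(10, 3))
        acc = 0.0
        for i in range(9):
            acc += ((traj[i + 1] - traj[i]) ** 2).sum()
        assert smoothness_penalty(traj, 1.7) == pytest.approx(1.7 * acc,
                                                              abs=1e-12)

    def test_reversal_invariance_and_quadratic_scaling(self):
        rng = np.random.default_rng(1)
        traj = rng.normal(size=(8, 2))
        v = smoothness_penalty(traj, 1.0)
        assert smoothness_penalty(traj[::-1], 1.0) == pytest.approx(v)
        assert smoothness_penalty(3.0 * traj, 1.0) == pytest.approx(9.0 * v)


def _generate(true, n_sessions, n_steps, rng):
    trajs = []
    for _ in range(n_sessions):
        states = [np.zeros(true.n_latent)]
        cues = [rng.uniform(0, 1, true.n_cues)]
        for _ in range(n_steps - 1):
            x = rng.uniform(0, 1, true.n_cues)
            z = transition_step(states[-1], x, true, rng,
                                x_mean=np.mean(cues, axis=0))
            states.append(z)
            cues.append(x)
        trajs.append((np.array(states), np.array(cues)))
    return trajs


class TestFitTransition:
    def test_fixed_point_at_truth_without_noise(self):
        true = random_params(d=2, m=2, seed=31, noise_scale=0.0,
                             attention_renorm="sum_to_D")
        trajs = _generate(true, 5, 20, np.random.default_rng(0))
        res = fit_transition(trajs, true)
        assert res.final_loss == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.params.state_map, true.state_map,
                                   atol=1e-6)
        np.testing.assert_allclose(res.params.input_map, true.input_map,
                                   atol=1e-6)

    def test_loss_trace_monotone(self):
        true = random_params(d=2, m=3, seed=33, noise_scale=0.05,
                             attention_renorm="sum_to_D")
        trajs = _generate(true, 10, 15, np.random.default_rng(1))
        res = fit_transition(trajs, TransitionParams.zeros(
            2, 3, attention_renorm="sum_to_D"), max_iter=200)
        assert np.all(np.diff(res.loss_trace) <= 1e-15)
        assert res.final_loss <= res.loss_trace[0]

    def test_degenerate_data_flagged_not_crashed(self):
        z = np.tile([0.1, 0.2], (6, 1))
        x = np.tile([0.5, 0.5, 0.5], (6, 1))
        res = fit_transition([(z, x)], TransitionParams.zeros(2, 3))
        assert res.degenerate
        assert np.isfinite(res.final_loss)


class TestTransitionModelEstimator:
    def test_sklearn_protocol(self):
        from sklearn.base import clone
        m = TransitionModel(n_latent=2, n_cues=2, reg_lambda=0.1)
        params = m.get_params()
        assert params["reg_lambda"] == 0.1
        m2 = clone(m).set_params(reg_lambda=0.0)
        assert m2.get_params()["reg_lambda"] == 0.0

    def test_fit_predict_shapes(self):
        true = random_params(d=2, m=2, seed=2, noise_scale=0.02,
                             attention_renorm="sum_to_D")
        trajs = _generate(true, 8, 12, np.random.default_rng(3))
        m = TransitionModel(n_latent=2, n_cues=2,
                            attention_renorm="sum_to_D", max_iter=100).fit(trajs)
        pred = m.predict(trajs)
        assert pred.shape == (8 * 11, 2)
        assert np.all(np.isfinite(pred))


def test_transition_params_json_round_trip():
    p = random_params(seed=4, noise_scale=0.01, attention_renorm="max")
    q = TransitionParams.from_json(p.to_json())
    np.testing.assert_array_equal(p.state_map, q.state_map)
    np.testing.assert_array_equal(p.attn_weights, q.attn_weights)
    assert q.attention_renorm == "max" and q.noise_scale == 0.01
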