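"""Tabular TD policy: discretization, updates, exploration, closed loop."""

import numpy as np
import pytest

from adaptint import (CohortConfig, QTable, TransitionTuple, batch_update,
                      discounted_return, discretize_state, epsilon_greedy,
                      make_child_profile, run_adaptive_session, td_update)
from adaptint.policy import EpsilonSchedule, SessionError
from adaptint.simulator import ChildEnvironment


class TestDiscretizeState:
    def test_edges(self):
        assert discretize_state(None, 0.0, n_bins=5) == (0,)
        assert discretize_state(None, 1.0, n_bins=5) == (4,)
        assert discretize_state(None, 0.39, n_bins=5) == (1,)

    def test_out_of_range_clipped(self):
        assert discretize_state(None, -0.5, n_bins=5) == (0,)
        assert discretize_state(None, 1.5, n_bins=5) == (4,)

    def test_sign_code(self):
        key = discretize_state(np.array([0.5, -0.1, 0.2]), 0.5,
                               use_sign_code=True)
        assert key == (5, 0b101)

    def test_occupancy_uniform_for_uniform_scores(self, rng):
        from scipy import stats
        n = 10_000
        bins = np.zeros(10)
        for s in rng.uniform(0, 1, n):
            bins[discretize_state(None, s)[0]] += 1
        # uniform scores -> multinomial bin counts; chi-square GOF at 0.001
        assert stats.chisquare(bins).pvalue > 1e-3


class TestTdUpdate:
    def test_single_step_arithmetic(self):
        q = QTable(learn_rate_beta=0.5, discount_gamma=0.9)
        td_update(q, TransitionTuple((0,), "A", 1.0, (1,)), ["A", "B"])
        assert q.get((0,), "A") == pytest.approx(0.5)
        assert q.get((0,), "B") == 0.0  # untouched

    def test_degenerate_learning_rate_rejected(self):
        with pytest.raises(ValueError):
            QTable(learn_rate_beta=0.0)

    def test_fixed_point_of_self_loop(self):
        # constant reward 1, gamma 0.5 -> Q* = R / (1 - gamma) = 2
        q = QTable(learn_rate_beta=0.1, discount_gamma=0.5)
        t = TransitionTuple((0,), "A", 1.0, (0,))
        for _ in range(100_000):
            td_update(q, t, ["A"])
        assert q.get((0,), "A") == pytest.approx(2.0, abs=0.01)

    def test_bounded_by_rmax_over_one_minus_gamma(self, rng):
        q = QTable(learn_rate_beta=0.5, discount_gamma=0.9)
        arms = ["A", "B"]
        bound = 1.0 / (1 - 0.9)
        for _ in range(5000):
            t = TransitionTuple((int(rng.integers(4)),), arms[rng.integers(2)],
                                float(rng.uniform(-1, 1)),
                                (int(rng.integers(4)),))
            td_update(q, t, arms)
        assert max(abs(v) for v in q.values.values()) <= bound + 1e-9


class TestEpsilonGreedy:
    def test_pure_greedy(self, rng):
        q = QTable(epsilon=0.0)
        q.values[((0,), "A")] = 0.1
        q.values[((0,), "B")] = 0.9
        assert all(epsilon_greedy(q, (0,), ["A", "B"], rng) == "B"
                   for _ in range(100))

    def test_tie_breaks_to_lowest_index(self, rng):
        q = QTable(epsilon=0.0)
        assert epsilon_greedy(q, (0,), ["A", "B", "C"], rng) == "A"

    def test_full_exploration_uniform(self):
        rng = np.random.default_rng(0)
        q = QTable(epsilon=1.0)
        n = 100_000
        hits = sum(epsilon_greedy(q, (0,), ["A", "B"], rng) == "A"
                   for _ in range(n))
        assert abs(hits / n - 0.5) < 0.005

    def test_greedy_arm_frequency_formula(self):
        # greedy arm probability is (1 - eps) + eps / |I|
        rng = np.random.default_rng(1)
        q = QTable(epsilon=0.3)
        q.values[((0,), "B")] = 1.0
        n = 100_000
        hits = sum(epsilon_greedy(q, (0,), ["A", "B"], rng) == "B"
                   for _ in range(n))
        assert abs(hits / n - 0.85) < 0.005

    def test_empty_catalog_rejected(self, rng):
        with pytest.raises(ValueError):
            epsilon_greedy(QTable(), (0,), [], rng)


class TestDiscountedReturn:
    def test_closed_forms(self):
        assert discounted_return([1, 1, 1], 0.5) == pytest.approx(1.75)
        assert discounted_return([0.3, 0.9], 0.0) == pytest.approx(0.9)

    def test_loop_oracle(self):
        rng = np.random.default_rng(43)
        r = rng.uniform(-1, 1, 30)
        acc = 0.0
        for t in range(30):
            acc += 0.9 ** (29 - t) * r[t]
        assert discounted_return(r, 0.9) == pytest.approx(acc, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            discounted_return([], 0.9)


class TestBatchUpdate:
    def _random_batch(self, rng, n, keys=4):
        arms = ["A", "B"]
        return [TransitionTuple((int(rng.integers(keys)),),
                                arms[rng.integers(2)],
                                float(rng.uniform(-1, 1)),
                                (int(rng.integers(keys)),))
                for _ in range(n)]

    def test_singleton_equals_td_update(self, rng):
        t = TransitionTuple((0,), "A", 0.7, (1,))
        q1, q2 = QTable(), QTable()
        td_update(q1, t, ["A", "B"])
        batch_update(q2, [t], ["A", "B"])
        assert q1.values == q2.values

    def test_equals_sequential_fold_exactly(self):
        rng = np.random.default_rng(47)
        batch = self._random_batch(rng, 500)
        q1, q2 = QTable(), QTable()
        batch_update(q1, batch, ["A", "B"])
        for t in batch:
            td_update(q2, t, ["A", "B"])
        assert q1.values == q2.values

    def test_disjoint_keys_order_independent(self):
        rng = np.random.default_rng(5)
        batch = [TransitionTuple((i,), "A", float(rng.uniform()), (100 + i,))
                 for i in range(10)]
        ref = batch_update(QTable(), list(batch), ["A"]).values
        for _ in range(10):
            rng.shuffle(batch)
            assert batch_update(QTable(), list(batch), ["A"]).values == ref

    def test_empty_batch_noop(self):
        q = QTable()
        q.values[((0,), "A")] = 1.0
        assert batch_update(q, [], ["A"]).values == {((0,), "A"): 1.0}


class TestEpsilonSchedule:
    def test_decay_and_floor(self):
        s = EpsilonSchedule(0.3, 0.9, 0.05)
        assert s(0) == pytest.approx(0.3)
        assert s(1) == pytest.approx(0.27)
        assert s(1000) == 0.05


class TestRunAdaptiveSession:
    def test_same_seed_identical_logs(self, small_cohort_config):
        logs = []
        for _ in range(2):
            rng = np.random.default_rng(7)
            profile = make_child_profile(small_cohort_config, rng)
            session, _ = run_adaptive_session(profile, QTable(), 12, rng)
            logs.append(session)
        assert logs[0] == logs[1]

    def test_pretrained_greedy_prefers_best_arm(self, small_cohort_config):
        q = QTable()
        for b in range(10):
            q.values[((b,), "A")] = 10.0  # pre-trained toward the true best
        rng = np.random.default_rng(3)
        profile = make_child_profile(small_cohort_config, rng)
        session, _ = run_adaptive_session(profile, q, 200, rng, epsilon=0.0,
                                          learn=False)
        arms = [r.intervention for r in session.records
                if r.intervention is not None]
        assert arms and all(a == "A" for a in arms)

    def test_environment_failure_flushes_partial_log(self, small_cohort_config):
        class FailingEnv(ChildEnvironment):
            def __init__(self, profile, rng):
                super().__init__(profile, rng)
                self.count = 0

            def step(self, intervention=None, intensity=1.0):
                self.count += 1
                if self.count >= 3:
                    raise RuntimeError("sensor dropout")
                return super().step(intervention, intensity)

        rng = np.random.default_rng(0)
        profile = make_child_profile(small_cohort_config, rng)
        env = FailingEnv(profile, rng)
        with pytest.raises(SessionError) as err:
            run_adaptive_session(profile, QTable(), 20, rng, environment=env)
        assert len(err.value.partial_session.records) == 3
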