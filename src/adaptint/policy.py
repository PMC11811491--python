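"""Adaptive intervention selection by tabular temporal-difference learning.

The policy maintains a table of Q-values over discretized states (a uniform
score bin on [0, 1], optionally augmented with the sign pattern of the
latent state) and the finite intervention catalog.  After each intervened
step the touched entry moves toward the one-step TD target

    Q(s, j) <- Q(s, j) + beta * (R + gamma * max_j' Q(s', j') - Q(s, j))

Selection is epsilon-greedy: with probability epsilon a uniform draw over
the full catalog (the greedy arm included, so its selection probability is
(1 - eps) + eps / |I|), otherwise the argmax with lowest-index tie-breaking.
Exploration decays exponentially across training sessions,
eps_t = max(eps_min, eps_0 * d^t).

The closed loop (:func:`run_adaptive_session`) interleaves observation,
attention-based engagement scoring, confidence-gated epsilon-greedy
selection, intensity-scaled action, penalty-modified reward, and the TD
update, emitting a complete session log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ._common import DEFAULT_SCORE_BINS, discretize_score
from .adjustment import (AdjustmentConfig, AdjustmentState,
                         intervention_probability)
from .rewards import RewardConfig, immediate_reward, modified_reward
from .scoring import EngagementScorer
from .sessions import Session, SessionRecord
from .simulator import ChildEnvironment, CohortConfig, make_child_profile
from ._common import child_seed

logger = logging.getLogger("adaptint")

__all__ = [
    "QTable", "TransitionTuple", "EpsilonSchedule", "discretize_state",
    "td_update", "epsilon_greedy", "discounted_return", "batch_update",
    "run_adaptive_session", "q_learn_mdp", "engagement_mdp", "TDPolicy",
    "SessionError",
]


class SessionError(RuntimeError):
    """Environment failure mid-session; carries the partial log."""

    def __init__(self, msg, partial_session):
        super().__init__(msg)
        self.partial_session = partial_session


def discretize_state(z, s: float, n_bins: int = DEFAULT_SCORE_BINS,
                     use_sign_code: bool = False) -> tuple:
    """Deterministic tabular key for a (latent state, score) pair.

    The key is the uniform score bin of clip(s, 0, 1); when
    ``use_sign_code`` is set, the sign pattern of z (one bit per latent
    component) is appended, giving up to 2^D cells per score bin.
    """
    b = discretize_score(s, n_bins)
    if not use_sign_code:
        return (b,)
    zv = np.asarray(z, dtype=float)
    code = int(sum(1 << k for k, v in enumerate(zv) if v > 0))
    return (b, code)


@dataclass
class QTable:
    """Tabular state-action values plus the TD hyperparameters.

    learn_rate_beta in (0, 1]; discount_gamma in [0, 1); epsilon in [0, 1];
    default_q is the cold-start value for unseen (state, intervention) pairs.
    """

    learn_rate_beta: float = 0.1
    discount_gamma: float = 0.9
    epsilon: float = 0.3
    default_q: float = 0.0
    values: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 < self.learn_rate_beta <= 1.0:
            raise ValueError("learn_rate_beta must be in (0, 1]")
        if not 0.0 <= self.discount_gamma < 1.0:
            raise ValueError("discount_gamma must be in [0, 1)")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must be in [0, 1]")

    def get(self, state, intervention) -> float:
        return self.values.get((state, intervention), self.default_q)

    def best(self, state, catalog):
        """(argmax intervention, max Q) with lowest-index tie-breaking."""
        best_j, best_q = None, -np.inf
        for j in catalog:
            q = self.get(state, j)
            if q > best_q:
                best_j, best_q = j, q
        return best_j, best_q

    def to_json(self) -> str:
        items = sorted(((repr(k), v) for k, v in self.values.items()))
        return json.dumps({
            "schema": "adaptint.qtable.v1",
            "learn_rate_beta": self.learn_rate_beta,
            "discount_gamma": self.discount_gamma,
            "epsilon": self.epsilon,
            "default_q": self.default_q,
            "values": items,
        }, indent=1)


@dataclass
class TransitionTuple:
    """One TD experience (state key, intervention, reward, next state key)."""

    state: tuple
    intervention: object
    reward: float
    next_state: tuple

    def __post_init__(self):
        if not np.isfinite(self.reward):
            raise ValueError("reward must be finite")


@dataclass
class EpsilonSchedule:
    """Exponentially decaying exploration eps_t = max(eps_min, eps_0 * d^t)."""

    epsilon_0: float = 0.3
    decay: float = 0.999
    epsilon_min: float = 0.05

    def __call__(self, t: int) -> float:
        return max(self.epsilon_min, self.epsilon_0 * self.decay ** t)


def td_update(q: QTable, t: TransitionTuple, catalog) -> QTable:
    """One TD(0) correction of the touched entry; other entries untouched."""
    cur = q.get(t.state, t.intervention)
    _, next_best = q.best(t.next_state, catalog)
    target = t.reward + q.discount_gamma * next_best
    q.values[(t.state, t.intervention)] = cur + q.learn_rate_beta * (target - cur)
    return q


def epsilon_greedy(q: QTable, state, catalog, rng, epsilon: float | None = None):
    """Epsilon-greedy selection over the catalog.

    With probability epsilon a uniform draw over the *full* catalog (the
    greedy arm included); otherwise argmax Q with lowest-index tie-breaking.
    """
    arms = list(catalog)
    if not arms:
        raise ValueError("intervention catalog is empty")
    eps = q.epsilon if epsilon is None else epsilon
    if rng.random() < eps:
        return arms[rng.integers(len(arms))]
    return q.best(state, arms)[0]


def discounted_return(rewards, discount_gamma: float) -> float:
    """G = sum_{t=1..i} gamma^(i-t) * R_t (recent rewards weigh most)."""
    r = np.asarray(rewards, dtype=float)
    if r.size == 0:
        raise ValueError("discounted_return requires at least one reward")
    if not np.all(np.isfinite(r)):
        raise ValueError("rewards must be finite")
    powers = discount_gamma ** np.arange(r.size - 1, -1, -1)
    return float(np.dot(powers, r))


def batch_update(q: QTable, batch, catalog) -> QTable:
    """Mini-batch TD: applies td_update sequentially in batch order.

    Exactly equal to folding td_update over the batch; an empty batch is a
    warned no-op.
    """
    if not batch:
        logger.warning("batch_update called with an empty batch; no-op")
        return q
    for t in batch:
        td_update(q, t, catalog)
    return q


# ------------------------------------------------------------- closed loop

def run_adaptive_session(profile, q: QTable, n: int, rng,
                         scorer: EngagementScorer | None = None,
                         reward_cfg: RewardConfig | None = None,
                         adj_cfg: AdjustmentConfig | None = None,
                         epsilon: float | None = None,
                         learn: bool = True,
                         environment: ChildEnvironment | None = None):
    """Run one child through the full adaptive loop for ``n`` interactions.

    Per step: observe cues -> attention-based engagement score -> confidence
    over the rolling window gates whether to intervene -> epsilon-greedy arm
    selection -> act at the smoothed intensity -> penalty-modified immediate
    reward -> TD update (when ``learn``) and intensity adaptation.  Returns
    (Session, QTable); the table is updated in place.  An environment
    failure mid-session raises :class:`SessionError` with the partial log.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    env = environment if environment is not None else ChildEnvironment(profile, rng)
    catalog = list(env.profile.intervention_effects)
    scorer = scorer if scorer is not None else EngagementScorer()
    reward_cfg = reward_cfg if reward_cfg is not None else RewardConfig()
    adj_cfg = adj_cfg if adj_cfg is not None else AdjustmentConfig()
    adj = AdjustmentState(cfg=adj_cfg, interventions=catalog)

    records = []
    try:
        x, _ = env.reset()
        s = float(scorer.fit(x[None, :]).transform(x[None, :])[0])
        for t in range(n):
            adj.push_engagement(s)
            c = adj.current_confidence()
            key = discretize_state(None, s)
            arm, intensity = None, None
            if rng.random() < intervention_probability(c, adj_cfg):
                arm = epsilon_greedy(q, key, catalog, rng, epsilon=epsilon)
                intensity = adj.applied_intensity(arm)
            records.append(SessionRecord(t=float(t), x=x, intervention=arm,
                                         engagement=s, confidence=c,
                                         intensity=intensity))
            if t == n - 1:
                break
            x, _ = env.step(arm, intensity if intensity is not None else 1.0)
            s_next = float(scorer.transform(x[None, :])[0])
            if arm is not None:
                delta = s_next - s
                r = modified_reward(immediate_reward(s_next, s, reward_cfg),
                                    delta, reward_cfg)
                if learn:
                    td_update(q, TransitionTuple(key, arm, r,
                                                 discretize_state(None, s_next)),
                              catalog)
                adj.record_outcome(arm, delta, c)
            s = s_next
    except Exception as exc:  # flush the partial log before propagating
        partial = Session(child_id=env.profile.child_id, records=records)
        raise SessionError(f"environment failure mid-session: {exc}", partial) from exc
    return Session(child_id=env.profile.child_id, records=records), q


# --------------------------------------------------- finite-MDP utilities

def engagement_mdp(cfg: CohortConfig, n_bins: int = DEFAULT_SCORE_BINS,
                   baseline: float = 0.5, carryover: float = 0.7,
                   noise_sd: float = 0.02, reward_cfg: RewardConfig | None = None):
    """Finite MDP over score bins derived from the simulator dynamics.

    States are the ``n_bins`` uniform engagement bins (represented by their
    centers); actions are the intervention catalog.  The transition kernel
    integrates the Gaussian AR(1) step over the bin edges (out-of-range mass
    is absorbed into the edge bins, mirroring the simulator's clipping) and
    the reward table is the deterministic immediate reward evaluated at the
    expected next engagement.  Returns (P, R) with P of shape
    (n_bins, n_arms, n_bins) and R of shape (n_bins, n_arms).
    """
    reward_cfg = reward_cfg if reward_cfg is not None else RewardConfig(penalty_lambda=0.0)
    arms = list(cfg.interventions)
    effects = [cfg.best_effect if j == cfg.best_intervention else cfg.other_effect
               for j in arms]
    centers = (np.arange(n_bins) + 0.5) / n_bins
    edges = np.arange(n_bins + 1) / n_bins
    P = np.zeros((n_bins, len(arms), n_bins))
    R = np.zeros((n_bins, len(arms)))
    for b, e0 in enumerate(centers):
        for a, eff in enumerate(effects):
            mean = carryover * e0 + (1.0 - carryover) * baseline + eff
            cdf = stats.norm.cdf(edges, loc=mean, scale=noise_sd)
            p = np.diff(cdf)
            p[0] += cdf[0]
            p[-1] += 1.0 - cdf[-1]
            P[b, a] = p / p.sum()
            e_next = float(np.clip(mean, 0.0, 1.0))
            R[b, a] = immediate_reward(e_next, e0, reward_cfg)
    return P, R


def q_learn_mdp(P, R, n_steps: int, rng, learn_rate_beta: float = 0.1,
                discount_gamma: float = 0.9, epsilon: float = 0.2,
                episode_len: int = 5) -> QTable:
    """Tabular Q-learning on a known finite MDP (P, R).

    The behavior policy is epsilon-greedy; episodes restart from a uniform
    random state every ``episode_len`` steps (exploring starts), since the
    mean-reverting dynamics would otherwise concentrate visits in a few
    engagement bins and leave the others' values unconverged.  Uses the same td_update/epsilon_greedy kernels as the closed
    loop; state keys are (bin,) and arms are integer indices.
    """
    n_states, n_arms = R.shape
    q = QTable(learn_rate_beta=learn_rate_beta, discount_gamma=discount_gamma,
               epsilon=epsilon)
    arms = list(range(n_arms))
    s = int(rng.integers(n_states))
    for t in range(n_steps):
        if t and t % episode_len == 0:
            s = int(rng.integers(n_states))
        a = epsilon_greedy(q, (s,), arms, rng)
        s_next = int(rng.choice(n_states, p=P[s, a]))
        td_update(q, TransitionTuple((s,), a, float(R[s, a]), (s_next,)), arms)
        s = s_next
    return q


class TDPolicy(BaseEstimator):
    """Sklearn-style wrapper: learn an intervention policy on simulated cohorts.

    ``fit`` trains the tabular TD policy by running ``n_sessions`` adaptive
    closed-loop sessions on children drawn from ``cohort_config`` (one fresh
    child per session, seeds spawned from ``seed``), with the exploration
    rate decaying across sessions.  ``predict`` maps score values to greedy
    interventions.

    Attributes
    ----------
    q_table_ : QTable
    catalog_ : list of intervention ids
    n_sessions_ : int
    """

    def __init__(self, cohort_config=None, n_sessions=500, n_interactions=30,
                 learn_rate_beta=0.1, discount_gamma=0.9,
                 epsilon_0=0.3, epsilon_decay=0.999, epsilon_min=0.05,
                 default_q=0.0, seed=0):
        self.cohort_config = cohort_config
        self.n_sessions = n_sessions
        self.n_interactions = n_interactions
        self.learn_rate_beta = learn_rate_beta
        self.discount_gamma = discount_gamma
        self.epsilon_0 = epsilon_0
        self.epsilon_decay = epsilon_decay
        self.epsilon_min = epsilon_min
        self.default_q = default_q
        self.seed = seed

    def fit(self, X=None, y=None):
        cfg = self.cohort_config
        if cfg is None:
            cfg = CohortConfig(master_seed=self.seed)
        q = QTable(learn_rate_beta=self.learn_rate_beta,
                   discount_gamma=self.discount_gamma,
                   epsilon=self.epsilon_0, default_q=self.default_q)
        sched = EpsilonSchedule(self.epsilon_0, self.epsilon_decay,
                                self.epsilon_min)
        for k in range(self.n_sessions):
            rng = np.random.default_rng(child_seed(self.seed, k))
            profile = make_child_profile(cfg, rng, child_id=f"train-{k}")
            run_adaptive_session(profile, q, self.n_interactions, rng,
                                 epsilon=sched(k))
        self.q_table_ = q
        self.catalog_ = list(cfg.interventions)
        self.n_sessions_ = self.n_sessions
        return self

    def predict(self, X):
        """Greedy intervention for each score in ``X`` (array-like of scores)."""
        check_is_fitted(self, "q_table_")
        scores = np.asarray(X, dtype=float).ravel()
        return np.array([self.q_table_.best(discretize_state(None, s),
                                            self.catalog_)[0]
                         for s in scores])
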