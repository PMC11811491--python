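"""Policy evaluation on simulated cohorts: returns, engagement, comparisons.

Evaluation is paired: every policy is rolled on children drawn from the same
per-child seeds, so cross-policy differences are differences in behavior,
not in the sampled children.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._common import child_seed
from .adjustment import AdjustmentConfig
from .policy import QTable, discounted_return, run_adaptive_session
from .rewards import RewardConfig, immediate_reward, modified_reward
from .simulator import CohortConfig, make_child_profile

__all__ = ["session_rewards", "session_return", "evaluate_policy",
           "compare_policies", "PolicyEvaluation"]


def session_rewards(session, reward_cfg: RewardConfig) -> np.ndarray:
    """Penalty-modified immediate rewards along a session's engagement series."""
    e = session.engagements
    if e.size < 2:
        return np.zeros(0)
    out = np.empty(e.size - 1)
    for i in range(1, e.size):
        delta = e[i] - e[i - 1]
        out[i - 1] = modified_reward(immediate_reward(e[i], e[i - 1], reward_cfg),
                                     delta, reward_cfg)
    return out


def session_return(session, reward_cfg: RewardConfig,
                   discount_gamma: float) -> float:
    """Discounted return of a session's penalty-modified reward sequence."""
    r = session_rewards(session, reward_cfg)
    if r.size == 0:
        raise ValueError("session too short to score")
    return discounted_return(r, discount_gamma)


@dataclass
class PolicyEvaluation:
    policy: str
    returns: np.ndarray
    mean_engagement: np.ndarray
    best_arm_fraction: float  # fraction of intervened steps using the best arm

    @property
    def mean_return(self) -> float:
        return float(self.returns.mean())

    @property
    def sd_return(self) -> float:
        return float(self.returns.std(ddof=1))


def evaluate_policy(mode: str, cfg: CohortConfig, n_sessions: int, eval_seed: int,
                    q: QTable | None = None,
                    reward_cfg: RewardConfig | None = None,
                    adj_cfg: AdjustmentConfig | None = None,
                    n_interactions: int | None = None) -> PolicyEvaluation:
    """Roll ``n_sessions`` evaluation children under one policy mode.

    Modes: "q" (greedy on the supplied table, epsilon = 0, no learning),
    "random" (uniform over the catalog whenever the loop intervenes) and
    "never" (intervention probability forced to zero).  Child i's seed is
    spawned from (eval_seed, i) regardless of mode, pairing the cohorts.
    """
    if mode not in ("q", "random", "never"):
        raise ValueError(f"unknown policy mode {mode!r}")
    reward_cfg = reward_cfg if reward_cfg is not None else RewardConfig()
    adj_cfg = adj_cfg if adj_cfg is not None else AdjustmentConfig()
    if mode == "never":
        adj_cfg = AdjustmentConfig(**{**adj_cfg.__dict__, "p_min": 0.0, "p_max": 0.0})
    n = n_interactions if n_interactions is not None else cfg.n_interactions
    epsilon = 0.0 if mode == "q" else 1.0
    returns, engagements, n_best, n_intervened = [], [], 0, 0
    for i in range(n_sessions):
        rng = np.random.default_rng(child_seed(eval_seed, i))
        profile = make_child_profile(cfg, rng, child_id=f"eval-{i}")
        table = q if (mode == "q" and q is not None) else QTable()
        session, _ = run_adaptive_session(
            profile, table, n, rng, reward_cfg=reward_cfg, adj_cfg=adj_cfg,
            epsilon=epsilon, learn=False)
        returns.append(session_return(session, reward_cfg, table.discount_gamma))
        engagements.append(float(session.engagements.mean()))
        for rec in session.records:
            if rec.intervention is not None:
                n_intervened += 1
                n_best += rec.intervention == cfg.best_intervention
    frac = n_best / n_intervened if n_intervened else float("nan")
    return PolicyEvaluation(policy=mode, returns=np.array(returns),
                            mean_engagement=np.array(engagements),
                            best_arm_fraction=frac)


def compare_policies(evals) -> pd.DataFrame:
    """Summary table: one row per policy (mean return, sd, session count)."""
    return pd.DataFrame([{
        "policy": ev.policy,
        "mean_return": ev.mean_return,
        "sd_return": ev.sd_return,
        "n_sessions": ev.returns.size,
    } for ev in evals])
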