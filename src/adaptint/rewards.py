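"""Reward stack quantifying intervention effectiveness.

Five layers, from one interaction to a whole session:

* immediate reward      R = s_i + alpha * (s_i - s_prev)
* discounted cumulative R_total = gamma * sum_k beta^(i-k) * R_k
* predictive reward     R_pred = E[s_{i+1} | s_i, j] + alpha * delta_s
* penalty-modified      R_mod = R - lambda * 1[delta_s < delta_threshold]
* final objective       R_final = sum over prefixes of the discounted
                        cumulative of the penalty-modified rewards

The original symbols gamma, beta, lambda, delta are reused elsewhere in the
method for unrelated roles (TD learning rate/discount, smoothing,
regularization); config keys here carry role-prefixed names to keep them
apart — see the symbol map in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._common import DEFAULT_SCORE_BINS, check_finite, discretize_score

__all__ = [
    "RewardConfig",
    "NextScorePredictor",
    "immediate_reward",
    "cumulative_reward",
    "predicted_reward",
    "modified_reward",
    "final_objective",
]


@dataclass
class RewardConfig:
    """Reward hyperparameters.

    sensitivity_alpha scales the reward contribution of the observed
    score improvement; scale_gamma is the overall cumulative-reward scale;
    discount_beta in [0, 1] emphasizes recent interactions; penalty_lambda
    and improvement_threshold_delta define the flat penalty applied when an
    intervention improves the score by less than the threshold.
    """

    sensitivity_alpha: float = 1.0
    scale_gamma: float = 1.0
    discount_beta: float = 0.9
    penalty_lambda: float = 0.1
    improvement_threshold_delta: float = 0.0

    def __post_init__(self):
        if self.sensitivity_alpha < 0:
            raise ValueError("sensitivity_alpha must be >= 0")
        if self.scale_gamma <= 0:
            raise ValueError("scale_gamma must be > 0")
        if not 0.0 <= self.discount_beta <= 1.0:
            raise ValueError("discount_beta must be in [0, 1]")
        if self.penalty_lambda < 0:
            raise ValueError("penalty_lambda must be >= 0")


def immediate_reward(s_i: float, s_prev: float, cfg: RewardConfig) -> float:
    """R = s_i + alpha * (s_i - s_prev)."""
    if not (np.isfinite(s_i) and np.isfinite(s_prev)):
        raise ValueError("immediate_reward requires finite scores")
    return float(s_i + cfg.sensitivity_alpha * (s_i - s_prev))


def cumulative_reward(rewards, cfg: RewardConfig) -> float:
    """Discounted cumulative reward gamma * sum_{k=1..i} beta^(i-k) * R_k.

    At beta = 0 only the newest reward survives (0^0 := 1 here, the only
    reading under which "emphasize recent interactions" holds in the limit).
    """
    r = check_finite(rewards, "rewards")
    if r.size == 0:
        raise ValueError("cumulative_reward requires at least one reward")
    i = r.size
    if cfg.discount_beta == 0.0:
        return float(cfg.scale_gamma * r[-1])
    powers = cfg.discount_beta ** np.arange(i - 1, -1, -1)
    return float(cfg.scale_gamma * np.dot(powers, r))


class NextScorePredictor:
    """Binned empirical conditional mean E[s_{i+1} | s_i, j].

    Cells are (score bin of s_i, intervention); each holds the running mean
    of observed next-step scores.  A cold cell falls back to s_i itself (a
    martingale prior), so the predictor is usable before any observation.
    Shares its binning with the effectiveness table and the policy state key.
    """

    def __init__(self, n_bins: int = DEFAULT_SCORE_BINS):
        self.n_bins = n_bins
        self._sums: dict = {}
        self._counts: dict = {}

    def observe(self, s_i: float, intervention, s_next: float) -> None:
        key = (discretize_score(s_i, self.n_bins), intervention)
        self._sums[key] = self._sums.get(key, 0.0) + float(s_next)
        self._counts[key] = self._counts.get(key, 0) + 1

    def predict(self, s_i: float, intervention) -> float:
        key = (discretize_score(s_i, self.n_bins), intervention)
        n = self._counts.get(key, 0)
        return self._sums[key] / n if n else float(s_i)


def predicted_reward(s_i: float, intervention, predictor: NextScorePredictor,
                     cfg: RewardConfig, delta_s: float = 0.0) -> float:
    """R_pred = E[s_{i+1} | s_i, j] + alpha * delta_s."""
    return float(predictor.predict(s_i, intervention)
                 + cfg.sensitivity_alpha * delta_s)


def modified_reward(reward: float, delta_s: float, cfg: RewardConfig) -> float:
    """Penalty-modified reward R - lambda * 1[delta_s < threshold].

    The indicator is strict: an improvement exactly at the threshold incurs
    no penalty.
    """
    if not (np.isfinite(reward) and np.isfinite(delta_s)):
        raise ValueError("modified_reward requires finite inputs")
    pen = cfg.penalty_lambda if delta_s < cfg.improvement_threshold_delta else 0.0
    return float(reward - pen)


def final_objective(modified_rewards, cfg: RewardConfig) -> float:
    """Session objective: sum over prefixes of the discounted cumulative reward.

    R_final = sum_{i=1..N} gamma * sum_{k=1..i} beta^(i-k) * R_mod_k — i.e.
    the discounted cumulative reward of every prefix, summed.  Note early
    rewards are double-discounted relative to a standard RL return; the
    standard return lives in :func:`adaptint.policy.discounted_return` and is
    what the policy optimizes — this quantity is a session diagnostic.
    """
    r = check_finite(modified_rewards, "modified_rewards")
    if r.size == 0:
        raise ValueError("final_objective requires at least one reward")
    return float(sum(cumulative_reward(r[: i + 1], cfg) for i in range(r.size)))
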