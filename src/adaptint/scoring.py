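"""Attention-based engagement scoring and skill trajectories.

One social interaction is summarized by a length-M vector of behavioral-cue
intensities (eye contact, vocal tone, posture, ...), conventionally scaled to
[0, 1].  An attention mechanism converts alignment scores between cues and a
target skill goal into softmax weights, and the engagement score E_i is the
attention-weighted aggregate of the cue intensities.  Skill trajectories are
summarized by their mean (the skill score) and their finite-difference
learning rate, and a greedy mapping picks the intervention with the highest
empirically estimated effectiveness at the current score level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from ._common import DEFAULT_SCORE_BINS, check_finite, discretize_score

logger = logging.getLogger("adaptint")

__all__ = [
    "skill_score",
    "learning_rate",
    "alignment_scores",
    "attention_weights",
    "engagement_score",
    "scoring_loss",
    "greedy_intervention",
    "feedback_update",
    "EffectivenessTable",
    "EngagementScorer",
]


def skill_score(scores) -> float:
    """Mean of the per-interaction skill components, (1/N) * sum(s_i)."""
    s = check_finite(scores, "scores")
    if s.size == 0:
        raise ValueError("skill_score requires at least one interaction")
    return float(np.mean(s))


def learning_rate(scores, times) -> np.ndarray:
    """Finite-difference rate of skill acquisition, ds/dt.

    Forward differences g_i = (s_i - s_{i-1}) / (t_i - t_{i-1}) for
    i = 2..N; positive entries signal progress.  Sessions are discrete event
    sequences, so the time derivative is discretized as forward differences.
    """
    s = check_finite(scores, "scores")
    t = check_finite(times, "times")
    if s.shape != t.shape:
        raise ValueError("scores and times must have equal length")
    if s.size < 2:
        raise ValueError("learning_rate requires at least two interactions")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("times must be strictly increasing")
    return np.diff(s) / dt


def alignment_scores(x, goal) -> np.ndarray:
    """Alignment e_ij between cue intensity x_ij and the skill-goal component.

    The alignment kernel is the elementwise product x_ij * goal_j; with the
    default all-ones goal this reduces attention to a softmax over the raw
    cue intensities.
    """
    xv = check_finite(x, "x")
    gv = check_finite(goal, "goal")
    if xv.shape != gv.shape:
        raise ValueError(f"cue vector ({xv.shape}) and goal ({gv.shape}) lengths differ")
    return xv * gv


def attention_weights(e) -> np.ndarray:
    """Softmax attention weights a_ij = exp(e_ij) / sum_k exp(e_ik).

    Numerically stabilized by max-subtraction; the output sums to 1 and every
    component lies in (0, 1).
    """
    ev = check_finite(e, "alignment scores")
    if ev.size == 0:
        raise ValueError("attention_weights requires at least one feature")
    z = np.exp(ev - ev.max())
    return z / z.sum()


def engagement_score(x, a) -> float:
    """Attention-weighted engagement E_i = sum_j a_ij * x_ij.

    With normalized weights the score is a convex combination of the cue
    intensities, hence bounded by [min(x), max(x)]; cues in [0, 1] give an
    engagement score in [0, 1].
    """
    xv = check_finite(x, "x")
    av = check_finite(a, "attention weights")
    if xv.shape != av.shape:
        raise ValueError("cue vector and attention weights lengths differ")
    return float(np.dot(av, xv))


def scoring_loss(observed, predicted) -> float:
    """Mean squared error between observed and predicted engagement scores."""
    o = check_finite(observed, "observed")
    p = check_finite(predicted, "predicted")
    if o.shape != p.shape:
        raise ValueError("observed and predicted lengths differ")
    if o.size == 0:
        raise ValueError("scoring_loss requires at least one pair")
    return float(np.mean((o - p) ** 2))


def feedback_update(s_i: float, delta_s: float) -> float:
    """Feedback-loop score update s_i + delta_s (observed post-intervention change)."""
    if not (np.isfinite(s_i) and np.isfinite(delta_s)):
        raise ValueError("feedback_update requires finite inputs")
    return float(s_i + delta_s)


@dataclass
class EffectivenessTable:
    """Empirical per-intervention effectiveness, binned by score level.

    Effectiveness(j | s) is estimated as the mean observed score change
    following intervention j among interactions whose pre-score fell in the
    same score bin as s.  Unobserved (bin, intervention) cells default to 0
    so a cold-started table is usable immediately; ties break toward the
    lowest intervention index, which makes the greedy map deterministic.
    """

    interventions: list
    n_bins: int = DEFAULT_SCORE_BINS
    _sums: dict = field(default_factory=dict, repr=False)
    _counts: dict = field(default_factory=dict, repr=False)

    def observe(self, s_before: float, intervention, delta_s: float) -> None:
        if intervention not in self.interventions:
            raise KeyError(f"unknown intervention {intervention!r}")
        key = (discretize_score(s_before, self.n_bins), intervention)
        self._sums[key] = self._sums.get(key, 0.0) + float(delta_s)
        self._counts[key] = self._counts.get(key, 0) + 1

    def effectiveness(self, intervention, s: float) -> float:
        key = (discretize_score(s, self.n_bins), intervention)
        n = self._counts.get(key, 0)
        return self._sums.get(key, 0.0) / n if n else 0.0


def greedy_intervention(s_i: float, table: EffectivenessTable):
    """Argmax over interventions of the estimated Effectiveness(j | s_i)."""
    if not table.interventions:
        raise ValueError("intervention catalog is empty")
    best, best_val = None, -np.inf
    for j in table.interventions:  # catalog order == tie-break order
        v = table.effectiveness(j, s_i)
        if v > best_val:
            best, best_val = j, v
    return best


class EngagementScorer(TransformerMixin, BaseEstimator):
    """Transform cue-intensity vectors into attention-weighted engagement scores.

    Parameters
    ----------
    goal : array-like of shape (n_features,) or None
        Target social-skill goal vector used to form alignment scores
        ``e_ij = x_ij * goal_j``.  ``None`` (default) means an all-ones goal,
        i.e. attention is a softmax over the raw cue intensities.

    Attributes
    ----------
    n_features_in_ : int
        Number of behavioral cues M seen during :meth:`fit`.
    goal_ : ndarray of shape (n_features_in_,)
        Effective goal vector.

    Examples
    --------
    >>> import numpy as np
    >>> X = np.array([[0.2, 0.8], [0.5, 0.5]])
    >>> EngagementScorer().fit_transform(X).shape
    (2,)
    """

    def __init__(self, goal=None):
        self.goal = goal

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        if self.goal is None:
            self.goal_ = np.ones(self.n_features_in_)
        else:
            self.goal_ = check_finite(self.goal, "goal")
            if self.goal_.shape != (self.n_features_in_,):
                raise ValueError("goal length must equal the number of cues")
        return self

    def transform(self, X) -> np.ndarray:
        """Per-row engagement scores E_i for a (n_interactions, M) cue matrix."""
        check_is_fitted(self, "goal_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count changed between fit and transform")
        out = np.empty(X.shape[0])
        for i, row in enumerate(X):
            a = attention_weights(alignment_scores(row, self.goal_))
            out[i] = engagement_score(row, a)
        return out

    def attention(self, x) -> np.ndarray:
        """Attention weights for a single cue vector."""
        check_is_fitted(self, "goal_")
        return attention_weights(alignment_scores(x, self.goal_))
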