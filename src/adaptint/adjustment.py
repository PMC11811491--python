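"""Confidence-based modulation of intervention frequency and intensity.

Confidence c_i = exp(-variance of the last K engagement scores) is 1 exactly
when engagement is stable and decays toward 0 as engagement fluctuates.
High confidence reduces the probability that the engine intervenes at all
(a linear map from 1 - c_i onto [p_min, p_max]); low confidence both raises
that probability and speeds up intensity adaptation, because the per-
intervention intensity phi(j) moves by eta * c_i * deltaE after each applied
intervention and is exponentially smoothed to prevent abrupt shifts.

Intensity has an operational meaning in the closed loop: the applied
effect of intervention j is its ground-truth effect size times the smoothed
intensity, capped to [0, phi_max].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._common import check_finite

__all__ = [
    "AdjustmentConfig",
    "AdjustmentState",
    "confidence",
    "intensity_update",
    "smooth_intensity",
    "intervention_probability",
]


@dataclass
class AdjustmentConfig:
    """Hyperparameters of the confidence-based controller.

    window_size K of the rolling engagement window; eta, the intensity
    adaptation step; smooth_lambda in [0, 1], the exponential-smoothing
    memory; p_min <= p_max, the intervention-probability range; phi_max,
    the intensity cap.
    """

    window_size: int = 5
    eta: float = 0.1
    smooth_lambda: float = 0.8
    p_min: float = 0.2
    p_max: float = 0.9
    phi_max: float = 2.0

    def __post_init__(self):
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if not 0.0 <= self.smooth_lambda <= 1.0:
            raise ValueError("smooth_lambda must be in [0, 1]")
        if not (0.0 <= self.p_min <= self.p_max <= 1.0):
            raise ValueError("need 0 <= p_min <= p_max <= 1")
        if self.phi_max <= 0:
            raise ValueError("phi_max must be > 0")


def confidence(window) -> float:
    """c = exp(-(1/K) * sum (E_k - mean)^2); in (0, 1], 1 iff constant.

    ``window`` holds the last K engagement scores.  Early in a session, when
    fewer than K observations exist, the caller passes all available scores
    and K is the actual count.  Shift-invariant: adding a constant to every
    element leaves the confidence unchanged.
    """
    w = check_finite(window, "window")
    if w.size == 0:
        raise ValueError("confidence requires a non-empty window")
    return float(np.exp(-np.mean((w - w.mean()) ** 2)))


def intensity_update(phi_j: float, delta_e: float, c_i: float, eta: float) -> float:
    """phi(j) <- phi(j) + eta * c_i * deltaE (confidence-weighted adaptation).

    The unweighted rule is the c_i = 1 special case.  Increases iff the
    engagement change is positive (for eta, c_i > 0).
    """
    if not all(np.isfinite(v) for v in (phi_j, delta_e, c_i, eta)):
        raise ValueError("intensity_update requires finite inputs")
    return float(phi_j + eta * c_i * delta_e)


def smooth_intensity(smoothed: float, raw: float, smooth_lambda: float) -> float:
    """Exponential smoothing phi~ <- lambda * phi~ + (1 - lambda) * phi."""
    if not 0.0 <= smooth_lambda <= 1.0:
        raise ValueError("smooth_lambda must be in [0, 1]")
    return float(smooth_lambda * smoothed + (1.0 - smooth_lambda) * raw)


def intervention_probability(c_i: float, cfg: AdjustmentConfig) -> float:
    """p = p_min + (p_max - p_min) * (1 - c_i): intervene less when confident.

    Full confidence gives the minimal rate p_min; vanishing confidence
    (unstable engagement) approaches the maximal rate p_max.
    """
    if not (0.0 < c_i <= 1.0):
        raise ValueError("confidence must be in (0, 1]")
    return float(cfg.p_min + (cfg.p_max - cfg.p_min) * (1.0 - c_i))


@dataclass
class AdjustmentState:
    """Per-session controller state: rolling window and intensities."""

    cfg: AdjustmentConfig
    interventions: list
    window: list = field(default_factory=list)
    intensities: dict = field(default_factory=dict)
    smoothed: dict = field(default_factory=dict)

    def __post_init__(self):
        for j in self.interventions:
            self.intensities.setdefault(j, 1.0)
            self.smoothed.setdefault(j, 1.0)

    def push_engagement(self, e: float) -> None:
        self.window.append(float(e))
        if len(self.window) > self.cfg.window_size:
            self.window.pop(0)

    def current_confidence(self) -> float:
        return confidence(self.window) if self.window else 1.0

    def applied_intensity(self, j) -> float:
        """Smoothed intensity capped to [0, phi_max] — what the loop applies."""
        return float(min(max(self.smoothed[j], 0.0), self.cfg.phi_max))

    def record_outcome(self, j, delta_e: float, c_i: float) -> None:
        self.intensities[j] = intensity_update(self.intensities[j], delta_e,
                                               c_i, self.cfg.eta)
        self.smoothed[j] = smooth_intensity(self.smoothed[j],
                                            self.intensities[j],
                                            self.cfg.smooth_lambda)
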