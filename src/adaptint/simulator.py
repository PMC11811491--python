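"""Synthetic cohorts of child sessions with known ground truth.

The generator is deliberately simpler than the latent-state model the
package fits: each child's latent engagement follows a mean-reverting AR(1)
with additive intervention effects,

    l_{t+1} = carryover * l_t + (1 - carryover) * baseline
              + effect(j_t) * intensity_t + Normal(0, noise_sd^2)

so that fitting and policy tests have analytically tractable truth (e.g.
the steady-state engagement shift of a policy intervening with probability
p is effect * p / (1 - carryover)).  The observed engagement is the latent
value clipped to [0, 1]; the M behavioral cues are noisy linear read-outs
of the latent value, also clipped.  Clipping events are counted per session
so test configurations can verify they stay in the interior.

Every child draws its own seed from the master seed via numpy SeedSequence
spawn keys, making whole cohorts bit-reproducible and children independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._common import child_seed
from .sessions import Session, SessionRecord

logger = logging.getLogger("adaptint")

__all__ = ["ChildProfile", "CohortConfig", "make_child_profile",
           "ChildEnvironment", "simulate_session", "simulate_cohort"]


@dataclass
class ChildProfile:
    """Ground-truth generative parameters of one simulated child."""

    child_id: str
    baseline: float
    carryover: float
    intervention_effects: dict
    cue_loadings: np.ndarray
    noise_sd: float = 0.05
    cue_noise_sd: float = 0.05

    def __post_init__(self):
        self.cue_loadings = np.asarray(self.cue_loadings, dtype=float)
        if not 0.0 <= self.carryover < 1.0:
            raise ValueError("carryover must be in [0, 1)")
        if self.noise_sd < 0 or self.cue_noise_sd < 0:
            raise ValueError("noise scales must be >= 0")
        if not all(np.isfinite(v) for v in self.intervention_effects.values()):
            raise ValueError("intervention effects must be finite")


@dataclass
class CohortConfig:
    """Cohort-level generative settings.

    By default one designated intervention carries a +0.3 additive effect on
    next-step engagement and the others none; baselines are Uniform(0.3, 0.7)
    and AR(1) carryover Uniform(0.5, 0.9).  All ranges are configurable and
    ``master_seed`` is mandatory.
    """

    master_seed: int
    n_children: int = 30
    n_interactions: int = 30
    n_cues: int = 6
    interventions: tuple = ("A", "B", "C")
    best_intervention: str = "A"
    best_effect: float = 0.3
    other_effect: float = 0.0
    baseline_range: tuple = (0.3, 0.7)
    carryover_range: tuple = (0.5, 0.9)
    loading_range: tuple = (0.5, 1.0)
    noise_sd: float = 0.05
    cue_noise_sd: float = 0.05

    def __post_init__(self):
        if self.n_children < 1 or self.n_interactions < 1 or self.n_cues < 1:
            raise ValueError("counts must be positive")
        if self.master_seed is None:
            raise ValueError("master_seed is mandatory")
        if self.best_intervention not in self.interventions:
            raise ValueError("best_intervention must be in the catalog")
        for name in ("baseline_range", "carryover_range", "loading_range"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError(f"invalid {name}")


def make_child_profile(cfg: CohortConfig, rng, child_id: str = "child-0") -> ChildProfile:
    """Draw one child's ground-truth parameters; deterministic per (cfg, rng state)."""
    effects = {j: (cfg.best_effect if j == cfg.best_intervention else cfg.other_effect)
               for j in cfg.interventions}
    return ChildProfile(
        child_id=child_id,
        baseline=float(rng.uniform(*cfg.baseline_range)),
        carryover=float(rng.uniform(*cfg.carryover_range)),
        intervention_effects=effects,
        cue_loadings=rng.uniform(*cfg.loading_range, cfg.n_cues),
        noise_sd=cfg.noise_sd,
        cue_noise_sd=cfg.cue_noise_sd,
    )


class ChildEnvironment:
    """Stepwise simulator of one child; the contract the closed loop runs on.

    ``reset`` places the latent engagement at the child's baseline and
    returns the first observation; ``step(intervention, intensity)`` advances
    the AR(1) latent state (the intervention's effect scaled by intensity)
    and returns the next observation.  Observations are (cues, engagement)
    with engagement = clip(latent, 0, 1).
    """

    def __init__(self, profile: ChildProfile, rng):
        self.profile = profile
        self.rng = rng
        self.latent = None
        self.n_clipped = 0

    def _observe(self):
        p = self.profile
        e = float(np.clip(self.latent, 0.0, 1.0))
        if e != self.latent:
            self.n_clipped += 1
        x_raw = p.cue_loadings * self.latent
        if p.cue_noise_sd > 0:
            x_raw = x_raw + self.rng.normal(0.0, p.cue_noise_sd, x_raw.shape)
        x = np.clip(x_raw, 0.0, 1.0)
        self.n_clipped += int(np.sum(x != x_raw))
        return x, e

    def reset(self):
        self.latent = float(self.profile.baseline)
        self.n_clipped = 0
        return self._observe()

    def step(self, intervention=None, intensity: float = 1.0):
        if self.latent is None:
            raise RuntimeError("call reset() before step()")
        p = self.profile
        eff = p.intervention_effects[intervention] * intensity if intervention is not None else 0.0
        self.latent = (p.carryover * self.latent
                       + (1.0 - p.carryover) * p.baseline + eff)
        if p.noise_sd > 0:
            self.latent += float(self.rng.normal(0.0, p.noise_sd))
        return self._observe()


def simulate_session(profile: ChildProfile, policy, n: int, rng,
                     seed: int | None = None) -> Session:
    """Roll one child for ``n`` interactions under a fixed policy.

    ``policy(t, x, engagement, rng)`` returns an intervention id or None;
    the chosen intervention acts on the *next* step's engagement.  Unit
    intensity throughout (the adaptive loop with intensity modulation lives
    in :func:`adaptint.policy.run_adaptive_session`).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    env = ChildEnvironment(profile, rng)
    x, e = env.reset()
    records = []
    for t in range(n):
        j = policy(t, x, e, rng)
        records.append(SessionRecord(t=float(t), x=x, intervention=j, engagement=e))
        if t < n - 1:
            x, e = env.step(j)
    if env.n_clipped:
        logger.info("session %s: %d clip events", profile.child_id, env.n_clipped)
    return Session(child_id=profile.child_id, records=records, seed=seed)


def simulate_cohort(cfg: CohortConfig, policy) -> list:
    """Simulate ``cfg.n_children`` independent sessions.

    Each child gets a seed spawned from the master seed, so the whole cohort
    is a pure function of (config, master_seed).
    """
    sessions = []
    for i in range(cfg.n_children):
        ss = child_seed(cfg.master_seed, i)
        rng = np.random.default_rng(ss)
        profile = make_child_profile(cfg, rng, child_id=f"child-{i}")
        sessions.append(simulate_session(profile, policy, cfg.n_interactions,
                                         rng, seed=int(ss.entropy)))
    return sessions


def never_intervene(t, x, e, rng):
    """Baseline policy: no intervention at any step."""
    return None


def uniform_random_policy(interventions):
    """Policy choosing uniformly among ``interventions`` at every step."""
    arms = list(interventions)

    def policy(t, x, e, rng):
        return arms[rng.integers(len(arms))]

    return policy


def fixed_policy(intervention):
    """Policy applying the same intervention at every step."""

    def policy(t, x, e, rng):
        return intervention

    return policy
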