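"""Latent interaction-state dynamics.

The latent state z_i is a length-D real vector summarizing the child's
cognitive/affective response at interaction i.  It combines

* an immediate encoding of the current cue vector, ``tanh(W1 @ x + b1)``,
* a decaying sum over the whole state history,
  ``sum_{j<i} exp(-rho * (i - j)) * (A @ z_j)``, which makes the "memory
  fades geometrically with lag" contract literal,
* an adaptive logistic gate on the concatenated (cues, previous state)
  context, applied elementwise, and
* isotropic Gaussian noise of scale ``noise_scale`` (minor behavioral
  fluctuation; 0 gives a fully deterministic recursion).

The one-step recurrent map of the plain formulation is subsumed by the
decayed history sum (its j = i-1 term); the initial state z_0 is the zero
vector so the cold start is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._common import check_finite

__all__ = ["LatentParams", "encode_immediate", "decay_contribution", "gate", "update_latent"]

_SCHEMA = "adaptint.latent-params.v1"


@dataclass
class LatentParams:
    """Parameters of the latent-state recursion.

    encoder_weights/encoder_bias: D x M matrix and D vector of the immediate
    tanh-affine encoder.  decay_map (D x D) and decay_rate (rho >= 0) define
    the history kernel exp(-rho * lag) * (A @ z).  gate_weights/gate_bias map
    the concatenated [x; z_prev] (length M + D) to D logistic gate units.
    noise_scale is the standard deviation of the additive Gaussian noise.
    """

    encoder_weights: np.ndarray
    encoder_bias: np.ndarray
    decay_map: np.ndarray
    decay_rate: float
    gate_weights: np.ndarray
    gate_bias: np.ndarray
    noise_scale: float = 0.05

    def __post_init__(self):
        self.encoder_weights = check_finite(self.encoder_weights, "encoder_weights")
        self.encoder_bias = check_finite(self.encoder_bias, "encoder_bias")
        self.decay_map = check_finite(self.decay_map, "decay_map")
        self.gate_weights = check_finite(self.gate_weights, "gate_weights")
        self.gate_bias = check_finite(self.gate_bias, "gate_bias")
        d, m = self.encoder_weights.shape
        if self.encoder_bias.shape != (d,):
            raise ValueError("encoder_bias shape inconsistent with encoder_weights")
        if self.decay_map.shape != (d, d):
            raise ValueError("decay_map must be D x D")
        if self.gate_weights.shape != (d, m + d):
            raise ValueError("gate_weights must be D x (M + D)")
        if self.gate_bias.shape != (d,):
            raise ValueError("gate_bias must be length D")
        if self.decay_rate < 0:
            raise ValueError("decay_rate must be >= 0")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")

    @property
    def n_latent(self) -> int:
        return self.encoder_weights.shape[0]

    @property
    def n_cues(self) -> int:
        return self.encoder_weights.shape[1]

    @classmethod
    def random(cls, n_latent: int = 4, n_cues: int = 6, rng=None,
               scale: float = 0.5, decay_rate: float = 0.5,
               noise_scale: float = 0.05) -> "LatentParams":
        """Random parameters with entries ~ U(-scale, scale); test/demo helper."""
        rng = np.random.default_rng(rng)
        d, m = n_latent, n_cues
        return cls(
            encoder_weights=rng.uniform(-scale, scale, (d, m)),
            encoder_bias=rng.uniform(-scale, scale, d),
            decay_map=rng.uniform(-scale, scale, (d, d)),
            decay_rate=decay_rate,
            gate_weights=rng.uniform(-scale, scale, (d, m + d)),
            gate_bias=rng.uniform(-scale, scale, d),
            noise_scale=noise_scale,
        )

    def to_json(self) -> str:
        doc = {
            "schema": _SCHEMA,
            "encoder_weights": self.encoder_weights.tolist(),
            "encoder_bias": self.encoder_bias.tolist(),
            "decay_map": self.decay_map.tolist(),
            "decay_rate": self.decay_rate,
            "gate_weights": self.gate_weights.tolist(),
            "gate_bias": self.gate_bias.tolist(),
            "noise_scale": self.noise_scale,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "LatentParams":
        doc = json.loads(text)
        if doc.get("schema") != _SCHEMA:
            raise ValueError(f"unexpected schema tag {doc.get('schema')!r}")
        return cls(
            encoder_weights=np.asarray(doc["encoder_weights"], dtype=float),
            encoder_bias=np.asarray(doc["encoder_bias"], dtype=float),
            decay_map=np.asarray(doc["decay_map"], dtype=float),
            decay_rate=float(doc["decay_rate"]),
            gate_weights=np.asarray(doc["gate_weights"], dtype=float),
            gate_bias=np.asarray(doc["gate_bias"], dtype=float),
            noise_scale=float(doc["noise_scale"]),
        )


def encode_immediate(x, params: LatentParams) -> np.ndarray:
    """Immediate encoding tanh(W1 @ x + b1); components in (-1, 1)."""
    xv = check_finite(x, "x")
    if xv.shape != (params.n_cues,):
        raise ValueError(f"cue vector length {xv.shape} != M={params.n_cues}")
    return np.tanh(params.encoder_weights @ xv + params.encoder_bias)


def decay_contribution(past_states, params: LatentParams) -> np.ndarray:
    """Decayed history sum sum_{j<i} exp(-rho * (i - j)) * (A @ z_j).

    ``past_states`` is the ordered prefix z_1 .. z_{i-1}; the lag of the most
    recent state is 1.  An empty history contributes the zero vector.
    """
    d = params.n_latent
    out = np.zeros(d)
    n = len(past_states)
    for j, z in enumerate(past_states):  # j = 0 .. n-1, lag = n - j
        lag = n - j
        out += np.exp(-params.decay_rate * lag) * (params.decay_map @ np.asarray(z, dtype=float))
    return out


def gate(x, z_prev, params: LatentParams) -> np.ndarray:
    """Adaptive gate logistic(W_g @ [x; z_prev] + b_g); components in (0, 1)."""
    xv = check_finite(x, "x")
    zv = check_finite(z_prev, "z_prev")
    if xv.shape != (params.n_cues,) or zv.shape != (params.n_latent,):
        raise ValueError("gate input shapes inconsistent with params")
    u = params.gate_weights @ np.concatenate([xv, zv]) + params.gate_bias
    return 1.0 / (1.0 + np.exp(-u))


def update_latent(history, x, params: LatentParams, rng,
                  gate_override=None) -> np.ndarray:
    """One latent-state update.

    z_i = gate(x, z_{i-1}) * (encode_immediate(x) + decay_contribution(history))
          + Normal(0, noise_scale^2 I)

    ``history`` is the full ordered prefix of past states (empty at i = 1, in
    which case the gate sees the zero state).  ``gate_override`` replaces the
    gate output with a constant vector — a test hook for compositional checks.
    With ``noise_scale = 0`` the update is deterministic.
    """
    z_prev = history[-1] if len(history) else np.zeros(params.n_latent)
    g = gate(x, z_prev, params) if gate_override is None else np.asarray(gate_override, dtype=float)
    core = g * (encode_immediate(x, params) + decay_contribution(history, params))
    if params.noise_scale > 0:
        core = core + rng.normal(0.0, params.noise_scale, params.n_latent)
    return core
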