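"""One-step temporal evolution of the latent state.

The transition z_i -> z_{i+1} blends a squashed recurrent map of the current
state, g(z) = tanh(W4 @ z + b4), with an affine map of the incoming cue
vector, h(x) = W5 @ x + b5, through a context-dependent persistence weight
delta_i in (0, 1), then modulates the blend elementwise with a softmax
attention vector computed from the concatenated (state, cues) context:

    z_{i+1} = a_i * (delta_i * g(z_i) + (1 - delta_i) * h(x_{i+1})) + eps

* ``g`` is tanh-squashed so the convex combination stays bounded; ``h`` is
  affine so new cues can move the state anywhere in the squashed range.
* delta_i is a logistic novelty gate, logistic(c0 - c1 * ||x_{i+1} - x_bar||),
  where x_bar is the running mean of cues seen so far: persistence is high
  when the new interaction carries little novel information.
* The raw softmax attention systematically shrinks magnitudes (each weight
  < 1); ``attention_renorm`` optionally rescales it ("max" divides by the
  largest weight, "sum_to_D" rescales the weights to sum to D) for stable
  long runs.  The verbatim form ("none") is the default.

Parameters are fit to observed trajectories by full-batch gradient descent
on the mean-squared one-step prediction error plus an optional smoothness
penalty, with a backtracking (Armijo) line search so the loss trace is
non-increasing by construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ._common import check_finite

logger = logging.getLogger("adaptint")

__all__ = [
    "TransitionParams",
    "TrajectoryFit",
    "transition_attention",
    "context_decay",
    "transition_step",
    "smoothness_penalty",
    "fit_transition",
    "TransitionModel",
]

_SCHEMA = "adaptint.transition-params.v1"
_RENORMS = ("none", "max", "sum_to_D")


@dataclass
class TransitionParams:
    """Parameters of the latent transition z_i -> z_{i+1}.

    state_map/state_bias (theta4): D x D + D, tanh-squashed recurrent map.
    input_map/input_bias (theta5): D x M + D, affine cue map.
    attn_weights/attn_bias: D x (D + M) + D softmax attention over the D
    state components given the concatenated [z; x_next] context.
    decay_c0/decay_c1: scalars of the logistic novelty gate delta_i.
    reg_lambda: smoothness-penalty weight (>= 0).  noise_scale: transition
    noise sd.  attention_renorm: "none" | "max" | "sum_to_D".
    """

    state_map: np.ndarray
    state_bias: np.ndarray
    input_map: np.ndarray
    input_bias: np.ndarray
    attn_weights: np.ndarray
    attn_bias: np.ndarray
    decay_c0: float = 0.0
    decay_c1: float = 1.0
    reg_lambda: float = 0.0
    noise_scale: float = 0.0
    attention_renorm: str = "none"

    def __post_init__(self):
        for name in ("state_map", "state_bias", "input_map", "input_bias",
                     "attn_weights", "attn_bias"):
            setattr(self, name, check_finite(getattr(self, name), name))
        d = self.state_map.shape[0]
        m = self.input_map.shape[1]
        if self.state_map.shape != (d, d) or self.state_bias.shape != (d,):
            raise ValueError("state_map/state_bias shapes inconsistent")
        if self.input_map.shape != (d, m) or self.input_bias.shape != (d,):
            raise ValueError("input_map/input_bias shapes inconsistent")
        if self.attn_weights.shape != (d, d + m) or self.attn_bias.shape != (d,):
            raise ValueError("attention parameter shapes inconsistent")
        if self.reg_lambda < 0:
            raise ValueError("reg_lambda must be >= 0")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.attention_renorm not in _RENORMS:
            raise ValueError(f"attention_renorm must be one of {_RENORMS}")

    @property
    def n_latent(self) -> int:
        return self.state_map.shape[0]

    @property
    def n_cues(self) -> int:
        return self.input_map.shape[1]

    @classmethod
    def zeros(cls, n_latent: int, n_cues: int, **kw) -> "TransitionParams":
        d, m = n_latent, n_cues
        return cls(np.zeros((d, d)), np.zeros(d), np.zeros((d, m)), np.zeros(d),
                   np.zeros((d, d + m)), np.zeros(d), **kw)

    def to_json(self) -> str:
        doc = {"schema": _SCHEMA}
        for name in ("state_map", "state_bias", "input_map", "input_bias",
                     "attn_weights", "attn_bias"):
            doc[name] = getattr(self, name).tolist()
        for name in ("decay_c0", "decay_c1", "reg_lambda", "noise_scale",
                     "attention_renorm"):
            doc[name] = getattr(self, name)
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TransitionParams":
        doc = json.loads(text)
        if doc.get("schema") != _SCHEMA:
            raise ValueError(f"unexpected schema tag {doc.get('schema')!r}")
        kw = {k: np.asarray(doc[k], dtype=float)
              for k in ("state_map", "state_bias", "input_map", "input_bias",
                        "attn_weights", "attn_bias")}
        for k in ("decay_c0", "decay_c1", "reg_lambda", "noise_scale"):
            kw[k] = float(doc[k])
        kw["attention_renorm"] = str(doc["attention_renorm"])
        return cls(**kw)


@dataclass
class TrajectoryFit:
    """Result of fitting transition parameters to observed trajectories."""

    params: TransitionParams
    final_loss: float
    loss_trace: np.ndarray
    converged: bool
    degenerate: bool = False


def _renorm(a: np.ndarray, mode: str) -> np.ndarray:
    if mode == "max":
        return a / a.max(axis=-1, keepdims=True)
    if mode == "sum_to_D":
        return a * a.shape[-1]
    return a


def transition_attention(z, x_next, params: TransitionParams,
                         renorm: bool = True) -> np.ndarray:
    """Softmax attention over the D state components.

    a_i = softmax(W_a @ [z; x_next] + b_a); sums to 1 with components in
    (0, 1).  When ``renorm`` is true the configured ``attention_renorm``
    rescaling is applied afterwards (the raw softmax is returned otherwise).
    """
    zv = check_finite(z, "z")
    xv = check_finite(x_next, "x_next")
    if zv.shape != (params.n_latent,) or xv.shape != (params.n_cues,):
        raise ValueError("transition_attention input shapes inconsistent")
    u = params.attn_weights @ np.concatenate([zv, xv]) + params.attn_bias
    w = np.exp(u - u.max())
    a = w / w.sum()
    return _renorm(a, params.attention_renorm) if renorm else a


def context_decay(x_next, params: TransitionParams, x_mean=None) -> float:
    """Persistence weight delta_i = logistic(c0 - c1 * ||x_next - x_bar||_2).

    ``x_mean`` is the running mean of cue vectors seen so far in the session;
    at the first interaction (no history) the novelty distance is taken as 0,
    giving logistic(c0).  delta is in (0, 1) and strictly decreasing in the
    novelty distance when c1 > 0.
    """
    xv = check_finite(x_next, "x_next")
    dist = 0.0 if x_mean is None else float(np.linalg.norm(xv - np.asarray(x_mean, dtype=float)))
    return float(1.0 / (1.0 + np.exp(-(params.decay_c0 - params.decay_c1 * dist))))


def transition_step(z, x_next, params: TransitionParams, rng=None,
                    x_mean=None, delta=None, attention_override=None) -> np.ndarray:
    """One transition z_{i+1} = a * (delta * g(z) + (1 - delta) * h(x_next)) + eps.

    ``delta`` overrides the context-computed persistence; ``attention_override``
    replaces the attention vector (test hook).  With ``noise_scale = 0`` the
    step is a pure function of its inputs.
    """
    zv = check_finite(z, "z")
    xv = check_finite(x_next, "x_next")
    if delta is None:
        delta = context_decay(xv, params, x_mean)
    if attention_override is None:
        a = transition_attention(zv, xv, params)
    else:
        a = np.asarray(attention_override, dtype=float)
    g = np.tanh(params.state_map @ zv + params.state_bias)
    h = params.input_map @ xv + params.input_bias
    out = a * (delta * g + (1.0 - delta) * h)
    if params.noise_scale > 0:
        if rng is None:
            raise ValueError("rng required when noise_scale > 0")
        out = out + rng.normal(0.0, params.noise_scale, params.n_latent)
    return out


def smoothness_penalty(trajectory, reg_lambda: float) -> float:
    """Smoothness regularizer Omega = lambda * sum_i ||z_{i+1} - z_i||^2.

    Non-negative; zero iff the trajectory is constant or has length 1.
    Invariant to trajectory reversal and quadratic under state rescaling.
    """
    if reg_lambda < 0:
        raise ValueError("reg_lambda must be >= 0")
    Z = np.asarray(trajectory, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.shape[0] < 2:
        return 0.0
    return float(reg_lambda * np.sum(np.diff(Z, axis=0) ** 2))


# ---------------------------------------------------------------- fitting

def _stack_transitions(trajectories, params: TransitionParams):
    """Teacher-forced design arrays from (states, cues) trajectory pairs.

    Returns Z (current states), Xn (next cue vectors), Znext (targets), the
    per-transition attention vectors A and persistence weights delta, all
    computed from the *fixed* attention/decay parameters in ``params``.
    """
    Zs, Xs, Ts, As, Ds = [], [], [], [], []
    for states, cues in trajectories:
        S = np.asarray(states, dtype=float)
        X = np.asarray(cues, dtype=float)
        if S.shape[0] != X.shape[0]:
            raise ValueError("states and cues must have equal length")
        if S.shape[0] < 2:
            raise ValueError("each trajectory needs at least two interactions")
        for i in range(S.shape[0] - 1):
            x_mean = X[: i + 1].mean(axis=0)
            Ds.append(context_decay(X[i + 1], params, x_mean))
            As.append(transition_attention(S[i], X[i + 1], params))
            Zs.append(S[i])
            Xs.append(X[i + 1])
            Ts.append(S[i + 1])
    return (np.array(Zs), np.array(Xs), np.array(Ts),
            np.array(As), np.array(Ds))


def _loss_and_grad(theta, shapes, Z, Xn, Znext, A, Dl, reg_lambda):
    d, m = shapes
    k = 0
    W4 = theta[k:k + d * d].reshape(d, d); k += d * d
    b4 = theta[k:k + d]; k += d
    W5 = theta[k:k + d * m].reshape(d, m); k += d * m
    b5 = theta[k:k + d]
    T = Z.shape[0]
    Th = np.tanh(Z @ W4.T + b4)
    H = Xn @ W5.T + b5
    pred = A * (Dl[:, None] * Th + (1.0 - Dl)[:, None] * H)
    R = pred - Znext
    loss = float(np.sum(R ** 2) / T)
    G = (2.0 / T) * R
    if reg_lambda > 0:
        R2 = pred - Z
        loss += float(reg_lambda * np.sum(R2 ** 2))
        G = G + 2.0 * reg_lambda * R2
    dU = G * A * Dl[:, None] * (1.0 - Th ** 2)
    dV = G * A * (1.0 - Dl)[:, None]
    grad = np.concatenate([
        (dU.T @ Z).ravel(), dU.sum(axis=0),
        (dV.T @ Xn).ravel(), dV.sum(axis=0),
    ])
    return loss, grad


def fit_transition(trajectories, init: TransitionParams, max_iter: int = 5000,
                   tol: float = 1e-8) -> TrajectoryFit:
    """Fit theta4 (state map) and theta5 (input map) to observed trajectories.

    Full-batch gradient descent with backtracking (Armijo) line search on the
    teacher-forced one-step MSE plus ``init.reg_lambda`` times the smoothness
    penalty of the predictions.  The attention and novelty-gate parameters of
    ``init`` are held fixed; the loss trace is non-increasing by construction
    and the run stops when the relative loss change drops below ``tol``.

    Degenerate data (all transitions identical) is fit without error but
    flagged on the returned :class:`TrajectoryFit`.
    """
    if not trajectories:
        raise ValueError("fit_transition requires at least one trajectory")
    Z, Xn, Znext, A, Dl = _stack_transitions(trajectories, init)
    degenerate = bool(np.allclose(Z, Z[0]) and np.allclose(Xn, Xn[0]))
    if degenerate:
        logger.warning("degenerate trajectories: all transitions identical")
    d, m = init.n_latent, init.n_cues
    theta = np.concatenate([init.state_map.ravel(), init.state_bias,
                            init.input_map.ravel(), init.input_bias])
    loss, grad = _loss_and_grad(theta, (d, m), Z, Xn, Znext, A, Dl, init.reg_lambda)
    trace = [loss]
    step = 1.0
    converged = False
    for _ in range(max_iter):
        gnorm2 = float(grad @ grad)
        if gnorm2 == 0.0:
            converged = True
            break
        # Armijo backtracking: accept theta - step*grad when it gives
        # sufficient decrease; otherwise halve the step.
        accepted = False
        for _bt in range(60):
            cand = theta - step * grad
            new_loss, new_grad = _loss_and_grad(cand, (d, m), Z, Xn, Znext, A, Dl,
                                                init.reg_lambda)
            if new_loss <= loss - 1e-4 * step * gnorm2:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True  # no descent direction progress at machine scale
            break
        rel = (loss - new_loss) / max(loss, 1e-300)
        theta, loss, grad = cand, new_loss, new_grad
        trace.append(loss)
        step *= 2.0
        if rel < tol:
            converged = True
            break
    k = 0
    W4 = theta[k:k + d * d].reshape(d, d); k += d * d
    b4 = theta[k:k + d]; k += d
    W5 = theta[k:k + d * m].reshape(d, m); k += d * m
    b5 = theta[k:k + d]
    fitted = TransitionParams(
        state_map=W4, state_bias=b4, input_map=W5, input_bias=b5,
        attn_weights=init.attn_weights.copy(), attn_bias=init.attn_bias.copy(),
        decay_c0=init.decay_c0, decay_c1=init.decay_c1,
        reg_lambda=init.reg_lambda, noise_scale=init.noise_scale,
        attention_renorm=init.attention_renorm)
    return TrajectoryFit(params=fitted, final_loss=loss,
                         loss_trace=np.array(trace), converged=converged,
                         degenerate=degenerate)


class TransitionModel(BaseEstimator):
    """Sklearn-style estimator for the latent transition dynamics.

    ``fit`` takes a list of (states, cues) trajectory pairs — ``states`` of
    shape (n_i, D) and ``cues`` of shape (n_i, M) — and estimates the state
    map theta4 and input map theta5 by teacher-forced least squares (gradient
    descent with backtracking line search).  Attention and novelty-gate
    parameters are fixed hyperparameters of the estimator.

    Attributes
    ----------
    params_ : TransitionParams
        Fitted parameters.
    loss_trace_ : ndarray
        Objective value per accepted descent step (non-increasing).
    converged_ : bool
    degenerate_ : bool
    """

    def __init__(self, n_latent=4, n_cues=6, decay_c0=0.0, decay_c1=1.0,
                 reg_lambda=0.0, attention_renorm="none", max_iter=5000,
                 tol=1e-8, init_params=None):
        self.n_latent = n_latent
        self.n_cues = n_cues
        self.decay_c0 = decay_c0
        self.decay_c1 = decay_c1
        self.reg_lambda = reg_lambda
        self.attention_renorm = attention_renorm
        self.max_iter = max_iter
        self.tol = tol
        self.init_params = init_params

    def fit(self, X, y=None):
        """Fit to trajectories ``X`` = list of (states, cues) pairs."""
        init = self.init_params
        if init is None:
            init = TransitionParams.zeros(
                self.n_latent, self.n_cues, decay_c0=self.decay_c0,
                decay_c1=self.decay_c1, reg_lambda=self.reg_lambda,
                attention_renorm=self.attention_renorm)
        res = fit_transition(X, init, max_iter=self.max_iter, tol=self.tol)
        self.params_ = res.params
        self.loss_trace_ = res.loss_trace
        self.final_loss_ = res.final_loss
        self.converged_ = res.converged
        self.degenerate_ = res.degenerate
        return self

    def predict(self, X):
        """One-step-ahead state predictions for trajectories ``X``."""
        check_is_fitted(self, "params_")
        Z, Xn, _, A, Dl = _stack_transitions(X, self.params_)
        p = self.params_
        Th = np.tanh(Z @ p.state_map.T + p.state_bias)
        H = Xn @ p.input_map.T + p.input_bias
        return A * (Dl[:, None] * Th + (1.0 - Dl)[:, None] * H)
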