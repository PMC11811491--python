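# adaptint

An adaptive social-engagement intervention engine. The package targets
researchers studying technology-assisted social-skill interventions for
children with autism spectrum disorder (ASD) — and, more generally, anyone
building **dynamic treatment regimes** over short behavioral time series:
decision rules that map a participant's evolving state to the next
intervention.

Each interaction is observed as a vector of M behavioral-cue intensities
x_i (eye contact, vocal tone, posture, ..., scaled to [0, 1]). The engine
layers:

* **Attention-based engagement scoring.** Alignment scores e_ij between
  cues and a target skill goal feed a softmax,
  a_ij = exp(e_ij) / Σ_k exp(e_ik), and the engagement score is the
  attended aggregate E_i = Σ_j a_ij x_ij. Skill trajectories are summarized
  by their mean and finite-difference learning rate.
* **Latent state dynamics.** A latent vector z_i combines a tanh-affine
  encoding of current cues, a geometrically decaying sum over past states
  Σ_{j<i} exp(−ρ(i−j)) A z_j, an elementwise logistic gate, and Gaussian
  noise; a one-step transition model blends a squashed recurrent map with
  an affine cue map through a context-dependent persistence weight δ_i and
  softmax attention, and is fit to trajectories by monotone gradient
  descent on the one-step MSE.
* **A reward stack.** Immediate reward R = s_i + α Δs, discounted
  cumulative reward γ Σ_k β^{i−k} R_k, a binned conditional-mean predictive
  reward, a flat penalty for interventions whose improvement falls below a
  threshold, and a per-session objective summing the discounted cumulative
  reward of every prefix.
* **A tabular TD(0) intervention policy.** Q-values over discretized
  (score-bin) states and the intervention catalog, updated by
  Q(s,j) ← Q(s,j) + β (R + γ max_j' Q(s',j') − Q(s,j)), with ε-greedy
  exploration decaying across sessions.
* **Confidence-based adjustment.** Confidence c_i = exp(−Var of the last K
  engagement scores) gates how often the engine intervenes (linearly onto
  [p_min, p_max]) and scales per-intervention intensity adaptation with
  exponential smoothing.
* **A reproducible simulator.** Cohorts of synthetic children whose latent
  engagement follows a mean-reverting AR(1) with known additive
  intervention effects — the ground truth for parameter-recovery and
  policy-evaluation tests.

## Worked example

```python
import numpy as np
from adaptint import (CohortConfig, EngagementScorer, TDPolicy,
                      simulate_cohort, uniform_random_policy)
from adaptint.evaluation import compare_policies, evaluate_policy

cfg = CohortConfig(master_seed=7, n_children=5, n_interactions=20)
cohort = simulate_cohort(cfg, uniform_random_policy(cfg.interventions))

X = cohort[0].cues                      # (20, 6) cue matrix of one child
scores = EngagementScorer().fit(X).transform(X)
print(np.round(scores[:5], 3))
# [0.482 0.665 0.562 0.528 0.556]

agent = TDPolicy(cohort_config=CohortConfig(master_seed=7),
                 n_sessions=500, seed=7).fit()
evs = [evaluate_policy(m, CohortConfig(master_seed=7), 100, 10_000_026,
                       q=agent.q_table_) for m in ("q", "random", "never")]
print(compare_policies(evs).to_string(index=False))
# policy  mean_return  sd_return  n_sessions
#      q     4.747853   1.231204         100
# random     3.679957   0.986849         100
#  never     3.223468   0.908905         100
```

The engagement scores are attention-weighted cue aggregates on [0, 1]. In
the comparison table, `mean_return` is the per-session discounted return of
the penalty-modified immediate rewards: the TD-learned greedy policy (which
here picks the true best intervention in 99.7% of its intervened steps)
clearly outperforms both the uniform-random policy and never intervening,
because one catalog arm carries a genuine +0.3 engagement effect.

The same workflows are available from the shell via the `adaptint` CLI
(`simulate`, `score`, `fit`, `run-adaptive`, `evaluate`), each driven by a
YAML config with a mandatory master seed and each emitting a
reproducibility manifest. Run `adaptint --help` for details.

## Layout

```
src/adaptint/
  scoring.py     attention weights, engagement/skill scores, greedy map
  latent.py      latent-state recursion (encoder, decay memory, gate)
  transition.py  one-step transition model and its fitting
  rewards.py     the reward stack
  policy.py      Q-table, TD updates, epsilon-greedy, closed loop
  adjustment.py  confidence windows, intensity, frequency mapping
  simulator.py   synthetic cohorts with known ground truth
  evaluation.py  paired policy evaluation
  io.py, config.py, cli.py
docs/methods.md  model assumptions, parameter defaults, limitations
```
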