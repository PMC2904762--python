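# risksteer

Risk-sensitive optimal feedback control of a stochastic ball-steering task:
controllers, closed-loop simulation, synthetic subjects and the behavioral
analysis pipeline.

## The problem

A ball travels at constant speed toward a target line, crossing it after 1 s,
while Brownian force noise pushes it sideways. A controller (a human hand, or
a model of one) exerts a lateral force and is scored by an explicit quadratic
cost: the squared lateral error where the ball crosses the line, plus the
accumulated squared control force,

```
C = w_p x_T^2 + c Σ_t u_t^2 .
```

A **risk-neutral** optimal feedback controller minimises `E[C]`. Its feedback
law is famously independent of the process-noise level: additive noise adds a
constant to the expected cost-to-go, so the policy does not change when the
world gets noisier. A **risk-sensitive** (LEQG) controller instead minimises
the exponential-of-quadratic criterion

```
γ_θ = (1/θ) log E[exp(θ C)] ≈ E[C] + (θ/2) Var[C] ,
```

which for `θ > 0` penalises cost *variance* (risk-averse) and for `θ < 0`
rewards it (risk-seeking). Its finite-horizon Riccati recursion passes the
cost-to-go through the process noise, `S̃ = (S⁻¹ − 2θΩ)⁻¹`, so the law now
depends on the noise covariance `Ω`: a risk-averse controller applies larger
feedback gains the noisier the world, up to a finite θ ("neurotic breakdown")
beyond which the criterion diverges. This noise-dependence of the policy is
the behavioral fingerprint that separates risk attitudes in steering
behavior.

The package implements, for a 2×2 design (two noise levels × two control-cost
levels, 250 analysed trials per condition):

- risk-neutral and risk-sensitive finite-horizon Riccati recursions, with
  explicit breakdown detection (`risksteer.control`);
- partial observation: sensory noise, a 150 ms visuomotor delay via state
  augmentation, offline Kalman gains, and risk-sensitive certainty
  equivalence `u = −L (I − 2θPS)⁻¹ x̂` (`risksteer.estimation`);
- a batched closed-loop simulator with per-trial reproducible noise streams,
  full cost accounting, and exact no-control counterfactuals
  (`risksteer.simulate`);
- a synthetic-subject generator: risk-sensitive controllers with individual
  θ, delay, sensory noise and execution noise (`risksteer.subjects`);
- the analysis pipeline: the no-intercept policy-plane regression of the
  control at 0.9 s on the ball state at 0.75 s, variance-weighted
  nested-model F-tests, risk-parameter inference by matching noise-driven
  gain changes against simulated predictions (`RiskSensitiveModel` →
  `RiskFitResults`), control-cost fractions, the extra expected cost of
  hedging, impact-angle counterfactuals and visuomotor-delay sweeps
  (`risksteer.analysis`).

## Worked example

Simulate a risk-averse subject (θ = 0.0012) through the 2×2 design and run
the analysis on its high-control-cost conditions:

```python
import risksteer as rs

conditions = rs.default_experiment()
spec = rs.SubjectSpec(subject_id="s1", theta=0.0012)
sets = rs.generate_subject(spec, seed=902)

for label in ("low_noise/high_cost", "high_noise/high_cost"):
    print(label)
    print(rs.fit_policy_plane(sets[label]).summary())
    cf = rs.cost_fraction(sets[label])
    print(f"  control-cost fraction: {cf.fraction:.3f} (se {cf.se:.3f})")

model = rs.RiskSensitiveModel(conditions["low_noise/high_cost"],
                              conditions["high_noise/high_cost"], seed=42)
fit = model.fit(sets["low_noise/high_cost"], sets["high_noise/high_cost"])
print(fit.summary())
```

prints

```
low_noise/high_cost
Policy-plane regression (no intercept)
  state probed at t = 0.75 s, control at t = 0.90 s, n = 250 trials
  position gain: -0.0166 (se 0.0002) N/cm
  velocity gain: -0.0038 (se 0.0001) N/(cm/s)
  R^2 (vs zero model): 0.9785
  control-cost fraction: 0.388 (se 0.017)
high_noise/high_cost
Policy-plane regression (no intercept)
  state probed at t = 0.75 s, control at t = 0.90 s, n = 250 trials
  position gain: -0.0169 (se 0.0001) N/cm
  velocity gain: -0.0043 (se 0.0000) N/(cm/s)
  R^2 (vs zero model): 0.9945
  control-cost fraction: 0.676 (se 0.018)
Risk-parameter inference from noise-driven gain changes
  conditions: low_noise/high_cost  vs  high_noise/high_cost
  observed gain change (high - low noise): position -0.0003, velocity -0.0005
  theta_hat = +0.001055  (bootstrap sd 0.000312, 95% CI [+0.0004527, +0.00161])
  attitude: risk-averse
```

Reading the output: the gain magnitudes and especially the control-cost
fraction grow with the noise level — a risk-neutral controller would keep
both flat — and matching the observed gain changes against closed-loop
simulations over a θ grid recovers the generative risk attitude, with the
95% bootstrap interval covering the true θ = 0.0012. The premium this
subject pays for hedging, relative to a risk-neutral controller under the
same noise, is

```python
rs.extra_cost_of_risk(fit.theta_hat, conditions["high_noise/high_cost"],
                      n_mc=2000, seed=1)   # -> 11.7 (% extra expected cost)
```

A command-line interface wraps the same pipeline for shell use:

```
risksteer simulate --subject-theta 0.0012 --trials 250 --seed 7 --out logs/
risksteer analyze --in logs/ --out report/
risksteer infer-theta --in logs/ --out report/
```

Trial logs are plain CSV (one row per timestep, with the injected noise
recorded so counterfactual trajectories can be reconstructed exactly), plus a
YAML manifest carrying the condition configuration and seeds.

## Layout

```
src/risksteer/
  task.py         dynamics, costs, experiment configuration (2x2 design)
  control.py      LQR / LEQG Riccati recursions, risk criterion, breakdown
  estimation.py   delay augmentation, Kalman filtering, risk-sensitive CE
  simulate.py     closed-loop batch simulator, policies, trial logs, CSV I/O
  subjects.py     synthetic subjects and cohorts
  analysis.py     regression, F-tests, theta inference, cost & angle analyses
  cli.py          command-line interface
docs/methods.md   model, assumptions, defaults, numerical choices, limits
```
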