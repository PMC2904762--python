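# Methods

## Task model

The lateral motion of the ball is a frictionless point mass, discretized by
explicit Euler with the position update using the pre-update velocity:

```
x_{t+1} = x_t + Δt v_t
v_{t+1} = v_t + Δt (u_t + ξ_t) · (100 / m)
```

with state in cm and cm/s, forces in N, mass in kg (1 N on 1 kg gives
100 cm/s²), and Δt = 10 ms over a 1 s horizon (100 steps). The random force
ξ_t is zero-mean Gaussian. Its per-step standard deviation is stated at the
10 ms reference step and rescaled by √(Δt_ref/Δt) when the integration step
changes, so the ball's displacement statistics are invariant to the
discretization (the closed-form final-position variance
(100σ/m)²·Δt_ref·T³/3 agrees within 2% between 10 ms and 1 ms steps).

The trial cost is `C = w_p x_T² + c Σ u_t²`: only the terminal lateral error
is penalised (running state cost zero), control continuously. In matrix
form `Q_final = diag(w_p, 0)`, `Q_running = 0`, `R = [c]`; for the
delay-augmented state the weights act on the current-state block only.

### Default condition parameters

The 2×2 design ships as a packaged YAML configuration; every number is
overridable. Where a quantity has a published value it is used directly
(ball speed 15 cm/s, horizon 1 s, mass 1 kg, hand-to-force gains 10 and
50 N/cm, delay 150 ms, sensory noise 0.5 cm and 5 cm/s); the remaining four
(σ per noise level, c per cost level, with w_p ≡ 1 setting the points scale)
are constrained as follows:

- `σ_low = 1.2 N`, `σ_high = 6.0 N`. The 5× ratio makes the uncontrolled
  final error exactly 5× larger in the high-noise condition (the headline
  simulation check); the absolute scale puts the uncontrolled mean |final x|
  at ≈5.5 cm — a few centimetres, large enough that the physiological
  sensory noise (0.5 cm, 5 cm/s) is negligible relative to the process
  noise, the regime the experimental design targets. With smaller σ the
  filter's sensory-noise attenuation becomes noise-level-dependent and
  masquerades as risk-sensitivity.
- `c_low = 1`, `c_high = 5` points/N² (5× apart). This sets the "control
  power" |B|²/c high enough that risk-sensitivity leaves a measurable
  fingerprint at the late-trial regression probe (see below): the
  risk-sensitive Riccati inflation compounds *backward* from the horizon, so
  late-trial gains — exactly what the regression measures — respond to θ
  only when control is cheap enough to reshape the cost-to-go near the end.
  With expensive control (fraction of control cost in total cost ≲ 0.3) the
  probed-gain separation stays below 0.5% even at 90% of breakdown and no
  analysis could detect risk attitude. At the chosen values the risk-neutral
  partially observed controller spends ≈45% (high cost) to ≈55% (low cost)
  of its total cost on control, and the probed-gain separation reaches
  5–8% near breakdown.

## Controllers

**Risk-neutral (LQR).** Backward recursion from `S_T = Q_final`:
`L_t = (R + BᵀS_{t+1}B)⁻¹ BᵀS_{t+1}A`, `S_t = Q_t + AᵀS_{t+1}(A − BL_t)`.
The law never involves Ω.

**Risk-sensitive (LEQG).** The criterion used throughout is
`γ_θ = (1/θ) log E[exp(θC)]` (θ > 0 risk-averse; Taylor expansion
`E[C] + (θ/2)Var[C] + …`). Before each backward step the cost-to-go is
inflated through the noise:

```
S̃_{t+1} = (S_{t+1}⁻¹ − 2θΩ)⁻¹ = (I − 2θ S_{t+1} Ω)⁻¹ S_{t+1}
```

then the standard step runs with S̃ in place of S. Two conventions in the
literature differ by where the factor 2 sits: with θ/2 in the exponent the
inflation carries θ. The factored form on the right is valid for singular S
(the terminal cost here is rank-1); the multiplication order matters —
`(I − 2θΩS)⁻¹S` is *not* the same matrix, and using it produces a law that a
brute-force grid search over feedback gains beats (this is tested). Breakdown
is declared when the smallest eigenvalue of `(I − 2θSΩ)` falls below 1e-10
or the inflated matrix overflows; the returned law then carries
`feasible=False` rather than silently wrong gains. All solves avoid explicit
inverses and S is re-symmetrized each step.

The sign convention is anchored two ways, both tested: (i) the γ_θ-minimising
law on small instances is found by Monte-Carlo grid search over feedback
gains (log-sum-exp estimator of γ_θ, common random numbers across the grid);
(ii) behaviorally, the θ > 0 branch applies larger position gains under
larger Ω.

## Partial observation

The controller sees `y_t = x_{t−d} + ω_t` — the physical state as it was
d = 15 steps (150 ms) ago, corrupted by sensory noise
Σω = diag(0.5², 5²) (cm, cm/s). The delay is handled by augmenting the
state with its last d values (32-dimensional state), so the observation is a
linear readout and standard Kalman filtering applies. Filter gains are
precomputed offline (linear system, known statistics); the initial state is
known exactly (P₀ = 0). The filter predicts with the *emitted* control
(efference copy), so downstream execution noise is handled correctly in
expectation. The covariance recursion runs through Ω, so estimate quality
degrades with process noise even for a risk-neutral controller — with the
default σ levels this leaks <1% into cross-condition gain comparisons.

Risk-sensitive control with partial observation couples estimation and
control through the risk-adjusted estimate

```
u_t = −L_t (I − 2θ P_t S_t)⁻¹ x̂_t ,
```

exact certainty equivalence at θ = 0. The coupling form is validated by a
Monte-Carlo policy-comparison oracle (the coupled policy achieves a
criterion value no worse than naive certainty equivalence on a scalar
partially observed instance). Near the Riccati breakdown the coupling matrix
becomes singular *first* (the θ-inflated S grows without bound), so the
feasible θ range of the partially observed controller is tighter than the
full-observation one; `lqg_breakdown_theta` bisects the combined boundary
and the inference grids use it. Within ~70% of this cap the probed gains are
monotone in θ; close to the cap the estimate-coupling can overshoot, which
is why cohort defaults stay below 0.8 of the cap.

## Synthetic subjects

A subject is a risk-sensitive partially observed controller with its own θ,
delay, sensory noise and execution noise, run through all four conditions
with independent per-trial noise streams derived from
(master seed, subject index, condition index, trial index) — any trial is
reproducible in isolation. Default 250 analysed trials per condition.

Execution noise has an additive term (N) and a signal-dependent term
(standard deviation = cv·|u|). Both default to zero: the ideal controller
the theory describes has no motor noise, and parameter-recovery experiments
use these defaults. Data-emulating cohorts use cv = 0.5
(`DEFAULT_EXECUTION_CV`), chosen so the policy-plane R² lands near 0.8 in
*all four* conditions, as human subjects show; a purely additive noise
cannot do that because the command scale differs ~5× between cost
conditions (signal-dependence is also why the experiment re-scaled the
hand-to-force gain between noise levels). The generator emulates
steady-state behavior only — no trial-by-trial learning or adaptation — so
passing tests say nothing about adaptation phases of real experiments; the
first 100 of 350 trials a real session would contain are simply not
generated.

## Behavioral analysis

**Policy plane.** Per trial, the control at t = 0.9 s is regressed on the
ball's position and velocity at t = 0.75 s with *no intercept* (the fit is a
plane through the origin of state-control space; R² is computed against the
zero model). One observation per trial, never pooled timepoints. On
noiseless undelayed linear-feedback data at zero lag the estimator returns
the generative gains exactly.

**Nested-model F-test.** The full model fits both conditions with separate
position and velocity slopes (4 predictors); the reduced model shares one
slope (3 predictors). Residual variance differs ~25× between noise
conditions (control magnitudes scale with σ), which would leave a raw pooled
F-test mis-calibrated (observed null rejection rate 0 instead of 5%), so
each condition's rows are weighted by its own separate-fit residual standard
deviation before pooling (feasible GLS; measured type-I rate 5.8% at
α = 0.05 over 120 null replicates). Per-subject tests are not corrected for
multiple comparisons. At 250 trials/condition the achievable power of the
position-slope test against a feasible risk-averse alternative is ~50%: the
model's probed-gain separations (≤8%) are smaller than those human subjects
exhibit.

**Risk-parameter inference** (`RiskSensitiveModel`). For each θ on a
log-spaced grid (50 points per branch, capped at 0.9× the per-condition-pair
breakdown, three decades deep) the partially observed controller is
simulated closed-loop in both noise conditions (default 2000 trials each,
common random numbers across θ so the predicted manifold is smooth) and the
*same* policy-plane estimator is applied. A subject's observed
(Δposition gain, Δvelocity gain) between noise conditions is matched to the
manifold by minimum Mahalanobis distance; the weight matrix is the inverse
of the observed coefficient covariance *plus* the manifold's own Monte-Carlo
coefficient covariance — the manifold error is shared across every subject
analysed with that model, so ignoring it biases all estimates in the same
direction. Uncertainty comes from a trial bootstrap (default 1000
resamples); estimates at the grid edge are flagged as extrapolated.
θ is best identified on the high-cost condition pair, whose feasible range
is narrowest so a given θ sits at a large fraction of breakdown; on the
low-cost pair the same θ produces a ~4× smaller signature and small θ are
only weakly identified (wide bootstrap intervals, used for the cross-pair
consistency check). Below ~40% of the cap single-subject estimates are
noise-dominated; recovery experiments therefore probe the upper half of the
feasible range.

**Cost decomposition.** Control-cost fraction = mean control cost / mean
total cost, with a delta-method standard error over trials. Noise-invariant
at θ = 0; increasing in noise for risk-averse, decreasing for risk-seeking.

**Extra cost of hedging.** Risk-sensitive and risk-neutral partially
observed controllers simulated under identical noise streams; reported as
percent extra expected cost. Zero exactly at θ = 0, non-negative and
increasing on the risk-averse branch.

**Delay sweep.** The probed state time is fixed (0.75 s) and the control
time swept; R² peaks at the generative 150 ms delay. Sweeping the state
time backward at a fixed control time instead biases the peak ~30–40 ms
late, because the filter's estimate is a weighted average over older states.
In conditions where sensory noise is relatively large (low noise × low
state excursions) the peak can sit one to three 10 ms grid steps late even
with the adopted convention.

**Impact angles.** The angle between the final velocity vector and the
target line (90° = orthogonal, tolerance ±5°, both configurable), counted
for the actual trajectories and for the no-control counterfactuals
re-integrated from the logged noise streams (exact by linear superposition;
tested to 1e-10). A known limitation: human subjects *decreased* their
orthogonal-impact probability by intervening, but the optimal controller
here always increases it — its closed-loop terminal-velocity impulse
response has magnitude ≤1 at every kick time for every cost level, noise
level and feasible θ tested, so feedback always shrinks the terminal
lateral-velocity spread. The direction observed in humans is not a property
of this controller class under these task parameters.

## Numerical choices

- Breakdown detection: smallest eigenvalue of (I − 2θSΩ) below 1e-10, or
  overflow of the inflated cost-to-go; bisection locates the boundary to
  1e-6 relative.
- Kalman update in Joseph form; singular innovation covariances (noise-free
  channels) handled by pseudo-inverse, so Σω → 0 reduces exactly to the
  fully observed controller path-by-path.
- Monte-Carlo γ_θ via log-sum-exp; an infinite estimate is reported as
  breakdown evidence, never an overflow.
- Degenerate regressions (all-zero response at the final step, where the
  optimal gain is exactly zero because a force in the last step cannot move
  the position) return R² = 0 rather than NaN.
- The trial-log CSV round-trips states, controls and noise to ~1e-9
  (decimal text); costs are recomputed from the logged arrays on read.

## Known limitations

- No signal-dependent noise *in the controller's model* (no closed-form
  risk-sensitive law exists for multiplicative noise); execution noise in
  the generator is a data-realism feature the controller is unaware of.
- The risk-sensitive filter is the standard Kalman filter plus the
  certainty-equivalent coupling; the fully coupled information-state
  solution is not implemented. The coupling is oracle-validated on small
  instances and behaves monotonically only below ~70–80% of the breakdown
  cap.
- Inference precision at 250 trials/condition is intrinsically limited by
  the small probed-gain signature; sign and magnitude recover well in the
  upper half of the feasible θ range, poorly near θ = 0.
- The orthogonal-impact direction seen in human data is outside this model
  class (see above).
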