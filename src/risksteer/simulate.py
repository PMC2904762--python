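"""Closed-loop trial simulation with full cost accounting and replayable noise.

Every trial logs its complete noise stream alongside states and controls, so
counterfactual trajectories (what the ball would have done had the controller
not intervened) can be reconstructed exactly — the same bookkeeping the
original experiment relied on.

Randomness is organised as one independent stream per trial, derived from
``(master_seed, subject, condition, trial index)``, so any trial can be
reproduced bit-exactly on its own and batches can be generated in any order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .control import ControlLaw
from .estimation import ObservationModel, augment_for_delay, precompute_filter
from .task import CM_PER_M, TaskConfig, build_cost, discretize_dynamics

__all__ = [
    "TrialRecord",
    "TrialSet",
    "NullPolicy",
    "FeedbackPolicy",
    "LQGPolicy",
    "run_trial",
    "simulate_batch",
    "counterfactual_no_control",
    "trial_rng",
    "write_trialset",
    "read_trialset",
]


class SimulationError(RuntimeError):
    pass


def trial_rng(
    master_seed: int, subject: int = 0, condition: int = 0, trial: int = 0
) -> np.random.Generator:
    """Independent, reproducible RNG stream for one trial."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(master_seed), spawn_key=(subject, condition, trial))
    )


@dataclass
class TrialRecord:
    """One simulated trial: per-step arrays plus cost/impact summaries.

    States have ``steps + 1`` samples (t = 0..T), controls and noise forces
    ``steps`` samples.  ``xi_N`` is the random force actually applied each
    step (N), recorded for counterfactual reconstruction.
    """

    time_s: np.ndarray
    x_cm: np.ndarray
    v_cm_s: np.ndarray
    u_N: np.ndarray
    xi_N: np.ndarray
    error_cost: float
    control_cost: float
    total_cost: float
    final_x_cm: float
    impact_angle_deg: float

    @property
    def n_steps(self) -> int:
        return len(self.u_N)


def _impact_angle_deg(vx_final: float, vy: float) -> float:
    """Angle between the final velocity vector and the target line, degrees.

    The line is horizontal and the ball approaches at constant forward speed
    ``vy``; a purely forward impact is 90 deg, lateral drift tilts the angle
    toward 0 (rightward) or 180 (leftward).
    """
    return float(np.degrees(np.arctan2(vy, vx_final)))


def _make_record(
    cfg: TaskConfig, x: np.ndarray, v: np.ndarray, u: np.ndarray, xi: np.ndarray
) -> TrialRecord:
    steps = cfg.n_steps
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(v)) and np.all(np.isfinite(u))):
        bad = np.flatnonzero(~(np.isfinite(x) & np.isfinite(v)))
        step = int(bad[0]) if bad.size else -1
        raise SimulationError(f"non-finite state encountered at step {step}")
    err = cfg.error_weight * float(x[-1]) ** 2
    ctl = cfg.control_weight * float(np.sum(u**2))
    return TrialRecord(
        time_s=np.arange(steps + 1) * cfg.dt_s,
        x_cm=x,
        v_cm_s=v,
        u_N=u,
        xi_N=xi,
        error_cost=err,
        control_cost=ctl,
        total_cost=err + ctl,
        final_x_cm=float(x[-1]),
        impact_angle_deg=_impact_angle_deg(float(v[-1]), cfg.ball_speed_y_cm_s),
    )


# ---------------------------------------------------------------------------
# Policies
# ---------------------------------------------------------------------------


class NullPolicy:
    """No intervention: u = 0 always (uncontrolled Brownian drift)."""

    delay_steps = 0
    obs_noise_dim = 0

    def begin(self, n_trials: int) -> None:
        self._n = n_trials

    def step(self, t, x_now, x_delayed, obs_noise):
        return np.zeros(self._n)

    def notify_emitted(self, u):
        pass


class FeedbackPolicy:
    """Full state observation, no delay: u_t = -L_t [x, v]."""

    delay_steps = 0
    obs_noise_dim = 0

    def __init__(self, law: ControlLaw):
        self.law = law

    def begin(self, n_trials: int) -> None:
        pass

    def step(self, t, x_now, x_delayed, obs_noise):
        return self.law.control(t, x_now)[:, 0]

    def notify_emitted(self, u):
        pass


class LQGPolicy:
    """Partial observation with sensory noise and sensorimotor delay.

    Solves the risk-sensitive control problem on the delay-augmented state,
    precomputes the time-varying Kalman gains offline, and at run time applies
    the feedback gains to the risk-adjusted estimate
    (I - 2 theta P_t S_t)^-1 x_hat_t.  The filter predicts with the *emitted*
    control (efference copy), so execution noise added downstream is still
    accounted for correctly in expectation.
    """

    def __init__(
        self,
        cfg: TaskConfig,
        obs: ObservationModel,
        theta: float = 0.0,
        law: ControlLaw | None = None,
    ):
        from .control import riccati_risk_sensitive

        self.cfg = cfg
        self.obs_physical = obs
        dyn = discretize_dynamics(cfg)
        cost = build_cost(cfg)
        dyn_a, cost_a, obs_a = augment_for_delay(dyn, cost, obs)
        steps = cfg.n_steps
        if law is None:
            law = riccati_risk_sensitive(dyn_a, cost_a, steps, theta)
        if not law.feasible:
            from .control import RiccatiBreakdownError

            raise RiccatiBreakdownError(
                f"theta={theta} is beyond breakdown for condition "
                f"{cfg.condition_label!r}"
            )
        self.law = law
        self.dyn_aug, self.obs_aug = dyn_a, obs_a
        self.K, self.P = precompute_filter(dyn_a, obs_a, steps)
        nz = dyn_a.state_dim
        # Effective gains on the filter mean: L_t (I - 2 theta P_t S_t)^-1.
        self.gains_eff = np.empty((steps, law.gains.shape[1], nz))
        for t in range(steps):
            if theta == 0.0:
                self.gains_eff[t] = law.gains[t]
            else:
                M = np.eye(nz) - 2.0 * theta * self.P[t] @ law.cost_to_go[t]
                # Estimation-side breakdown: the risk-adjusted estimate
                # diverges when 2*theta*P*S reaches a unit eigenvalue.
                if np.max(np.linalg.eigvals(2.0 * theta * self.P[t] @ law.cost_to_go[t]).real) >= 1.0 - 1e-9:
                    from .control import RiccatiBreakdownError

                    raise RiccatiBreakdownError(
                        f"theta={theta}: risk-adjusted estimate diverges at step {t} "
                        f"(estimation-side breakdown) in condition {cfg.condition_label!r}"
                    )
                self.gains_eff[t] = np.linalg.solve(M.T, law.gains[t].T).T
        self._obs_chol = _psd_sqrt(obs.Sigma_omega)

    @property
    def delay_steps(self) -> int:
        return self.obs_physical.delay_steps

    @property
    def obs_noise_dim(self) -> int:
        return self.obs_physical.obs_dim

    def begin(self, n_trials: int) -> None:
        self._xhat = np.zeros((n_trials, self.dyn_aug.state_dim))
        self._u_prev = np.zeros((n_trials, 1))

    def step(self, t, x_now, x_delayed, obs_noise):
        if t > 0:
            pred = self._xhat @ self.dyn_aug.A.T + self._u_prev @ self.dyn_aug.B.T
            y = x_delayed @ self.obs_physical.H.T + obs_noise @ self._obs_chol.T
            innov = y - pred @ self.obs_aug.H.T
            self._xhat = pred + innov @ self.K[t].T
        return -(self._xhat @ self.gains_eff[t].T)[:, 0]

    def notify_emitted(self, u):
        self._u_prev = u.reshape(-1, 1)


def _psd_sqrt(M: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(M)
    return V * np.sqrt(np.clip(w, 0.0, None)) @ V.T


def lqg_breakdown_theta(
    cfg: TaskConfig, obs: ObservationModel, upper: float = 10.0, tol: float = 1e-4
) -> float:
    """Largest risk-averse theta for which the partially observed controller
    exists: both the LEQG Riccati recursion and the risk-adjusted estimate
    coupling must stay finite.  The coupling (which passes the filter
    covariance through the inflated cost-to-go) typically binds first.
    """
    from .control import RiccatiBreakdownError

    def feasible(th: float) -> bool:
        try:
            LQGPolicy(cfg, obs, theta=th)
            return True
        except RiccatiBreakdownError:
            return False

    lo, hi = 0.0, upper
    if feasible(hi):
        return hi
    while hi - lo > tol * max(1.0, lo):
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            lo = mid
        else:
            hi = mid
    return lo


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate_batch(
    cfg: TaskConfig,
    policy,
    n_trials: int,
    master_seed: int,
    subject: int = 0,
    condition: int = 0,
    trial_offset: int = 0,
    motor_noise_sd: float = 0.0,
    motor_noise_cv: float = 0.0,
) -> list[TrialRecord]:
    """Simulate ``n_trials`` closed-loop trials, vectorised over trials.

    Each trial draws its noise from its own stream (see :func:`trial_rng`), so
    the result is identical whether trials are run singly or in a batch, and
    the process-noise stream of trial i is the same under any policy —
    enabling paired (common-random-number) controller comparisons.

    Execution noise on the emitted control has an additive part
    (``motor_noise_sd``, N) and a signal-dependent part (``motor_noise_cv``,
    fraction of the commanded force), the latter matching how human motor
    variability scales with command magnitude.  The emitted (noisy) control
    is what is logged, applied to the ball, and fed back to the policy's
    forward model as efference copy.
    """
    steps = cfg.n_steps
    dt = cfg.dt_s
    gain = dt * CM_PER_M / cfg.mass_kg
    xi_sd = cfg.noise_force_sd_per_step
    d = policy.delay_steps
    od = policy.obs_noise_dim

    has_motor = motor_noise_sd > 0 or motor_noise_cv > 0
    xi = np.empty((n_trials, steps))
    obs_z = np.zeros((n_trials, steps, max(od, 1)))
    motor_z = np.zeros((n_trials, steps))
    for i in range(n_trials):
        rng = trial_rng(master_seed, subject, condition, trial_offset + i)
        xi[i] = rng.normal(0.0, xi_sd, steps)
        if od:
            obs_z[i, :, :od] = rng.standard_normal((steps, od))
        if has_motor:
            motor_z[i] = rng.standard_normal(steps)

    X = np.zeros((n_trials, steps + 1))
    V = np.zeros((n_trials, steps + 1))
    U = np.zeros((n_trials, steps))
    state = np.zeros((n_trials, 2))
    policy.begin(n_trials)
    for t in range(steps):
        t_del = max(t - d, 0)
        x_delayed = np.column_stack([X[:, t_del], V[:, t_del]])
        u = policy.step(t, state, x_delayed, obs_z[:, t, :od])
        if has_motor:
            u = u + (motor_noise_sd + motor_noise_cv * np.abs(u)) * motor_z[:, t]
        policy.notify_emitted(u)
        U[:, t] = u
        X[:, t + 1] = X[:, t] + dt * V[:, t]
        V[:, t + 1] = V[:, t] + gain * (u + xi[:, t])
        state = np.column_stack([X[:, t + 1], V[:, t + 1]])

    return [_make_record(cfg, X[i], V[i], U[i], xi[i]) for i in range(n_trials)]


def run_trial(cfg: TaskConfig, policy, seed: int, **kwargs) -> TrialRecord:
    """Simulate a single trial (see :func:`simulate_batch`)."""
    return simulate_batch(cfg, policy, 1, master_seed=seed, **kwargs)[0]


def counterfactual_no_control(trial: TrialRecord, cfg: TaskConfig) -> TrialRecord:
    """Re-integrate a logged trial with u = 0 and the recorded noise stream.

    Deterministic given the log; answers "where would the ball have gone had
    the controller not intervened".
    """
    if trial.xi_N is None or len(trial.xi_N) != cfg.n_steps:
        raise ValueError("trial log is missing its noise stream")
    steps = cfg.n_steps
    dt = cfg.dt_s
    gain = dt * CM_PER_M / cfg.mass_kg
    x = np.zeros(steps + 1)
    v = np.zeros(steps + 1)
    for t in range(steps):
        x[t + 1] = x[t] + dt * v[t]
        v[t + 1] = v[t] + gain * trial.xi_N[t]
    return _make_record(cfg, x, v, np.zeros(steps), np.asarray(trial.xi_N, float))


# ---------------------------------------------------------------------------
# Trial sets and delimited-text I/O
# ---------------------------------------------------------------------------


@dataclass
class TrialSet:
    """All analysed trials of one subject in one condition."""

    condition_label: str
    subject_id: str
    theta_true: float
    trials: list[TrialRecord]
    rng_seed: int
    config: TaskConfig

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def to_timestep_frame(self) -> pd.DataFrame:
        """Long-format per-timestep table, one row per (trial, step)."""
        frames = []
        for j, tr in enumerate(self.trials):
            steps = tr.n_steps
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": self.subject_id,
                        "condition": self.condition_label,
                        "trial": j,
                        "t_s": tr.time_s,
                        "x_cm": tr.x_cm,
                        "v_cm_s": tr.v_cm_s,
                        "u_N": np.append(tr.u_N, np.nan),
                        "xi_N": np.append(tr.xi_N, np.nan),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "condition": self.condition_label,
                "trial": np.arange(self.n_trials),
                "error_cost": [t.error_cost for t in self.trials],
                "control_cost": [t.control_cost for t in self.trials],
                "total_cost": [t.total_cost for t in self.trials],
                "final_x_cm": [t.final_x_cm for t in self.trials],
                "impact_angle_deg": [t.impact_angle_deg for t in self.trials],
            }
        )


def _slug(label: str) -> str:
    return label.replace("/", "_")


def write_trialset(ts: TrialSet, out_dir: str | Path) -> Path:
    """Write a trial set as CSV trial logs + summary + YAML manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = f"{ts.subject_id}_{_slug(ts.condition_label)}"
    ts.to_timestep_frame().to_csv(out / f"{stem}_trials.csv", index=False)
    ts.summary_frame().to_csv(out / f"{stem}_summary.csv", index=False)
    manifest = {
        "subject_id": ts.subject_id,
        "condition_label": ts.condition_label,
        "theta_true": float(ts.theta_true),
        "rng_seed": int(ts.rng_seed),
        "config": {
            k: (float(v) if isinstance(v, (int, float)) and k != "condition_label" else v)
            for k, v in ts.config.__dict__.items()
        },
    }
    with open(out / f"{stem}_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return out / f"{stem}_trials.csv"


def read_trialset(out_dir: str | Path, subject_id: str, condition_label: str) -> TrialSet:
    """Round-trip reader for :func:`write_trialset` output."""
    out = Path(out_dir)
    stem = f"{subject_id}_{_slug(condition_label)}"
    with open(out / f"{stem}_manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    cfg = TaskConfig(**manifest["config"])
    df = pd.read_csv(out / f"{stem}_trials.csv")
    trials = []
    for _, g in df.groupby("trial", sort=True):
        g = g.sort_values("t_s")
        x = g["x_cm"].to_numpy()
        v = g["v_cm_s"].to_numpy()
        u = g["u_N"].to_numpy()[:-1]
        xi = g["xi_N"].to_numpy()[:-1]
        trials.append(_make_record(cfg, x, v, u, xi))
    return TrialSet(
        condition_label=manifest["condition_label"],
        subject_id=manifest["subject_id"],
        theta_true=manifest["theta_true"],
        trials=trials,
        rng_seed=manifest["rng_seed"],
        config=cfg,
    )
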