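"""Ball-steering task as a discrete-time linear-Gaussian system with quadratic cost.

The task: a ball travels at constant speed toward a target line, reaching it
after ``horizon_s`` seconds, while random forces (Brownian force noise) push it
sideways.  The controller exerts a lateral force to keep the ball near the
centre of the line.  Performance is scored by a quadratic cost on the final
lateral deviation plus a cumulative quadratic cost on the control force.

Lateral dynamics are a frictionless point mass integrated by explicit Euler;
the state is ``[x, v]`` with position in cm and velocity in cm/s, and forces
in N on a mass in kg (1 N on 1 kg gives 100 cm/s^2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "TaskConfig",
    "LinearDynamics",
    "CostSpec",
    "discretize_dynamics",
    "build_cost",
    "load_experiment_config",
    "default_experiment",
    "CM_PER_M",
    "REFERENCE_DT_S",
]

#: cm per m: converts an acceleration in m/s^2 (= N/kg) to cm/s^2.
CM_PER_M = 100.0

#: Reference time step (s) at which ``process_noise_sd`` is stated.  The
#: per-step force variance is rescaled by (REFERENCE_DT_S / dt) so that the
#: ball's displacement statistics do not depend on the integration step.
REFERENCE_DT_S = 0.01


class ConfigurationError(ValueError):
    """Raised for physically or numerically invalid task parameters."""


@dataclass(frozen=True)
class TaskConfig:
    """Physical and experimental parameters of one task condition.

    Parameters
    ----------
    mass_kg : float
        Ball mass ``m``.
    dt_s : float
        Integration time step (default 10 ms).
    horizon_s : float
        Trial duration; the ball crosses the target line at this time.
    ball_speed_y_cm_s : float
        Constant forward (y) speed of the ball in cm/s.
    target_distance_cm : float
        Distance from start to target line; must equal speed x duration.
    process_noise_sd : float
        Standard deviation sigma of the random lateral force in N, stated at
        the 10 ms reference step.
    hand_force_gain_N_per_cm : float
        Gain ``k`` mapping hand displacement (cm) to ball force (N); only used
        to report hand kinematics, the control law works in force units.
    error_weight : float
        Terminal positional cost weight ``w_p`` (points per cm^2).
    control_weight : float
        Per-step control cost weight ``c`` (points per N^2); must be positive
        so the Riccati step is well posed.
    condition_label : str
        Free-form label, e.g. ``"low_noise/high_cost"``.
    """

    mass_kg: float = 1.0
    dt_s: float = 0.01
    horizon_s: float = 1.0
    ball_speed_y_cm_s: float = 15.0
    target_distance_cm: float = 15.0
    process_noise_sd: float = 1.2
    hand_force_gain_N_per_cm: float = 10.0
    error_weight: float = 1.0
    control_weight: float = 5.0
    condition_label: str = "low_noise/high_cost"

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ConfigurationError(f"dt_s must be positive, got {self.dt_s}")
        if self.mass_kg <= 0:
            raise ConfigurationError(f"mass_kg must be positive, got {self.mass_kg}")
        if self.horizon_s <= 0:
            raise ConfigurationError("horizon_s must be positive")
        n = self.horizon_s / self.dt_s
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"horizon_s/dt_s = {n} is not an integer number of steps"
            )
        if self.process_noise_sd < 0:
            raise ConfigurationError("process_noise_sd must be non-negative")
        if self.error_weight < 0:
            raise ConfigurationError("error_weight must be non-negative")
        if self.control_weight <= 0:
            raise ConfigurationError(
                "control_weight must be positive (the control cost must be "
                "invertible in the Riccati recursion)"
            )
        expected = self.ball_speed_y_cm_s * self.horizon_s
        if abs(self.target_distance_cm - expected) > 1e-6 * max(1.0, expected):
            raise ConfigurationError(
                f"target_distance_cm={self.target_distance_cm} inconsistent with "
                f"ball_speed_y_cm_s*horizon_s={expected}"
            )

    @property
    def n_steps(self) -> int:
        """Number of integration steps in one trial."""
        return round(self.horizon_s / self.dt_s)

    @property
    def noise_force_sd_per_step(self) -> float:
        """Std of the random force actually drawn each step (N), after the
        dt-invariance rescaling."""
        return self.process_noise_sd * np.sqrt(REFERENCE_DT_S / self.dt_s)

    def with_(self, **kwargs) -> "TaskConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class LinearDynamics:
    """Discrete-time linear-Gaussian dynamics x_{t+1} = A x_t + B u_t + xi_t.

    ``A`` is the state transition over ``[x (cm), v (cm/s)]``, ``B`` maps a
    control force in N to the state increment, and ``Omega`` is the process
    noise covariance (noise enters through the velocity channel only).
    """

    A: np.ndarray
    B: np.ndarray
    Omega: np.ndarray

    def __post_init__(self) -> None:
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        B = np.atleast_2d(np.asarray(self.B, dtype=float))
        Om = np.atleast_2d(np.asarray(self.Omega, dtype=float))
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "Omega", Om)
        n = A.shape[0]
        if A.shape != (n, n):
            raise ValueError("A must be square")
        if B.shape[0] != n:
            raise ValueError("B row dimension must match A")
        if Om.shape != (n, n):
            raise ValueError("Omega must match the state dimension")
        if not np.allclose(Om, Om.T):
            raise ValueError("Omega must be symmetric")
        if np.min(np.linalg.eigvalsh((Om + Om.T) / 2)) < -1e-10:
            raise ValueError("Omega must be positive semi-definite")

    @property
    def state_dim(self) -> int:
        return self.A.shape[0]

    @property
    def control_dim(self) -> int:
        return self.B.shape[1]


@dataclass(frozen=True)
class CostSpec:
    """Quadratic cost: terminal state cost + per-step control cost.

    Only the final positional error is penalised, so the running state cost is
    zero: total cost = x_T' Q_final x_T + sum_t u_t' R u_t.
    """

    Q_running: np.ndarray
    Q_final: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        Qr = np.atleast_2d(np.asarray(self.Q_running, dtype=float))
        Qf = np.atleast_2d(np.asarray(self.Q_final, dtype=float))
        R = np.atleast_2d(np.asarray(self.R, dtype=float))
        object.__setattr__(self, "Q_running", Qr)
        object.__setattr__(self, "Q_final", Qf)
        object.__setattr__(self, "R", R)
        for name, M in (("Q_running", Qr), ("Q_final", Qf)):
            if not np.allclose(M, M.T):
                raise ValueError(f"{name} must be symmetric")
            if np.min(np.linalg.eigvalsh(M)) < -1e-10:
                raise ValueError(f"{name} must be positive semi-definite")
        if np.min(np.linalg.eigvalsh((R + R.T) / 2)) <= 0:
            raise ConfigurationError("R must be positive definite")

    def trial_cost(self, x_final: np.ndarray, controls: np.ndarray) -> tuple[float, float]:
        """(error_cost, control_cost) of one logged trial.

        ``x_final`` is the terminal state, ``controls`` the (steps, m) control
        sequence.
        """
        x = np.asarray(x_final, dtype=float).reshape(-1)
        u = np.atleast_2d(np.asarray(controls, dtype=float))
        if u.shape[1] != self.R.shape[0]:
            u = u.reshape(-1, self.R.shape[0])
        err = float(x @ self.Q_final @ x)
        ctl = float(np.einsum("ti,ij,tj->", u, self.R, u))
        return err, ctl


def discretize_dynamics(cfg: TaskConfig) -> LinearDynamics:
    """Explicit-Euler discretization of the frictionless lateral dynamics.

    Position is advanced with the pre-update velocity, velocity with the total
    force divided by the mass: A = [[1, dt], [0, 1]],
    B = [[0], [dt * 100 / m]] (cm state, N force).  The process-noise
    covariance uses the dt-rescaled per-step force variance so that
    trajectory statistics are invariant to the integration step.
    """
    dt = cfg.dt_s
    gain = dt * CM_PER_M / cfg.mass_kg  # cm/s change per N of force
    A = np.array([[1.0, dt], [0.0, 1.0]])
    B = np.array([[0.0], [gain]])
    sd = cfg.noise_force_sd_per_step
    Omega = np.array([[0.0, 0.0], [0.0, (gain * sd) ** 2]])
    return LinearDynamics(A=A, B=B, Omega=Omega)


def build_cost(cfg: TaskConfig, state_dim: int = 2) -> CostSpec:
    """Quadratic cost matrices for a condition.

    ``Q_final`` puts ``error_weight`` on the position-position entry and zeros
    elsewhere; the running state cost is zero; ``R = [[control_weight]]``.
    For an augmented (delay) state pass the augmented ``state_dim``: weights
    land on the current-state block only.
    """
    Qf = np.zeros((state_dim, state_dim))
    Qf[0, 0] = cfg.error_weight
    Qr = np.zeros((state_dim, state_dim))
    R = np.array([[cfg.control_weight]])
    return CostSpec(Q_running=Qr, Q_final=Qf, R=R)


# ---------------------------------------------------------------------------
# Experiment configuration files
# ---------------------------------------------------------------------------

_CONDITION_KEYS = (
    "low_noise/low_cost",
    "high_noise/low_cost",
    "low_noise/high_cost",
    "high_noise/high_cost",
)


def _cfg_from_mapping(label: str, shared: Mapping, block: Mapping) -> TaskConfig:
    merged = {**shared, **block}
    merged.setdefault("condition_label", label)
    return TaskConfig(**merged)


def load_experiment_config(path: str | Path) -> dict[str, TaskConfig]:
    """Load a hierarchical YAML experiment configuration.

    Layout: optional top-level ``shared`` mapping with fields common to all
    conditions, plus a ``conditions`` mapping of label -> field overrides.
    Returns a dict label -> :class:`TaskConfig`.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    shared = doc.get("shared", {}) or {}
    conditions = doc.get("conditions", {}) or {}
    if not conditions:
        raise ConfigurationError(f"no conditions defined in {path}")
    return {
        label: _cfg_from_mapping(label, shared, block or {})
        for label, block in conditions.items()
    }


def default_experiment() -> dict[str, TaskConfig]:
    """The packaged 2x2 design: {low, high} noise x {low, high} control cost.

    High-condition noise sd is 5x the low one (so uncontrolled final error is
    5x larger); the hand-to-force gain is 10 N/cm (low noise) and 50 N/cm
    (high noise) to equalise hand excursions across noise levels.
    """
    ref = resources.files("risksteer.data").joinpath("default_experiment.yaml")
    with resources.as_file(ref) as p:
        return load_experiment_config(p)
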