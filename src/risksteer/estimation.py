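"""Partial state observation: sensory noise, sensorimotor delay, Kalman filtering.

The controller does not see the ball's state directly; it sees a noisy copy of
the state as it was ``d`` time steps ago (the visuomotor latency, 150 ms by
default).  The delay is modelled by augmenting the state with its last ``d``
values, so that the delayed observation is a linear readout of the augmented
state and standard Kalman filtering applies.

Risk-sensitive control with partial observation does not separate cleanly into
estimation plus control, but a risk-sensitive certainty-equivalence principle
holds: the optimal control applies the full-observation gains to a
risk-adjusted estimate that couples the filter mean, the filter covariance,
the cost-to-go and theta,

    x_check_t = (I - 2 theta P_t S_t)^-1 x_hat_t,      u_t = -L_t x_check_t.

For ``theta = 0`` this is classic certainty-equivalent LQG.  Risk-averse
``theta > 0`` inflates the estimate along directions where estimation error
would be costly — the controller hedges against its own uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .control import ControlLaw, RiccatiBreakdownError
from .task import CostSpec, LinearDynamics

__all__ = [
    "ObservationModel",
    "FilterState",
    "default_observation_model",
    "augment_for_delay",
    "kalman_step",
    "precompute_filter",
    "risk_sensitive_estimate",
]


@dataclass(frozen=True)
class ObservationModel:
    """y_t = H z_t + omega_t with omega ~ N(0, Sigma_omega).

    ``delay_steps`` is the sensorimotor delay d in integration steps (15 at
    dt = 10 ms -> 150 ms).  ``H`` and ``Sigma_omega`` refer to the *physical*
    state that is observed; :func:`augment_for_delay` rewires them to read the
    d-step-old block of the augmented state.
    """

    H: np.ndarray
    Sigma_omega: np.ndarray
    delay_steps: int = 15

    def __post_init__(self) -> None:
        H = np.atleast_2d(np.asarray(self.H, dtype=float))
        Sw = np.atleast_2d(np.asarray(self.Sigma_omega, dtype=float))
        object.__setattr__(self, "H", H)
        object.__setattr__(self, "Sigma_omega", Sw)
        if not np.allclose(Sw, Sw.T):
            raise ValueError("Sigma_omega must be symmetric")
        if np.min(np.linalg.eigvalsh(Sw)) < -1e-10:
            raise ValueError("Sigma_omega must be positive semi-definite")
        if self.delay_steps < 0:
            raise ValueError("delay_steps must be >= 0")
        if Sw.shape[0] != H.shape[0]:
            raise ValueError("Sigma_omega must match the observation dimension")

    @property
    def obs_dim(self) -> int:
        return self.H.shape[0]


def default_observation_model(delay_steps: int = 15) -> ObservationModel:
    """Full observation of position and velocity with physiological sensory
    noise: 0.5 cm on position, 5 cm/s on velocity."""
    return ObservationModel(
        H=np.eye(2),
        Sigma_omega=np.diag([0.5**2, 5.0**2]),
        delay_steps=delay_steps,
    )


@dataclass
class FilterState:
    """Kalman filter state: estimate mean, covariance and current gain."""

    x_hat: np.ndarray
    P: np.ndarray
    K: np.ndarray | None = None


def augment_for_delay(
    dyn: LinearDynamics, cost: CostSpec, obs: ObservationModel
) -> tuple[LinearDynamics, CostSpec, ObservationModel]:
    """State augmentation for a d-step observation delay.

    The augmented state stacks the current physical state with its last d
    values, z_t = [x_t, x_{t-1}, ..., x_{t-d}]; the transition shifts the
    history down and applies (A, B) to the current block; process noise enters
    the current block only; the observation reads the oldest block through H;
    costs act on the current block.  With d = 0 the inputs are returned
    unchanged.
    """
    d = obs.delay_steps
    if d == 0:
        return dyn, cost, obs
    n = dyn.state_dim
    nz = n * (d + 1)

    A_aug = np.zeros((nz, nz))
    A_aug[:n, :n] = dyn.A
    for i in range(d):  # block row i+1 copies block i of the previous state
        A_aug[(i + 1) * n : (i + 2) * n, i * n : (i + 1) * n] = np.eye(n)
    B_aug = np.zeros((nz, dyn.control_dim))
    B_aug[:n, :] = dyn.B
    Om_aug = np.zeros((nz, nz))
    Om_aug[:n, :n] = dyn.Omega

    Qf_aug = np.zeros((nz, nz))
    Qf_aug[:n, :n] = cost.Q_final
    Qr_aug = np.zeros((nz, nz))
    Qr_aug[:n, :n] = cost.Q_running

    H_aug = np.zeros((obs.H.shape[0], nz))
    H_aug[:, d * n :] = obs.H

    return (
        LinearDynamics(A=A_aug, B=B_aug, Omega=Om_aug),
        CostSpec(Q_running=Qr_aug, Q_final=Qf_aug, R=cost.R),
        ObservationModel(H=H_aug, Sigma_omega=obs.Sigma_omega, delay_steps=0),
    )


def _posterior_update(
    x_pred: np.ndarray, P_pred: np.ndarray, y: np.ndarray, H: np.ndarray, Sw: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    innov_cov = H @ P_pred @ H.T + Sw
    # pinv tolerates a singular innovation covariance (noise-free channels).
    K = P_pred @ H.T @ np.linalg.pinv(innov_cov, hermitian=True, rcond=1e-12)
    x_post = x_pred + K @ (y - H @ x_pred)
    I_KH = np.eye(P_pred.shape[0]) - K @ H
    # Joseph form keeps P symmetric PSD.
    P_post = I_KH @ P_pred @ I_KH.T + K @ Sw @ K.T
    return x_post, (P_post + P_post.T) / 2.0, K


def kalman_step(
    fs: FilterState,
    y: np.ndarray,
    u: np.ndarray,
    dyn: LinearDynamics,
    obs: ObservationModel,
) -> FilterState:
    """One predict-correct cycle.

    Predicts through the (augmented) dynamics with the emitted control ``u``,
    then corrects with the observation ``y``.  The covariance recursion runs
    through Omega, so the estimate quality degrades with process noise even
    for a risk-neutral controller.
    """
    x_pred = dyn.A @ fs.x_hat + (dyn.B @ np.atleast_1d(u)).reshape(-1)
    P_pred = dyn.A @ fs.P @ dyn.A.T + dyn.Omega
    x_post, P_post, K = _posterior_update(x_pred, P_pred, np.asarray(y, float), obs.H, obs.Sigma_omega)
    w = np.linalg.eigvalsh(P_post)
    if w.min() < -1e-6 * max(1.0, w.max()):
        raise FloatingPointError("filter covariance lost positive semi-definiteness")
    return FilterState(x_hat=x_post, P=P_post, K=K)


def precompute_filter(
    dyn: LinearDynamics,
    obs: ObservationModel,
    steps: int,
    P0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Offline time-varying Kalman gains.

    The system is linear with known statistics, so the covariance recursion —
    and hence the gain sequence — does not depend on the data.  Returns
    ``(K, P)`` where ``K[t]`` is the gain applied to the innovation at step t
    (t = 1..steps; ``K[0]`` is zero since the initial state is known) and
    ``P[t]`` the posterior covariance at step t.
    """
    nz = dyn.state_dim
    P = np.zeros((steps + 1, nz, nz))
    K = np.zeros((steps + 1, nz, obs.obs_dim))
    P[0] = np.zeros((nz, nz)) if P0 is None else np.asarray(P0, dtype=float)
    for t in range(1, steps + 1):
        P_pred = dyn.A @ P[t - 1] @ dyn.A.T + dyn.Omega
        _, P[t], K[t] = _posterior_update(
            np.zeros(nz), P_pred, np.zeros(obs.obs_dim), obs.H, obs.Sigma_omega
        )
    return K, P


def risk_sensitive_estimate(
    fs: FilterState, law: ControlLaw, t: int
) -> np.ndarray:
    """Control from the risk-adjusted state estimate.

    u_t = -L_t (I - 2 theta P_t S_t)^-1 x_hat_t.  For theta = 0 this is exactly
    certainty-equivalent LQG.  Raises :class:`RiccatiBreakdownError` if the
    coupling matrix is (numerically) singular — the estimation-side analogue
    of neurotic breakdown.
    """
    if not law.feasible:
        raise RiccatiBreakdownError("control law is infeasible")
    theta = law.theta
    if theta == 0.0:
        x_check = fs.x_hat
    else:
        M = np.eye(fs.P.shape[0]) - 2.0 * theta * fs.P @ law.cost_to_go[t]
        if abs(np.linalg.det(M)) < 1e-300 or np.linalg.cond(M) > 1e12:
            raise RiccatiBreakdownError(
                "risk-sensitive estimate coupling matrix is singular"
            )
        x_check = np.linalg.solve(M, fs.x_hat)
    return -law.gains[t] @ x_check
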