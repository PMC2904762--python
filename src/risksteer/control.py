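"""Finite-horizon optimal feedback laws: risk-neutral LQR and risk-sensitive LEQG.

The risk-sensitive controller minimises the exponential-of-quadratic criterion

    gamma_theta = (1/theta) * log E[exp(theta * C)],

where ``C`` is the quadratic trial cost and ``theta`` the risk parameter.
For small ``theta`` this is approximately ``E[C] + (theta/2) Var[C]``: a
mean-variance decision maker.  The convention used throughout this package is
``theta > 0`` risk-averse (cost variance is penalised), ``theta < 0``
risk-seeking, ``theta = 0`` risk-neutral.  In Whittle's textbook convention
the criterion is ``-(2/theta_W) log E[exp(-(theta_W/2) C)]`` (risk-averse for
``theta_W < 0``); the two agree under ``theta = -theta_W/2``, which is why the
Riccati inflation below carries ``2*theta`` where Whittle's carries
``-theta_W``.

Both controllers are computed by a backward Riccati recursion.  The
risk-sensitive recursion differs only in that the cost-to-go is inflated
(risk-averse) or deflated (risk-seeking) through the process-noise covariance
before each backward step.  For risk-averse ``theta`` this inflation diverges
at a finite ``theta`` ("neurotic breakdown"): beyond it the criterion is
infinite and no finite optimal law exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .task import CostSpec, LinearDynamics

__all__ = [
    "ControlLaw",
    "RiccatiBreakdownError",
    "riccati_neutral",
    "riccati_risk_sensitive",
    "risk_criterion",
    "breakdown_theta",
]

#: Smallest admissible eigenvalue of (I - theta * Omega * S) before the
#: recursion is declared infeasible.
_BREAKDOWN_EIG_TOL = 1e-10


class RiccatiBreakdownError(RuntimeError):
    """Risk parameter beyond the neurotic-breakdown boundary."""


@dataclass(frozen=True)
class ControlLaw:
    """Time-indexed feedback law u_t = -L_t x_t with its cost-to-go matrices.

    Attributes
    ----------
    gains : ndarray, shape (steps, m, n)
        Feedback gain L_t for t = 0..steps-1.
    cost_to_go : ndarray, shape (steps + 1, n, n)
        Symmetric matrices S_t, with S_T = Q_final.
    theta : float
        Risk parameter that produced the law (0 = risk-neutral).
    feasible : bool
        False if the recursion broke down before reaching t = 0.
    """

    gains: np.ndarray
    cost_to_go: np.ndarray
    theta: float
    feasible: bool = True

    @property
    def n_steps(self) -> int:
        return self.gains.shape[0]

    def control(self, t: int, x: np.ndarray) -> np.ndarray:
        """u_t = -L_t x for a single state or a batch (..., n) of states."""
        return -np.asarray(x) @ self.gains[t].T


def _symmetrize(M: np.ndarray) -> np.ndarray:
    return (M + M.T) / 2.0


def _riccati(dyn: LinearDynamics, cost: CostSpec, steps: int, theta: float) -> ControlLaw:
    A, B, Omega = dyn.A, dyn.B, dyn.Omega
    n, m = dyn.state_dim, dyn.control_dim
    R, Qr, Qf = cost.R, cost.Q_running, cost.Q_final

    S = np.empty((steps + 1, n, n))
    L = np.zeros((steps, m, n))
    S[steps] = _symmetrize(Qf)
    eye = np.eye(n)

    for t in range(steps - 1, -1, -1):
        S_next = S[t + 1]
        if theta != 0.0:
            # LEQG inflation for gamma = (1/theta) log E[exp(theta*C)]:
            # S~ = (S^-1 - 2*theta*Omega)^-1 = (I - 2*theta*S*Omega)^-1 S
            # (the factor 2 comes from the Gaussian integral of exp(theta x'Sx);
            # conventions that put theta/2 in the exponent drop it).  The
            # factored form is valid for singular S; mind the S*Omega order.
            # Eigenvalues of S@Omega are real >= 0 (product of PSD matrices);
            # breakdown when 1 - 2*theta*max_eig <= 0.
            M = eye - 2.0 * theta * S_next @ Omega
            eigs = np.linalg.eigvals(M)
            if np.min(eigs.real) < _BREAKDOWN_EIG_TOL:
                return ControlLaw(
                    gains=L, cost_to_go=S, theta=theta, feasible=False
                )
            S_eff = _symmetrize(np.linalg.solve(M, S_next))
            if not np.all(np.isfinite(S_eff)):
                return ControlLaw(gains=L, cost_to_go=S, theta=theta, feasible=False)
        else:
            S_eff = S_next
        BtS = B.T @ S_eff
        G = R + BtS @ B
        L[t] = np.linalg.solve(_symmetrize(G), BtS @ A)
        S[t] = _symmetrize(Qr + A.T @ S_eff @ (A - B @ L[t]))
    return ControlLaw(gains=L, cost_to_go=S, theta=theta, feasible=True)


def riccati_neutral(dyn: LinearDynamics, cost: CostSpec, steps: int) -> ControlLaw:
    """Risk-neutral finite-horizon LQR law.

    Backward recursion from S_T = Q_final:
    L_t = (R + B'S_{t+1}B)^-1 B'S_{t+1}A and
    S_t = Q_t + A'S_{t+1}(A - B L_t).  The result does not depend on the
    process-noise covariance: additive noise only adds a state-independent
    constant to the expected cost-to-go.
    """
    return _riccati(dyn, cost, steps, theta=0.0)


def riccati_risk_sensitive(
    dyn: LinearDynamics, cost: CostSpec, steps: int, theta: float
) -> ControlLaw:
    """Risk-sensitive (LEQG) finite-horizon law.

    At each backward step the cost-to-go is passed through the process noise,
    S~_{t+1} = (S_{t+1}^-1 - 2*theta*Omega)^-1, before the standard Riccati
    step.  Risk-averse ``theta > 0`` inflates the cost-to-go — the controller
    acts as if the noise conspired against it and applies larger gains the
    larger Omega is; risk-seeking ``theta < 0`` deflates it.  If
    (I - 2*theta*Omega*S_{t+1}) loses positive definiteness the criterion is
    infinite ("neurotic breakdown") and the returned law has
    ``feasible=False`` (gains are left zero from the breakdown step on; do
    not use them).
    """
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    return _riccati(dyn, cost, steps, theta=float(theta))


def rollout_costs(
    gains: np.ndarray,
    dyn: LinearDynamics,
    cost: CostSpec,
    n_mc: int,
    rng: np.random.Generator,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Total quadratic cost of ``n_mc`` Monte-Carlo rollouts of u = -L_t x.

    Full state observation; the process noise is sampled from N(0, Omega).
    """
    gains = np.asarray(gains, dtype=float)
    steps = gains.shape[0]
    n = dyn.state_dim
    x = np.zeros((n_mc, n)) if x0 is None else np.broadcast_to(
        np.asarray(x0, dtype=float), (n_mc, n)
    ).copy()
    # Noise enters through a (possibly singular) covariance: use its Cholesky
    # factor of the nonzero block via eigendecomposition.
    w, V = np.linalg.eigh(_symmetrize(dyn.Omega))
    w = np.clip(w, 0.0, None)
    noise_map = V * np.sqrt(w)  # z ~ N(0,I) -> noise_map @ z ~ N(0, Omega)
    total = np.zeros(n_mc)
    for t in range(steps):
        u = -x @ gains[t].T
        total += np.einsum("ti,ij,tj->t", u, cost.R, u)
        total += np.einsum("ti,ij,tj->t", x, cost.Q_running, x)
        xi = rng.standard_normal((n_mc, n)) @ noise_map.T
        x = x @ dyn.A.T + u @ dyn.B.T + xi
    total += np.einsum("ti,ij,tj->t", x, cost.Q_final, x)
    return total


def risk_criterion(
    gains: np.ndarray | ControlLaw,
    dyn: LinearDynamics,
    cost: CostSpec,
    theta: float,
    n_mc: int = 10_000,
    seed: int | np.random.Generator = 0,
    x0: np.ndarray | None = None,
) -> float:
    """Monte-Carlo estimate of gamma_theta = (1/theta) log E[exp(theta C)].

    Works for any linear feedback law (a ``ControlLaw`` or a raw gain array),
    serving as the optimality oracle for the Riccati recursions.  Implemented
    with log-sum-exp so large theta*C does not overflow; an infinite estimate
    is returned as ``inf`` (evidence of breakdown).  At ``theta = 0`` this is
    the sample mean of the cost.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    if isinstance(gains, ControlLaw):
        gains = gains.gains
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    costs = rollout_costs(gains, dyn, cost, n_mc, rng, x0=x0)
    if theta == 0.0:
        return float(np.mean(costs))
    return float((logsumexp(theta * costs) - np.log(n_mc)) / theta)


def breakdown_theta(
    dyn: LinearDynamics,
    cost: CostSpec,
    steps: int,
    upper: float = 1e6,
    tol: float = 1e-6,
) -> float:
    """Largest feasible risk-averse theta, located by bisection.

    Returns the supremum of the theta > 0 for which the LEQG recursion
    completes; the risk-seeking branch (theta < 0) never breaks down.
    """
    lo, hi = 0.0, upper
    if riccati_risk_sensitive(dyn, cost, steps, hi).feasible:
        return hi
    while hi - lo > tol * max(1.0, lo):
        mid = 0.5 * (lo + hi)
        if riccati_risk_sensitive(dyn, cost, steps, mid).feasible:
            lo = mid
        else:
            hi = mid
    return lo
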