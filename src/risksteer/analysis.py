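"""Behavioral analysis: gain regression, F-tests, theta inference, cost accounting.

The central estimator mirrors how the behavioral data are analysed: a
multiple linear regression of the control emitted late in the trial
(t = 0.9 s by default) on the ball's position and velocity 150 ms earlier
(t = 0.75 s), one observation per trial, with no intercept.  The fitted plane
in state-control space is the subject's policy; its slopes are the position
and velocity control gains.

The risk parameter theta is inferred by matching the *change* in regressed
gains between the low- and high-noise conditions against the changes a
risk-sensitive optimal controller predicts — computed by applying the exact
same estimator to closed-loop simulations over a grid of theta values.  A
risk-neutral controller predicts zero change; risk-averse controllers predict
gains that grow with the noise level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .estimation import ObservationModel, default_observation_model
from .simulate import (
    LQGPolicy,
    TrialSet,
    counterfactual_no_control,
    lqg_breakdown_theta,
    simulate_batch,
)
from .task import TaskConfig

__all__ = [
    "GainEstimate",
    "PolicyPlane",
    "fit_policy_plane",
    "FTestResult",
    "compare_policies_ftest",
    "RiskSensitiveModel",
    "RiskFitResults",
    "infer_theta",
    "CostFraction",
    "cost_fraction",
    "extra_cost_of_risk",
    "ImpactAngleCounts",
    "impact_angle_analysis",
    "DelaySweepResult",
    "delay_sweep",
]


# ---------------------------------------------------------------------------
# Policy-plane regression
# ---------------------------------------------------------------------------


def _design_arrays(
    ts: TrialSet, probe_time_s: float, lag_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """(X, y): state at the probe time, control ``lag_s`` later, per trial."""
    cfg = ts.config
    i_state = round(probe_time_s / cfg.dt_s)
    i_ctrl = round((probe_time_s + lag_s) / cfg.dt_s)
    if not (0 <= i_state <= cfg.n_steps) or not (0 <= i_ctrl < cfg.n_steps):
        raise ValueError(
            f"probe_time_s={probe_time_s} with lag_s={lag_s} falls outside the "
            f"{cfg.horizon_s} s horizon"
        )
    X = np.array([[tr.x_cm[i_state], tr.v_cm_s[i_state]] for tr in ts.trials])
    y = np.array([tr.u_N[i_ctrl] for tr in ts.trials])
    return X, y


@dataclass
class GainEstimate:
    """Regressed policy-plane gains for one subject x condition.

    ``position_gain`` and ``velocity_gain`` are the slopes of u(t+lag) on
    x(t) and v(t); for an optimal controller they estimate the negated
    feedback gains -L at the probed step.  ``r_squared`` is computed against
    the zero model (no intercept was fit).
    """

    position_gain: float
    velocity_gain: float
    se_position: float
    se_velocity: float
    cov: np.ndarray
    r_squared: float
    probe_time_s: float
    lag_s: float
    n_trials: int

    @property
    def params(self) -> np.ndarray:
        return np.array([self.position_gain, self.velocity_gain])

    def summary(self) -> str:
        lines = [
            "Policy-plane regression (no intercept)",
            f"  state probed at t = {self.probe_time_s:.2f} s, "
            f"control at t = {self.probe_time_s + self.lag_s:.2f} s, "
            f"n = {self.n_trials} trials",
            f"  position gain: {self.position_gain:+.4f} (se {self.se_position:.4f}) N/cm",
            f"  velocity gain: {self.velocity_gain:+.4f} (se {self.se_velocity:.4f}) N/(cm/s)",
            f"  R^2 (vs zero model): {self.r_squared:.4f}",
        ]
        return "\n".join(lines)


class PolicyPlane:
    """Model object for the no-intercept state-to-control regression."""

    def __init__(self, trialset: TrialSet, probe_time_s: float = 0.75, lag_s: float = 0.15):
        self.trialset = trialset
        self.probe_time_s = probe_time_s
        self.lag_s = lag_s
        self.exog, self.endog = _design_arrays(trialset, probe_time_s, lag_s)
        if len(self.endog) <= 2:
            raise ValueError("need more than 2 trials for the 2-predictor fit")
        if np.linalg.matrix_rank(self.exog) < 2:
            raise ValueError("degenerate predictors: position and velocity are collinear")

    def fit(self) -> GainEstimate:
        res = sm.OLS(self.endog, self.exog).fit()
        bse = res.bse
        r2 = float(res.rsquared)  # uncentered: no constant in the model
        if not np.isfinite(r2):  # all-zero response (e.g. final step, L = 0)
            r2 = 0.0
        return GainEstimate(
            position_gain=float(res.params[0]),
            velocity_gain=float(res.params[1]),
            se_position=float(bse[0]),
            se_velocity=float(bse[1]),
            cov=np.asarray(res.cov_params()),
            r_squared=r2,
            probe_time_s=self.probe_time_s,
            lag_s=self.lag_s,
            n_trials=len(self.endog),
        )


def fit_policy_plane(
    ts: TrialSet, probe_time_s: float = 0.75, lag_s: float = 0.15
) -> GainEstimate:
    """Least-squares fit of u(t + lag) on [x(t), v(t)], no intercept."""
    return PolicyPlane(ts, probe_time_s, lag_s).fit()


@dataclass
class FTestResult:
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    shared: str


def compare_policies_ftest(
    ts_a: TrialSet,
    ts_b: TrialSet,
    shared: str = "position",
    probe_time_s: float = 0.75,
    lag_s: float = 0.15,
) -> FTestResult:
    """Nested-model F-test for a gain difference between two conditions.

    Full model: both conditions fitted jointly with separate position and
    velocity slopes (4 predictors).  Reduced model: the ``shared`` slope
    (position or velocity) is common to both conditions (3 predictors).  The
    test compares residual sums of squares.

    Because control magnitudes scale with the condition's noise level, the
    two conditions' residual variances can differ ~25-fold, which would leave
    a raw pooled F-test badly mis-calibrated (the large-variance block swamps
    both numerator and denominator).  Each condition's rows are therefore
    weighted by the reciprocal residual standard deviation of its own
    separate fit before pooling — a feasible-GLS version of the nested-model
    comparison.  Slopes stay in force units, so the shared-slope null is the
    risk-neutral prediction.
    """
    if shared not in ("position", "velocity"):
        raise ValueError("shared must be 'position' or 'velocity'")
    Xa, ya = _design_arrays(ts_a, probe_time_s, lag_s)
    Xb, yb = _design_arrays(ts_b, probe_time_s, lag_s)
    for X, y in ((Xa, ya), (Xb, yb)):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s = np.sqrt(np.sum(resid**2) / max(len(y) - X.shape[1], 1))
        if s <= 0:
            raise ValueError("degenerate (noise-free) condition in F-test")
        X /= s
        y /= s
    na, nb = len(ya), len(yb)
    y = np.concatenate([ya, yb])
    za, zb = np.zeros(na), np.zeros(nb)
    xa, va = Xa[:, 0], Xa[:, 1]
    xb, vb = Xb[:, 0], Xb[:, 1]
    X_full = np.column_stack(
        [
            np.concatenate([xa, zb]),
            np.concatenate([va, zb]),
            np.concatenate([za, xb]),
            np.concatenate([za, vb]),
        ]
    )
    if shared == "position":
        X_red = np.column_stack(
            [
                np.concatenate([xa, xb]),
                np.concatenate([va, zb]),
                np.concatenate([za, vb]),
            ]
        )
    else:
        X_red = np.column_stack(
            [
                np.concatenate([va, vb]),
                np.concatenate([xa, zb]),
                np.concatenate([za, xb]),
            ]
        )
    full = sm.OLS(y, X_full).fit()
    red = sm.OLS(y, X_red).fit()
    f_stat, p_value, df_num = full.compare_f_test(red)
    return FTestResult(
        f_stat=float(f_stat),
        df_num=int(df_num),
        df_den=int(full.df_resid),
        p_value=float(p_value),
        shared=shared,
    )


# ---------------------------------------------------------------------------
# Risk-parameter inference
# ---------------------------------------------------------------------------


@dataclass
class RiskFitResults:
    """Inferred risk parameter for one subject at one cost level.

    ``theta_hat`` minimises the Mahalanobis distance between the observed
    (low -> high noise) gain differences and the differences predicted by the
    risk-sensitive controller over the theta grid; ``theta_sd`` comes from a
    trial bootstrap.  ``extrapolated`` flags an observed difference landing at
    the edge of the predicted manifold.
    """

    theta_hat: float
    theta_sd: float
    gain_diff_position: float
    gain_diff_velocity: float
    condition_pair: tuple[str, str]
    extrapolated: bool
    bootstrap_thetas: np.ndarray
    theta_grid: np.ndarray
    predicted_diffs: np.ndarray
    observed_gains: tuple[GainEstimate, GainEstimate]

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        lo, hi = np.quantile(self.bootstrap_thetas, [alpha / 2, 1 - alpha / 2])
        return float(lo), float(hi)

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            "Risk-parameter inference from noise-driven gain changes",
            f"  conditions: {self.condition_pair[0]}  vs  {self.condition_pair[1]}",
            f"  observed gain change (high - low noise): "
            f"position {self.gain_diff_position:+.4f}, velocity {self.gain_diff_velocity:+.4f}",
            f"  theta_hat = {self.theta_hat:+.4g}  (bootstrap sd {self.theta_sd:.3g}, "
            f"95% CI [{lo:+.4g}, {hi:+.4g}])",
            f"  attitude: {'risk-averse' if self.theta_hat > 0 else 'risk-seeking' if self.theta_hat < 0 else 'risk-neutral'}",
        ]
        if self.extrapolated:
            lines.append("  WARNING: observed difference at the edge of the predicted manifold")
        return "\n".join(lines)

    def plot_manifold(self, ax=None):
        """Predicted gain-difference manifold coloured by theta, with the
        observed difference overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sc = ax.scatter(
            self.predicted_diffs[:, 0],
            self.predicted_diffs[:, 1],
            c=self.theta_grid,
            cmap="coolwarm",
            s=14,
        )
        ax.plot(self.gain_diff_position, self.gain_diff_velocity, "k*", ms=12)
        ax.set_xlabel("Δ position gain (high − low noise)")
        ax.set_ylabel("Δ velocity gain (high − low noise)")
        plt.colorbar(sc, ax=ax, label="theta")
        return ax


class RiskSensitiveModel:
    """Forward model of noise-driven gain changes, fit by grid search.

    Built once per condition pair (low-noise vs high-noise at a fixed control
    cost): for each theta on a log-spaced grid (both branches, capped at
    ``cap_fraction`` of the per-condition breakdown theta) the partially
    observed risk-sensitive controller is simulated closed-loop in both
    conditions and the policy-plane estimator is applied exactly as it is to
    data.  The resulting predicted (Δ position gain, Δ velocity gain) manifold
    is then matched to each subject's observed differences by minimum
    Mahalanobis distance, with a trial bootstrap for uncertainty.  Building
    the manifold is the expensive step; one model can fit many subjects.
    """

    def __init__(
        self,
        cfg_low: TaskConfig,
        cfg_high: TaskConfig,
        obs: ObservationModel | None = None,
        n_grid_per_branch: int = 50,
        cap_fraction: float = 0.9,
        grid_decades: float = 3.0,
        n_sim: int = 2000,
        probe_time_s: float = 0.75,
        lag_s: float = 0.15,
        seed: int = 0,
    ):
        self.cfg_low, self.cfg_high = cfg_low, cfg_high
        self.obs = obs if obs is not None else default_observation_model()
        self.probe_time_s, self.lag_s = probe_time_s, lag_s
        self.n_sim = n_sim
        self.seed = seed

        # Cap at the tighter of the Riccati and estimation-side breakdowns of
        # the partially observed controller, per condition.
        caps = [lqg_breakdown_theta(cfg, self.obs) for cfg in (cfg_low, cfg_high)]
        theta_max = cap_fraction * min(caps)
        pos = np.logspace(
            np.log10(theta_max) - grid_decades, np.log10(theta_max), n_grid_per_branch
        )
        self.theta_grid = np.concatenate([-pos[::-1], [0.0], pos])
        self.breakdown_thetas = tuple(caps)
        self.predicted_diffs = self._build_manifold()

    def _simulated_gains(self, cfg: TaskConfig, theta: float, condition: int) -> GainEstimate:
        policy = LQGPolicy(cfg, self.obs, theta=theta)
        trials = simulate_batch(
            cfg, policy, self.n_sim, master_seed=self.seed, subject=0, condition=condition
        )
        ts = TrialSet(
            condition_label=cfg.condition_label,
            subject_id="model",
            theta_true=theta,
            trials=trials,
            rng_seed=self.seed,
            config=cfg,
        )
        return fit_policy_plane(ts, self.probe_time_s, self.lag_s)

    def _build_manifold(self) -> np.ndarray:
        # Common random numbers across theta (same per-trial streams) keep the
        # manifold smooth in theta.  The manifold's own Monte-Carlo coefficient
        # covariance is retained: it acts as a shared offset on every
        # predicted difference, so the matching metric must include it.
        diffs = np.empty((len(self.theta_grid), 2))
        covs = np.empty((len(self.theta_grid), 2, 2))
        for i, th in enumerate(self.theta_grid):
            g_low = self._simulated_gains(self.cfg_low, th, condition=0)
            g_high = self._simulated_gains(self.cfg_high, th, condition=1)
            diffs[i] = g_high.params - g_low.params
            covs[i] = g_low.cov + g_high.cov
        self.predicted_cov = covs.mean(axis=0)
        return diffs

    @staticmethod
    def _nearest(
        diff: np.ndarray, manifold: np.ndarray, W: np.ndarray
    ) -> int:
        resid = manifold - diff[None, :]
        d2 = np.einsum("ki,ij,kj->k", resid, W, resid)
        return int(np.argmin(d2))

    def fit(
        self,
        ts_low: TrialSet,
        ts_high: TrialSet,
        n_boot: int = 1000,
        boot_seed: int = 0,
    ) -> RiskFitResults:
        g_low = fit_policy_plane(ts_low, self.probe_time_s, self.lag_s)
        g_high = fit_policy_plane(ts_high, self.probe_time_s, self.lag_s)
        diff = g_high.params - g_low.params
        cov = g_low.cov + g_high.cov + self.predicted_cov
        try:
            W = np.linalg.inv(cov)
        except np.linalg.LinAlgError:  # Euclidean fallback
            W = np.eye(2)
        k = self._nearest(diff, self.predicted_diffs, W)
        extrapolated = k in (0, len(self.theta_grid) - 1)

        Xl, yl = _design_arrays(ts_low, self.probe_time_s, self.lag_s)
        Xh, yh = _design_arrays(ts_high, self.probe_time_s, self.lag_s)
        rng = np.random.default_rng(boot_seed)
        boot = np.empty(n_boot)
        for b in range(n_boot):
            il = rng.integers(0, len(yl), len(yl))
            ih = rng.integers(0, len(yh), len(yh))
            bl, *_ = np.linalg.lstsq(Xl[il], yl[il], rcond=None)
            bh, *_ = np.linalg.lstsq(Xh[ih], yh[ih], rcond=None)
            boot[b] = self.theta_grid[self._nearest(bh - bl, self.predicted_diffs, W)]
        return RiskFitResults(
            theta_hat=float(self.theta_grid[k]),
            theta_sd=float(np.std(boot, ddof=1)),
            gain_diff_position=float(diff[0]),
            gain_diff_velocity=float(diff[1]),
            condition_pair=(ts_low.condition_label, ts_high.condition_label),
            extrapolated=extrapolated,
            bootstrap_thetas=boot,
            theta_grid=self.theta_grid,
            predicted_diffs=self.predicted_diffs,
            observed_gains=(g_low, g_high),
        )


def infer_theta(
    ts_low: TrialSet,
    ts_high: TrialSet,
    obs: ObservationModel | None = None,
    model: RiskSensitiveModel | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    **model_kwargs,
) -> RiskFitResults:
    """Infer a subject's risk parameter from a low/high-noise condition pair.

    Pass a prebuilt :class:`RiskSensitiveModel` to amortise the manifold
    simulation across subjects.
    """
    if model is None:
        model = RiskSensitiveModel(
            ts_low.config, ts_high.config, obs=obs, seed=seed, **model_kwargs
        )
    return model.fit(ts_low, ts_high, n_boot=n_boot, boot_seed=seed)


# ---------------------------------------------------------------------------
# Cost decomposition and counterfactual analyses
# ---------------------------------------------------------------------------


@dataclass
class CostFraction:
    fraction: float
    se: float
    n_trials: int


def cost_fraction(ts: TrialSet) -> CostFraction:
    """Mean control cost over mean total cost, with a delta-method s.e.

    Noise-invariant for a risk-neutral controller; increases with noise for a
    risk-averse one and decreases for a risk-seeking one.
    """
    if ts.n_trials == 0:
        raise ValueError("empty trial set")
    c = np.array([t.control_cost for t in ts.trials])
    tot = np.array([t.total_cost for t in ts.trials])
    mt = tot.mean()
    if mt == 0:
        raise ValueError("total cost is zero on all trials; fraction undefined")
    f = c.mean() / mt
    resid = c - f * tot
    se = float(np.sqrt(np.var(resid, ddof=1) / len(c)) / mt)
    return CostFraction(fraction=float(f), se=se, n_trials=len(c))


def extra_cost_of_risk(
    theta: float,
    cfg: TaskConfig,
    obs: ObservationModel | None = None,
    n_mc: int = 2000,
    seed: int = 0,
) -> float:
    """Percent extra expected cost of running the risk-sensitive controller.

    Simulates the risk-sensitive and the risk-neutral partially observed
    controllers under identical noise streams (paired comparison) and returns
    100 * (E[C_theta] - E[C_0]) / E[C_0].  Non-negative for any theta, and 0
    exactly at theta = 0: expected cost is what the risk-neutral law
    minimises, so hedging against cost variance is bought at a premium.
    """
    obs = obs if obs is not None else default_observation_model()
    mean_cost = {}
    for key, th in (("rs", float(theta)), ("rn", 0.0)):
        policy = LQGPolicy(cfg, obs, theta=th)
        trials = simulate_batch(cfg, policy, n_mc, master_seed=seed)
        mean_cost[key] = np.mean([t.total_cost for t in trials])
    return float(100.0 * (mean_cost["rs"] - mean_cost["rn"]) / mean_cost["rn"])


@dataclass
class ImpactAngleCounts:
    """Orthogonal-impact counts, actual vs no-control counterfactual.

    ``n_center_*`` restrict to trials ending within ``center_cm`` of the
    target centre.
    """

    n_trials: int
    n_orthogonal_actual: int
    n_orthogonal_counterfactual: int
    n_center_actual: int
    n_center_counterfactual: int
    tolerance_deg: float
    center_cm: float


def impact_angle_analysis(
    ts: TrialSet, tolerance_deg: float = 5.0, center_cm: float = 2.5
) -> ImpactAngleCounts:
    """Count trials hitting the target line orthogonally (90° ± tolerance),
    for the actual trajectories and for the counterfactual trajectories the
    logged noise alone would have produced."""
    lo, hi = 90.0 - tolerance_deg, 90.0 + tolerance_deg

    def _counts(records):
        ang = np.array([r.impact_angle_deg for r in records])
        fx = np.array([r.final_x_cm for r in records])
        ortho = (ang >= lo) & (ang <= hi)
        center = np.abs(fx) <= center_cm
        return int(ortho.sum()), int((ortho & center).sum())

    cf = [counterfactual_no_control(tr, ts.config) for tr in ts.trials]
    na, nca = _counts(ts.trials)
    nc, ncc = _counts(cf)
    return ImpactAngleCounts(
        n_trials=ts.n_trials,
        n_orthogonal_actual=na,
        n_orthogonal_counterfactual=nc,
        n_center_actual=nca,
        n_center_counterfactual=ncc,
        tolerance_deg=tolerance_deg,
        center_cm=center_cm,
    )


@dataclass
class DelaySweepResult:
    lags_s: np.ndarray
    r_squared: np.ndarray
    best_lag_s: float


def delay_sweep(
    ts: TrialSet, lags_s, probe_time_s: float = 0.75
) -> DelaySweepResult:
    """R^2 of the policy-plane fit as a function of the assumed visuomotor lag.

    The probed state time is held fixed and the control time is moved forward
    by each candidate lag.  Controls emitted less than the true delay after
    the probe cannot yet reflect the probed state (sharp R^2 drop), while
    controls emitted much later are dominated by newer observations (gradual
    drop); the profile therefore peaks at the generative delay.
    """
    lags = np.asarray(list(lags_s), dtype=float)
    if lags.size == 0:
        raise ValueError("lag list is empty")
    r2 = np.array(
        [fit_policy_plane(ts, probe_time_s=probe_time_s, lag_s=lag).r_squared for lag in lags]
    )
    return DelaySweepResult(lags_s=lags, r_squared=r2, best_lag_s=float(lags[np.argmax(r2)]))
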