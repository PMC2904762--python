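"""Synthetic subjects: risk-sensitive optimal controllers run through the task.

Each synthetic subject is a risk-sensitive LQG controller with its own risk
parameter theta, sensory noise, 150 ms sensorimotor delay and (optionally)
execution noise on the emitted control, pushed through the full 2x2 design
(two process-noise levels x two control-cost levels) with 250 analysed trials
per condition — the study design this package emulates.

The generated data carries its ground truth (theta, delay, noise) so that
parameter-recovery analyses can be closed-loop tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .control import RiccatiBreakdownError
from .estimation import ObservationModel
from .simulate import LQGPolicy, TrialSet, simulate_batch
from .task import TaskConfig, default_experiment

__all__ = [
    "SubjectSpec",
    "generate_subject",
    "generate_cohort",
    "default_cohort_specs",
    "CONDITION_ORDER",
    "DEFAULT_EXECUTION_CV",
]

#: Signal-dependent execution-noise level (sd as a fraction of the commanded
#: force) used for data-emulating cohorts: chosen so the policy-plane
#: regression R^2 lands near 0.8, the middle of the range human subjects show.
DEFAULT_EXECUTION_CV = 0.5

CONDITION_ORDER = (
    "low_noise/low_cost",
    "high_noise/low_cost",
    "low_noise/high_cost",
    "high_noise/high_cost",
)


@dataclass(frozen=True)
class SubjectSpec:
    """Ground-truth description of one synthetic subject.

    ``sensory_noise`` is (position sd cm, velocity sd cm/s).  Execution noise
    on the emitted control force has an additive term (``motor_noise_sd``, N)
    and a signal-dependent term (``motor_noise_cv``, sd as a fraction of the
    commanded force).  Both default to 0 — the ideal controller the model
    describes has no execution noise; :data:`DEFAULT_EXECUTION_CV` emulates
    human-like variability, scaling with command magnitude so the
    policy-plane R^2 is comparable across all four conditions.
    """

    subject_id: str
    theta: float = 0.0
    delay_steps: int = 15
    sensory_noise: tuple[float, float] = (0.5, 5.0)
    motor_noise_sd: float = 0.0
    motor_noise_cv: float = 0.0
    conditions: dict[str, TaskConfig] | None = None
    trials_per_condition: int = 250

    def __post_init__(self) -> None:
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        if self.delay_steps < 0:
            raise ValueError("delay_steps must be >= 0")

    def resolved_conditions(self) -> dict[str, TaskConfig]:
        conds = self.conditions if self.conditions is not None else default_experiment()
        missing = [c for c in CONDITION_ORDER if c not in conds]
        if missing:
            raise ValueError(f"conditions must cover the 2x2 design; missing {missing}")
        return conds

    def observation_model(self) -> ObservationModel:
        return ObservationModel(
            H=np.eye(2),
            Sigma_omega=np.diag([self.sensory_noise[0] ** 2, self.sensory_noise[1] ** 2]),
            delay_steps=self.delay_steps,
        )


def generate_subject(
    spec: SubjectSpec, seed: int, subject_index: int = 0, labels=None
) -> dict[str, TrialSet]:
    """Simulate one subject through all four conditions (or the ``labels`` subset).

    For each condition the risk-sensitive partially observed control problem
    is solved for the subject's theta and the closed loop is simulated for
    ``trials_per_condition`` trials.  Raises
    :class:`~risksteer.control.RiccatiBreakdownError` naming the condition if
    theta is beyond breakdown there (the high-noise conditions break first).
    """
    conds = spec.resolved_conditions()
    obs = spec.observation_model()
    out: dict[str, TrialSet] = {}
    for ci, label in enumerate(CONDITION_ORDER):
        if labels is not None and label not in labels:
            continue
        cfg = conds[label]
        try:
            policy = LQGPolicy(cfg, obs, theta=spec.theta)
        except RiccatiBreakdownError as e:
            raise RiccatiBreakdownError(
                f"subject {spec.subject_id!r}: theta={spec.theta} infeasible in "
                f"condition {label!r}"
            ) from e
        trials = simulate_batch(
            cfg,
            policy,
            spec.trials_per_condition,
            master_seed=seed,
            subject=subject_index,
            condition=ci,
            motor_noise_sd=spec.motor_noise_sd,
            motor_noise_cv=spec.motor_noise_cv,
        )
        out[label] = TrialSet(
            condition_label=label,
            subject_id=spec.subject_id,
            theta_true=spec.theta,
            trials=trials,
            rng_seed=seed,
            config=cfg,
        )
    return out


def default_cohort_specs(
    thetas=(-0.0008, 0.0, 0.0004, 0.0008, 0.0012, 0.0016),
    motor_noise_cv: float = DEFAULT_EXECUTION_CV,
    trials_per_condition: int = 250,
) -> list[SubjectSpec]:
    """An illustrative six-subject cohort spanning both risk attitudes.

    Theta values stay within the feasible (pre-breakdown) range of the most
    restrictive condition (high noise, high control cost) of the default
    design; most subjects are risk-averse, mirroring the attitude
    distribution typically observed.
    """
    return [
        SubjectSpec(
            subject_id=f"s{i + 1}",
            theta=th,
            motor_noise_cv=motor_noise_cv,
            trials_per_condition=trials_per_condition,
        )
        for i, th in enumerate(thetas)
    ]


def generate_cohort(
    specs: list[SubjectSpec], seed: int
) -> dict[str, dict[str, TrialSet]]:
    """Simulate a cohort; returns {subject_id: {condition: TrialSet}}.

    Subjects get disjoint RNG streams derived from ``seed`` and their index,
    so the cohort is reproducible and order-independent.
    """
    return {
        spec.subject_id: generate_subject(spec, seed=seed, subject_index=i)
        for i, spec in enumerate(specs)
    }
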