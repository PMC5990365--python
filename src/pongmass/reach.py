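"""Blind-reach prediction under a misestimated endpoint mass.

Reaches are planned as straight-line minimum-jerk movements.  The planner
computes inverse-dynamics torques on a robot model whose endpoint mass is
augmented by the mass modifier ``m_hat``; those torques are then replayed
open-loop (feedforward, no visual correction) on the *true* robot model.
The model mismatch turns into a trajectory error: a positive ``m_hat``
(perceived-heavier robot) produces overshoot (hypermetria), a negative one
undershoot (hypometria).

Positions here are in the body frame; the robot base offset from
:mod:`pongmass.geometry` maps them into linkage coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .geometry import body_to_robot, robot_to_body
from .linkage import (
    DEFAULT_LINKAGE,
    FiveBarLinkage,
    JointState,
    LinkageParameters,
    SAMPLE_RATE,
)
from .minjerk import minimum_jerk

__all__ = [
    "ReachSpec",
    "ReachOutcome",
    "augment_model",
    "predict_reach",
    "reach_battery",
    "DEFAULT_REACH_DURATION",
]

DEFAULT_REACH_DURATION = 0.6  # s


@dataclass(frozen=True)
class ReachSpec:
    """One point-to-point blind reach (body frame, metres)."""

    start: tuple[float, float]
    target: tuple[float, float]
    duration: float = DEFAULT_REACH_DURATION

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.distance <= 0:
            raise ValueError("start and target must differ")

    @property
    def distance(self) -> float:
        return float(np.hypot(
            self.target[0] - self.start[0], self.target[1] - self.start[1]
        ))

    @property
    def direction(self) -> np.ndarray:
        d = np.array(self.target) - np.array(self.start)
        return d / np.linalg.norm(d)


@dataclass
class ReachOutcome:
    """Endpoint and error decomposition of a simulated blind reach."""

    endpoint: np.ndarray        # body frame (m)
    extent_error: float         # signed, along start->target; + = overshoot
    lateral_error: float        # orthogonal component (m)
    extent_error_peak: float    # same measure at peak excursion along the axis
    trajectory: np.ndarray      # endpoint path, body frame (n, 2)
    t: np.ndarray


def augment_model(params: LinkageParameters, m_hat: float) -> LinkageParameters:
    """Robot model with the mass modifier added as an endpoint point mass.

    The endpoint is the only placement consistent with the effective-mass
    definition: a point mass ``m`` at the handle adds exactly ``m`` to the
    effective mass in every direction at every configuration.
    """
    new_mass = params.endpoint_mass + m_hat
    if new_mass <= 0:
        raise ValueError(
            f"m_hat={m_hat} makes the endpoint mass non-positive (nonphysical)"
        )
    return params.with_endpoint_mass(new_mass)


def predict_reach(
    params: LinkageParameters,
    m_hat: float,
    spec: ReachSpec,
    sample_rate: float = SAMPLE_RATE,
) -> ReachOutcome:
    """Simulate one blind reach under mass modifier ``m_hat``.

    Inverse dynamics are computed on the augmented model along the
    minimum-jerk plan; the torques are replayed on the unaugmented model and
    the outcome is read at the end of the planned duration (no stopping
    controller: the reach is open-loop by construction).
    """
    n = int(round(spec.duration * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    x_plan, xd_plan, xdd_plan = minimum_jerk(
        body_to_robot(np.array(spec.start)),
        body_to_robot(np.array(spec.target)),
        spec.duration, t,
    )

    planner = FiveBarLinkage(augment_model(params, m_hat))
    q, qdot, qddot = planner.joint_trajectory_from_endpoint(
        t, x_plan, xd_plan, xdd_plan
    )
    torques = planner.inverse_dynamics(t, q, qdot, qddot)

    executor = FiveBarLinkage(params)
    traj = executor.forward_simulate(
        torques, JointState(q=q[0], qdot=np.zeros(2))
    )
    path = robot_to_body(traj.x)
    endpoint = path[-1]

    d = np.asarray(spec.direction)
    rel_end = endpoint - np.array(spec.start)
    extent = float(rel_end @ d) - spec.distance
    lateral = float(rel_end @ np.array([-d[1], d[0]]))
    along = (path - np.array(spec.start)) @ d
    extent_peak = float(along.max()) - spec.distance
    return ReachOutcome(
        endpoint=endpoint, extent_error=extent, lateral_error=lateral,
        extent_error_peak=extent_peak, trajectory=path, t=t,
    )


def reach_battery(
    params: LinkageParameters,
    m_hat: float,
    specs: Sequence[ReachSpec],
) -> tuple[list[Optional[ReachOutcome]], dict]:
    """Predict every reach in a target set; failures are reported, the
    battery continues.  Returns per-target outcomes and a summary with the
    mean and SD of the extent errors."""
    outcomes: list[Optional[ReachOutcome]] = []
    errors: list[str] = []
    for spec in specs:
        try:
            outcomes.append(predict_reach(params, m_hat, spec))
        except Exception as err:  # noqa: BLE001 - battery must continue
            outcomes.append(None)
            errors.append(f"{spec}: {err}")
    extents = [o.extent_error for o in outcomes if o is not None]
    summary = {
        "mean_extent_error": float(np.mean(extents)) if extents else np.nan,
        "sd_extent_error": float(np.std(extents)) if extents else np.nan,
        "n_ok": len(extents),
        "n_failed": len(errors),
        "failures": errors,
    }
    return outcomes, summary
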