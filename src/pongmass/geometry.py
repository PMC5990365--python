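"""Study geometry: pong courts, reach targets and robot placement.

Everything is expressed in the *body frame*: ``x = 0`` is the body midline,
``+x`` rightward, ``+y`` away from the body.  The robot base centre sits at
:data:`ROBOT_BASE_OFFSET` in this frame; the linkage module works in robot
coordinates (base joints symmetric about its own origin), so body points are
translated by ``body_to_robot`` before any kinematic call.

Three experimental groups:

* ``FP``    — frontal pong, one court centred on the midline, hits away from
  the body, visuomotor delay 80 ms.
* ``LP_R``  — lateral pong in the right court, hits rightward, delay 120 ms.
* ``LP_L``  — lateral pong in the left court, hits leftward, delay 120 ms.

Each court is a 0.2 m square; the nominal contact point is the court centre,
0.1 m from the midline for the lateral courts.  Blind reaches go to three
targets 0.14 m from the start, separated by 45 degrees, fanned about the
frontal direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ROBOT_BASE_OFFSET",
    "COURT_SIDE_LENGTH",
    "COURT_NEAR_Y",
    "TAU_FRONTAL",
    "TAU_LATERAL",
    "REACH_DISTANCE",
    "CourtGeometry",
    "court_for_group",
    "body_to_robot",
    "robot_to_body",
    "GROUPS",
]

#: Robot base centre in the body frame (m); calibrated jointly with the
#: linkage inertia scale against the 1.5 / 1.0 kg effective-mass targets.
ROBOT_BASE_OFFSET = np.array([0.06031945325106982, 0.03351402618919742])

COURT_SIDE_LENGTH = 0.2   # m, square courts
COURT_NEAR_Y = 0.30       # m, frontal distance from the body to the near edge
TAU_FRONTAL = 0.080       # s, visuomotor delay in the frontal experiment
TAU_LATERAL = 0.120       # s, visuomotor delay in the lateral experiments
REACH_DISTANCE = 0.14     # m, start-to-target distance
TARGET_FAN_DEG = (45.0, 90.0, 135.0)  # target directions, CCW from +x

GROUPS = ("FP", "LP_R", "LP_L")


def body_to_robot(p: np.ndarray) -> np.ndarray:
    """Translate body-frame point(s) into robot (linkage) coordinates."""
    return np.asarray(p, dtype=float) - ROBOT_BASE_OFFSET


def robot_to_body(p: np.ndarray) -> np.ndarray:
    return np.asarray(p, dtype=float) + ROBOT_BASE_OFFSET


@dataclass(frozen=True)
class CourtGeometry:
    """One pong court with its hit axis and reach layout (body frame)."""

    group: str
    xmin: float
    xmax: float
    ymin: float
    ymax: float
    hit_axis: tuple[float, float]    # unit vector toward the distinguished wall
    paddle_theta: float              # paddle orientation, CCW from +x (rad)
    tau: float                       # visuomotor delay (s)
    reach_start: tuple[float, float]

    # ------------------------------------------------------------------
    @property
    def h(self) -> np.ndarray:
        """Unit vector along the hit axis (toward the far wall)."""
        return np.array(self.hit_axis, dtype=float)

    @property
    def tvec(self) -> np.ndarray:
        """Transverse unit vector (hit axis rotated +90 degrees)."""
        hx, hy = self.hit_axis
        return np.array([-hy, hx])

    @property
    def centre(self) -> np.ndarray:
        return np.array([(self.xmin + self.xmax) / 2.0,
                         (self.ymin + self.ymax) / 2.0])

    @property
    def contact_point(self) -> np.ndarray:
        """Nominal mean hit position: the court centre."""
        return self.centre

    def s_of(self, p: np.ndarray) -> float:
        """Coordinate along the hit axis (larger = closer to the far wall)."""
        return float(np.dot(np.asarray(p, dtype=float), self.h))

    def tr_of(self, p: np.ndarray) -> float:
        return float(np.dot(np.asarray(p, dtype=float), self.tvec))

    @property
    def s_near(self) -> float:
        corners = self._corner_s()
        return min(corners)

    @property
    def s_far(self) -> float:
        return max(self._corner_s())

    @property
    def tr_lo(self) -> float:
        return min(self._corner_tr())

    @property
    def tr_hi(self) -> float:
        return max(self._corner_tr())

    def _corners(self) -> np.ndarray:
        return np.array(
            [[self.xmin, self.ymin], [self.xmin, self.ymax],
             [self.xmax, self.ymin], [self.xmax, self.ymax]]
        )

    def _corner_s(self):
        return [float(c @ self.h) for c in self._corners()]

    def _corner_tr(self):
        return [float(c @ self.tvec) for c in self._corners()]

    def point(self, s: float, tr: float) -> np.ndarray:
        """Body-frame point from (hit-axis, transverse) coordinates."""
        return s * self.h + tr * self.tvec

    # ------------------------------------------------------------------
    def reach_targets(self) -> np.ndarray:
        """Three reach targets 0.14 m from the start, 45 degrees apart."""
        start = np.array(self.reach_start)
        angles = np.deg2rad(TARGET_FAN_DEG)
        return start + REACH_DISTANCE * np.stack(
            [np.cos(angles), np.sin(angles)], axis=-1
        )


_COURTS = {
    "FP": CourtGeometry(
        group="FP",
        xmin=-COURT_SIDE_LENGTH / 2, xmax=COURT_SIDE_LENGTH / 2,
        ymin=COURT_NEAR_Y, ymax=COURT_NEAR_Y + COURT_SIDE_LENGTH,
        hit_axis=(0.0, 1.0), paddle_theta=0.0, tau=TAU_FRONTAL,
        reach_start=(0.0, COURT_NEAR_Y + 0.02),
    ),
    "LP_R": CourtGeometry(
        group="LP_R",
        xmin=0.0, xmax=COURT_SIDE_LENGTH,
        ymin=COURT_NEAR_Y, ymax=COURT_NEAR_Y + COURT_SIDE_LENGTH,
        hit_axis=(1.0, 0.0), paddle_theta=np.pi / 2, tau=TAU_LATERAL,
        reach_start=(COURT_SIDE_LENGTH / 2, COURT_NEAR_Y + 0.02),
    ),
    "LP_L": CourtGeometry(
        group="LP_L",
        xmin=-COURT_SIDE_LENGTH, xmax=0.0,
        ymin=COURT_NEAR_Y, ymax=COURT_NEAR_Y + COURT_SIDE_LENGTH,
        hit_axis=(-1.0, 0.0), paddle_theta=np.pi / 2, tau=TAU_LATERAL,
        reach_start=(-COURT_SIDE_LENGTH / 2, COURT_NEAR_Y + 0.02),
    ),
}


def court_for_group(group: str) -> CourtGeometry:
    """Court geometry for group ``FP``, ``LP_R`` or ``LP_L``."""
    try:
        return _COURTS[group]
    except KeyError:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
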