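"""Minimum-jerk (quintic) point-to-point motion primitives.

The normalized position profile ``P(s) = 10 s^3 - 15 s^4 + 6 s^5`` minimizes
integrated squared jerk for a rest-to-rest move; velocity and acceleration
vanish at both boundaries and the peak speed is ``(15/8) D / T`` at mid-move.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["minimum_jerk", "MinJerkSegment", "PEAK_SPEED_FACTOR"]

#: Peak speed of a rest-to-rest minimum-jerk move of unit distance/duration.
PEAK_SPEED_FACTOR = 15.0 / 8.0


def _profiles(s: np.ndarray):
    pos = 10 * s**3 - 15 * s**4 + 6 * s**5
    vel = 30 * s**2 - 60 * s**3 + 30 * s**4
    acc = 60 * s - 180 * s**2 + 120 * s**3
    return pos, vel, acc


def minimum_jerk(start, target, duration: float, t):
    """Position, velocity and acceleration of a minimum-jerk reach at ``t``.

    Straight-line path from ``start`` to ``target`` with the quintic time
    profile.  ``t`` may be scalar or array, and is clipped to ``[0, T]`` in
    the sense that queries outside the move hold the boundary states.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    start = np.asarray(start, dtype=float)
    target = np.asarray(target, dtype=float)
    t = np.asarray(t, dtype=float)
    s = np.clip(t / duration, 0.0, 1.0)
    pos_p, vel_p, acc_p = _profiles(s)
    disp = target - start
    pos = start + pos_p[..., None] * disp
    vel = (vel_p[..., None] / duration) * disp
    acc = (acc_p[..., None] / duration**2) * disp
    return pos, vel, acc


@dataclass(frozen=True)
class MinJerkSegment:
    """A straight-line quintic move from ``p0`` to ``p1`` starting at ``t0``."""

    t0: float
    duration: float
    p0: tuple[float, float]
    p1: tuple[float, float]

    @property
    def t1(self) -> float:
        return self.t0 + self.duration

    def state(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Position and velocity at absolute time ``t`` (clamped to the move)."""
        pos, vel, _ = minimum_jerk(self.p0, self.p1, self.duration, t - self.t0)
        return pos, vel
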