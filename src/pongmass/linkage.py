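"""Planar five-bar-linkage kinematics and dynamics.

The manipulandum is a symmetric parallel linkage: two actuated base joints on
the x-axis drive two proximal links; two distal links close the loop at the
handle (endpoint).  The two actuated base angles ``q = (q1, q2)`` are the
generalized coordinates; the passive elbow joints are eliminated analytically
through the loop-closure constraint.

Conventions
-----------
* Base joints at ``(-d/2, 0)`` and ``(+d/2, 0)`` with ``d = base_separation``.
* ``+x`` rightward (lateral), ``+y`` away from the body (frontal); all angles
  measured counter-clockwise from ``+x``.
* Closure branch: elbow-out for both chains, endpoint above the elbow-elbow
  line.  ``inverse_kinematics`` never switches branch.

The central quantity for the perceptual model is the *effective endpoint
mass*: the projection of the generalized inertia matrix onto the
instantaneous direction of motion,

    m_r(q, theta) = u^T J^{-T} M(q) J^{-1} u,   u = (cos theta, sin theta),

i.e. the scalar point mass whose kinetic energy at the endpoint velocity
equals the kinetic energy of the whole linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline

__all__ = [
    "LinkageParameters",
    "JointState",
    "TorqueSeries",
    "JointTrajectory",
    "FiveBarLinkage",
    "ClosureError",
    "SingularityError",
    "WorkspaceError",
    "calibrate_linkage",
    "DEFAULT_LINKAGE",
]

SAMPLE_RATE = 200.0  # Hz, the recording rate used throughout


class ClosureError(ValueError):
    """Loop-closure equations have no real solution for the given input."""


class WorkspaceError(ClosureError):
    """Requested endpoint lies outside the reachable workspace."""


class SingularityError(ValueError):
    """Configuration is kinematically singular (ill-conditioned Jacobian)."""


@dataclass(frozen=True)
class LinkageParameters:
    """Geometric and inertial description of the five-bar manipulandum.

    Lengths in metres, masses in kilograms, inertias in kg m^2 about each
    link's centre of mass.  Link order: left proximal, right proximal, left
    distal, right distal.  ``link_com_offsets`` are measured along the link
    from its proximal joint.  ``endpoint_mass`` lumps handle and sensor.
    """

    base_separation: float
    proximal_lengths: tuple[float, float]
    distal_lengths: tuple[float, float]
    link_masses: tuple[float, float, float, float]
    link_com_offsets: tuple[float, float, float, float]
    link_inertias: tuple[float, float, float, float]
    endpoint_mass: float

    def __post_init__(self) -> None:
        lengths = (self.base_separation, *self.proximal_lengths, *self.distal_lengths)
        if any(v <= 0 for v in lengths):
            raise ValueError("all lengths must be strictly positive")
        if any(m <= 0 for m in self.link_masses) or self.endpoint_mass <= 0:
            raise ValueError("all masses must be strictly positive")
        if any(i <= 0 for i in self.link_inertias):
            raise ValueError("all link inertias must be strictly positive")
        link_lengths = (*self.proximal_lengths, *self.distal_lengths)
        for c, length in zip(self.link_com_offsets, link_lengths):
            if not 0.0 <= c <= length:
                raise ValueError("COM offsets must lie within the link length")

    def scaled_inertia(self, factor: float) -> "LinkageParameters":
        """Return a copy with all masses and inertias multiplied by ``factor``."""
        return replace(
            self,
            link_masses=tuple(m * factor for m in self.link_masses),
            link_inertias=tuple(i * factor for i in self.link_inertias),
            endpoint_mass=self.endpoint_mass * factor,
        )

    def with_endpoint_mass(self, mass: float) -> "LinkageParameters":
        return replace(self, endpoint_mass=mass)

    def to_dict(self) -> dict:
        return {
            "base_separation": self.base_separation,
            "proximal_lengths": list(self.proximal_lengths),
            "distal_lengths": list(self.distal_lengths),
            "link_masses": list(self.link_masses),
            "link_com_offsets": list(self.link_com_offsets),
            "link_inertias": list(self.link_inertias),
            "endpoint_mass": self.endpoint_mass,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinkageParameters":
        return cls(
            base_separation=float(d["base_separation"]),
            proximal_lengths=tuple(float(v) for v in d["proximal_lengths"]),
            distal_lengths=tuple(float(v) for v in d["distal_lengths"]),
            link_masses=tuple(float(v) for v in d["link_masses"]),
            link_com_offsets=tuple(float(v) for v in d["link_com_offsets"]),
            link_inertias=tuple(float(v) for v in d["link_inertias"]),
            endpoint_mass=float(d["endpoint_mass"]),
        )


@dataclass
class JointState:
    """Actuated joint angles (rad) and angular velocities (rad/s)."""

    q: np.ndarray
    qdot: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float).reshape(2)
        self.qdot = np.asarray(self.qdot, dtype=float).reshape(2)


@dataclass
class TorqueSeries:
    """Generalized joint forces sampled uniformly (default 200 Hz)."""

    t: np.ndarray
    u: np.ndarray  # shape (n, 2), N m

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if self.u.shape != (self.t.size, 2):
            raise ValueError("torque array must have shape (len(t), 2)")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("torques must be finite")


@dataclass
class JointTrajectory:
    """Joint-space trajectory with the matching endpoint path."""

    t: np.ndarray
    q: np.ndarray      # (n, 2)
    qdot: np.ndarray   # (n, 2)
    x: np.ndarray      # (n, 2) endpoint positions
    xdot: np.ndarray   # (n, 2) endpoint velocities


def _circle_intersection(p0, r0, p1, r1, sign):
    """Intersection of two circles, vectorized over leading axes.

    ``sign=+1`` picks the point to the left of the p0->p1 direction.
    Raises :class:`ClosureError` when the circles do not intersect.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    diff = p1 - p0
    d = np.hypot(diff[..., 0], diff[..., 1])
    if np.any(d < 1e-12):
        raise ClosureError("coincident circle centres in closure construction")
    a = (r0 * r0 - r1 * r1 + d * d) / (2.0 * d)
    h2 = r0 * r0 - a * a
    if np.any(h2 < -1e-12):
        raise ClosureError("closure circles do not intersect (unreachable)")
    h = np.sqrt(np.clip(h2, 0.0, None))
    u = diff / d[..., None]
    perp = np.stack([-u[..., 1], u[..., 0]], axis=-1)
    return p0 + a[..., None] * u + sign * h[..., None] * perp


class FiveBarLinkage:
    """Kinematics and Euler-Lagrange dynamics of the five-bar manipulandum."""

    #: condition-number threshold beyond which a configuration is singular
    COND_LIMIT = 1e8

    def __init__(self, params: LinkageParameters):
        self.params = params
        d = params.base_separation
        self.base_left = np.array([-d / 2.0, 0.0])
        self.base_right = np.array([d / 2.0, 0.0])

    # ------------------------------------------------------------------
    # kinematics
    # ------------------------------------------------------------------
    def elbows(self, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Positions of the two passive elbow joints for base angles ``q``."""
        q = np.asarray(q, dtype=float)
        l1, l2 = self.params.proximal_lengths
        a = self.base_left + l1 * np.stack(
            [np.cos(q[..., 0]), np.sin(q[..., 0])], axis=-1
        )
        b = self.base_right + l2 * np.stack(
            [np.cos(q[..., 1]), np.sin(q[..., 1])], axis=-1
        )
        return a, b

    def forward_kinematics(self, q: np.ndarray) -> np.ndarray:
        """Endpoint (handle) position for base angles ``q``.

        Vectorized over leading axes of ``q`` (shape ``(..., 2)``).
        """
        a, b = self.elbows(np.asarray(q, dtype=float))
        l3, l4 = self.params.distal_lengths
        return _circle_intersection(a, l3, b, l4, sign=+1.0)

    def inverse_kinematics(self, x: np.ndarray) -> np.ndarray:
        """Base angles whose forward kinematics reproduce endpoint ``x``.

        Uses the fixed elbow-out branch: left elbow left of the base->endpoint
        ray, right elbow right of it.  Vectorized over leading axes.
        """
        x = np.asarray(x, dtype=float)
        l1, l2 = self.params.proximal_lengths
        l3, l4 = self.params.distal_lengths
        rl = np.hypot(*(x - self.base_left).T) if x.ndim > 1 else np.hypot(
            *(x - self.base_left)
        )
        rr = np.hypot(*(x - self.base_right).T) if x.ndim > 1 else np.hypot(
            *(x - self.base_right)
        )
        if np.any(rl > l1 + l3) or np.any(rr > l2 + l4):
            raise WorkspaceError("endpoint beyond total arm length")
        if np.any(rl < abs(l1 - l3)) or np.any(rr < abs(l2 - l4)):
            raise WorkspaceError("endpoint inside the inner workspace boundary")
        try:
            a = _circle_intersection(self.base_left, l1, x, l3, sign=+1.0)
            b = _circle_intersection(self.base_right, l2, x, l4, sign=-1.0)
        except ClosureError as err:  # pragma: no cover - guarded above
            raise WorkspaceError(str(err)) from err
        q1 = np.arctan2(a[..., 1] - self.base_left[1], a[..., 0] - self.base_left[0])
        q2 = np.arctan2(b[..., 1] - self.base_right[1], b[..., 0] - self.base_right[0])
        return np.stack([q1, q2], axis=-1)

    def _closure_geometry(self, q: np.ndarray):
        """Endpoint, elbows and the closure matrix G used by the Jacobian."""
        q = np.asarray(q, dtype=float).reshape(2)
        a, b = self.elbows(q)
        p = self.forward_kinematics(q)
        g = np.stack([p - a, p - b])  # rows
        cond = np.linalg.cond(g)
        if not np.isfinite(cond) or cond > self.COND_LIMIT:
            raise SingularityError(
                f"closure singular at q={q}: cond(G)={cond:.3g}"
            )
        return p, a, b, g

    def jacobian(self, q: np.ndarray) -> np.ndarray:
        """2x2 map from joint velocities to endpoint velocity."""
        p, a, b, g = self._closure_geometry(np.asarray(q, dtype=float))
        l1, l2 = self.params.proximal_lengths
        q = np.asarray(q, dtype=float).reshape(2)
        a1 = l1 * np.array([-np.sin(q[0]), np.cos(q[0])])  # dA/dq1
        b2 = l2 * np.array([-np.sin(q[1]), np.cos(q[1])])  # dB/dq2
        rhs = np.array([[np.dot(p - a, a1), 0.0], [0.0, np.dot(p - b, b2)]])
        jac = np.linalg.solve(g, rhs)
        cond = np.linalg.cond(jac)
        if not np.isfinite(cond) or cond > self.COND_LIMIT:
            raise SingularityError(f"jacobian singular at q={q}: cond={cond:.3g}")
        return jac

    # ------------------------------------------------------------------
    # dynamics
    # ------------------------------------------------------------------
    def _body_jacobians(self, q: np.ndarray):
        """Per-body COM-velocity maps B_i (2x2) and angular-rate rows w_i.

        Every body velocity is linear in qdot; the maps are assembled from the
        closure constraint so the passive joints never appear explicitly.
        """
        q = np.asarray(q, dtype=float).reshape(2)
        prm = self.params
        l1, l2 = prm.proximal_lengths
        l3, l4 = prm.distal_lengths
        c1, c2, c3, c4 = prm.link_com_offsets

        p, a, b, g = self._closure_geometry(q)
        a1 = l1 * np.array([-np.sin(q[0]), np.cos(q[0])])
        b2 = l2 * np.array([-np.sin(q[1]), np.cos(q[1])])
        rhs = np.array([[np.dot(p - a, a1), 0.0], [0.0, np.dot(p - b, b2)]])
        jac = np.linalg.solve(g, rhs)

        ea = np.column_stack([a1, np.zeros(2)])  # dA/dq
        eb = np.column_stack([np.zeros(2), b2])  # dB/dq

        u3 = (p - a) / l3
        u4 = (p - b) / l4
        perp3 = np.array([-u3[1], u3[0]])
        perp4 = np.array([-u4[1], u4[0]])
        # passive-link angular rates: phi_dot = cross(u, pdot - elbow_dot)/l
        w3 = (perp3 @ (jac - ea)) / l3
        w4 = (perp4 @ (jac - eb)) / l4

        bodies = [
            # left proximal: COM rotates about the left base joint
            (prm.link_masses[0],
             np.column_stack([(c1 / l1) * a1, np.zeros(2)]),
             prm.link_inertias[0], np.array([1.0, 0.0])),
            # right proximal
            (prm.link_masses[1],
             np.column_stack([np.zeros(2), (c2 / l2) * b2]),
             prm.link_inertias[1], np.array([0.0, 1.0])),
            # left distal: COM = elbow + c3*u3
            (prm.link_masses[2], ea + c3 * np.outer(perp3, w3),
             prm.link_inertias[2], w3),
            # right distal
            (prm.link_masses[3], eb + c4 * np.outer(perp4, w4),
             prm.link_inertias[3], w4),
        ]
        return bodies, jac

    def inertia_matrix(self, q: np.ndarray) -> np.ndarray:
        """Generalized inertia M(q) in actuated-joint coordinates."""
        bodies, jac = self._body_jacobians(q)
        m = self.params.endpoint_mass * jac.T @ jac
        for mass, bmat, inertia, w in bodies:
            m = m + mass * bmat.T @ bmat + inertia * np.outer(w, w)
        return 0.5 * (m + m.T)

    def inertia_gradient(self, q: np.ndarray, step: float = 1e-6) -> np.ndarray:
        """dM/dq_k by central differences; shape (2, 2, 2), last axis = k."""
        q = np.asarray(q, dtype=float).reshape(2)
        grad = np.empty((2, 2, 2))
        for k in range(2):
            dq = np.zeros(2)
            dq[k] = step
            grad[:, :, k] = (
                self.inertia_matrix(q + dq) - self.inertia_matrix(q - dq)
            ) / (2.0 * step)
        return grad

    def coriolis_matrix(self, q: np.ndarray, qdot: np.ndarray) -> np.ndarray:
        """Centripetal/Coriolis matrix from Christoffel symbols of M(q).

        Built so that ``Mdot - 2C`` is skew-symmetric for the same numerical
        gradient of M, which keeps passive simulations energy-conserving.
        """
        qdot = np.asarray(qdot, dtype=float).reshape(2)
        dm = self.inertia_gradient(q)
        c = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                c[i, j] = 0.5 * sum(
                    (dm[i, j, k] + dm[i, k, j] - dm[j, k, i]) * qdot[k]
                    for k in range(2)
                )
        return c

    def kinetic_energy(self, state: JointState) -> float:
        m = self.inertia_matrix(state.q)
        return 0.5 * float(state.qdot @ m @ state.qdot)

    # ------------------------------------------------------------------
    # effective endpoint mass
    # ------------------------------------------------------------------
    def endpoint_inertia(self, q: np.ndarray) -> np.ndarray:
        """Endpoint-space inertia  Lambda = J^{-T} M J^{-1}  (2x2)."""
        m = self.inertia_matrix(q)
        jinv = np.linalg.inv(self.jacobian(q))
        lam = jinv.T @ m @ jinv
        return 0.5 * (lam + lam.T)

    def effective_mass(self, q: np.ndarray, theta_dir: float) -> float:
        """Scalar effective mass felt at the endpoint for motion at angle
        ``theta_dir`` (rad, CCW from +x).  Invariant under theta -> theta+pi."""
        u = np.array([np.cos(theta_dir), np.sin(theta_dir)])
        mr = float(u @ self.endpoint_inertia(q) @ u)
        if mr <= 0:
            raise SingularityError("non-positive effective mass (singular closure)")
        return mr

    def effective_mass_polar(
        self, q: np.ndarray, n_directions: int = 64
    ) -> tuple[np.ndarray, np.ndarray]:
        """Effective-mass profile on a uniform angular grid (for polar plots).

        Returns ``(angles, masses)`` with ``angles`` in [0, 2pi).
        """
        if n_directions < 4:
            raise ValueError("n_directions must be at least 4")
        lam = self.endpoint_inertia(q)
        angles = np.linspace(0.0, 2.0 * np.pi, n_directions, endpoint=False)
        units = np.stack([np.cos(angles), np.sin(angles)], axis=-1)
        masses = np.einsum("ni,ij,nj->n", units, lam, units)
        return angles, masses

    # ------------------------------------------------------------------
    # inverse / forward dynamics
    # ------------------------------------------------------------------
    def inverse_dynamics(
        self, t: np.ndarray, q: np.ndarray, qdot: np.ndarray, qddot: np.ndarray
    ) -> TorqueSeries:
        """Torques u = M(q) qddot + C(q, qdot) qdot along a joint trajectory.

        No gravity term: the workspace is horizontal.
        """
        t = np.asarray(t, dtype=float)
        q = np.asarray(q, dtype=float)
        u = np.empty_like(q)
        bad: list[int] = []
        for i in range(t.size):
            try:
                m = self.inertia_matrix(q[i])
                c = self.coriolis_matrix(q[i], qdot[i])
            except (SingularityError, ClosureError):
                bad.append(i)
                continue
            u[i] = m @ qddot[i] + c @ qdot[i]
        if bad:
            raise SingularityError(
                f"singular configurations along the path at samples {bad[:10]}"
                + ("..." if len(bad) > 10 else "")
            )
        return TorqueSeries(t=t, u=u)

    def joint_trajectory_from_endpoint(
        self, t: np.ndarray, x: np.ndarray, xdot: np.ndarray, xddot: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map an endpoint plan to joint space.

        qdot comes from J^{-1} xdot; qddot from J^{-1}(xddot - Jdot qdot) with
        Jdot assembled from finite differences of J over q.
        """
        q = self.inverse_kinematics(x)
        n = len(t)
        qdot = np.empty((n, 2))
        qddot = np.empty((n, 2))
        h = 1e-7
        for i in range(n):
            jac = self.jacobian(q[i])
            jinv = np.linalg.inv(jac)
            qdot[i] = jinv @ xdot[i]
            jdot = np.zeros((2, 2))
            for k in range(2):
                dq = np.zeros(2)
                dq[k] = h
                djk = (self.jacobian(q[i] + dq) - self.jacobian(q[i] - dq)) / (2 * h)
                jdot += djk * qdot[i][k]
            qddot[i] = jinv @ (xddot[i] - jdot @ qdot[i])
        return q, qdot, qddot

    def forward_simulate(
        self,
        torques: TorqueSeries,
        initial: JointState,
        rtol: float = 1e-8,
        atol: float = 1e-10,
    ) -> JointTrajectory:
        """Integrate  qddot = M^{-1} (u - C qdot)  over the torque horizon.

        Adaptive Runge-Kutta with dense output resampled at the torque series'
        own (200 Hz) time base.
        """
        t = torques.t
        if t.size >= 2:
            u_of_t = CubicSpline(t, torques.u, axis=0)
        else:
            u_of_t = lambda _t: torques.u[0]  # noqa: E731

        def rhs(ti, y):
            q, qd = y[:2], y[2:]
            m = self.inertia_matrix(q)
            c = self.coriolis_matrix(q, qd)
            qdd = np.linalg.solve(m, np.asarray(u_of_t(ti)) - c @ qd)
            return np.concatenate([qd, qdd])

        y0 = np.concatenate([initial.q, initial.qdot])
        sol = solve_ivp(
            rhs, (t[0], t[-1]), y0, method="RK45", rtol=rtol, atol=atol,
            dense_output=True,
        )
        if not sol.success:
            raise SingularityError(f"forward simulation failed: {sol.message}")
        y = sol.sol(t).T
        q, qd = y[:, :2], y[:, 2:]
        x = self.forward_kinematics(q)
        xdot = np.einsum(
            "nij,nj->ni", np.stack([self.jacobian(qi) for qi in q]), qd
        )
        return JointTrajectory(t=t, q=q, qdot=qd, x=x, xdot=xdot)


# ----------------------------------------------------------------------
# calibration of the default parameter set
# ----------------------------------------------------------------------
def calibrate_linkage(
    nominal: LinkageParameters,
    contact_points: Sequence[np.ndarray],
    hit_angles: Sequence[float],
    target_masses: Sequence[float],
    base_offset_guess: tuple[float, float] = (0.0, -0.15),
    bounds: tuple = ((0.2, -0.25, -0.45), (8.0, 0.25, 0.05)),
):
    """Fit an inertia scale and the robot-base placement to effective-mass targets.

    ``contact_points`` are given in the body frame (midline x = 0); the robot
    base centre sits at ``(bx, by)`` in that frame, so a body point ``p`` maps
    to ``p - (bx, by)`` in robot coordinates.  Bounded least squares over
    ``(scale, bx, by)`` matches ``effective_mass`` at each contact point/angle
    to the corresponding target.

    Returns ``(params, base_offset, residual)``.
    """
    from scipy.optimize import least_squares

    pts = [np.asarray(p, dtype=float) for p in contact_points]

    def residuals(x):
        scale, bx, by = x
        linkage = FiveBarLinkage(nominal.scaled_inertia(scale))
        out = []
        for p, ang, target in zip(pts, hit_angles, target_masses):
            try:
                q = linkage.inverse_kinematics(p - np.array([bx, by]))
                mr = linkage.effective_mass(q, ang)
            except (ClosureError, SingularityError):
                return [1e3] * len(pts)
            out.append(mr - target)
        return out

    fit = least_squares(residuals, [1.0, *base_offset_guess], bounds=bounds)
    scale, bx, by = fit.x
    return nominal.scaled_inertia(scale), np.array([bx, by]), fit.fun


#: Nominal (pre-calibration) hardware description: a desk-scale parallel
#: manipulandum.  The left chain carries most of the drive-train mass, which
#: makes the endpoint inertia laterally anisotropic across the workspace; the
#: true hardware values are unpublished, so this set is a documented stand-in.
NOMINAL_LINKAGE = LinkageParameters(
    base_separation=0.12,
    proximal_lengths=(0.30, 0.30),
    distal_lengths=(0.42, 0.42),
    link_masses=(4.0, 0.8, 1.2, 0.3),
    link_com_offsets=(0.12, 0.12, 0.19, 0.19),
    link_inertias=(0.0385, 0.0085, 0.0195, 0.0056),
    endpoint_mass=0.8,
)

#: Inertia scale produced by :func:`calibrate_linkage` against the two
#: lateral-court effective-mass targets (1.5 kg right, 1.0 kg left) with the
#: base placement stored in :mod:`pongmass.geometry`; residual < 2e-8 kg.
CALIBRATED_INERTIA_SCALE = 0.47132836137452505

#: Calibrated package default.
DEFAULT_LINKAGE = NOMINAL_LINKAGE.scaled_inertia(CALIBRATED_INERTIA_SCALE)
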