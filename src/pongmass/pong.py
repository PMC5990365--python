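"""Event-driven simulation of the delayed virtual pong game.

The game is played by a parametric artificial player holding the handle of
the five-bar manipulandum.  The ball lives in a square court; the player
strikes it toward the distinguished (far) wall with a paddle that on screen
is *delayed* by the visuomotor delay ``tau``: the visual paddle at time ``t``
is the hand at ``t - tau``, and the ball physics interact with the visual
paddle.  The proprioceptive paddle is the hand itself.

Collision law (paddle orientation ``theta``, restitution 0.7, coupling 0.42)::

    v_out = 0.7 * R(theta) @ v_in + 0.42 * v_paddle
    R(theta) = [[cos 2t, sin 2t], [sin 2t, -cos 2t]]

Ball speed decays linearly with time (sliding friction); bounces off the far
wall add a uniform +-0.13 m/s perturbation to the along-wall velocity
component; each hit triggers a 5 ms haptic pulse ``f = 0.05 * dv_ball``.

The player model is deliberately simple and fully exposed: it predicts the
ball's return to the court centre and executes a reciprocal minimum-jerk
out-and-back stroke timed so that contact occurs at a controlled offset
``delta`` from the instant at which visual and proprioceptive paddle speeds
cross (for a symmetric stroke under delay ``tau`` that crossing sits ``tau/2``
after the true peak).  ``delta < 0 / = 0 / > 0`` therefore produce hits in
the accelerating / crossing / decelerating phase of the stroke — the three
hit-timing categories that map onto negative / zero / positive mass
modifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import CourtGeometry, court_for_group, body_to_robot
from .linkage import DEFAULT_LINKAGE, FiveBarLinkage, SAMPLE_RATE
from .minjerk import MinJerkSegment

__all__ = [
    "PongConfig",
    "PlayerModel",
    "BallState",
    "HitEvent",
    "HapticPulse",
    "SessionLog",
    "collision_response",
    "apply_friction",
    "bounce_perturbation",
    "delayed_view",
    "haptic_impulse",
    "simulate_player_stroke",
    "run_pong_session",
]

RESTITUTION = 0.7
PADDLE_COUPLING = 0.42
BOUNCE_NOISE_HALFWIDTH = 0.13  # m/s
HAPTIC_MASS = 0.05             # kg
HAPTIC_DURATION = 0.005        # s


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------
@dataclass
class PongConfig:
    """Game constants; the printed values are the defaults.

    ``friction_decay``, ``ball_speed_init``, ``paddle_half_length`` and
    ``serve_pause`` are unprinted game constants chosen to give several hits
    per minute; they are recorded in every session header.
    """

    court_side: str = "LP_R"               # FP | LP_R | LP_L
    delay_tau: Optional[float] = None      # s; default from the court
    restitution: float = RESTITUTION
    paddle_coupling: float = PADDLE_COUPLING
    bounce_noise_halfwidth: float = BOUNCE_NOISE_HALFWIDTH
    friction_decay: float = 0.05           # m/s per second of flight
    haptic_mass: float = HAPTIC_MASS
    haptic_duration: float = HAPTIC_DURATION
    sample_rate: float = SAMPLE_RATE
    ball_speed_init: float = 0.4           # m/s serve speed
    paddle_half_length: float = 0.04       # m
    serve_pause: float = 0.3               # s between a miss and the re-serve
    hit_refractory: float = 0.30           # s; debounces paddle follow-through
    seed: int = 0

    def __post_init__(self) -> None:
        self.court: CourtGeometry = court_for_group(self.court_side)
        if self.delay_tau is None:
            self.delay_tau = self.court.tau
        if self.delay_tau < 0:
            raise ValueError("delay_tau must be non-negative")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.friction_decay < 0 or self.ball_speed_init <= 0:
            raise ValueError("invalid ball constants")

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "court"}
        return d


@dataclass
class PlayerModel:
    """Parametric artificial player.

    ``timing_offset`` (s) shifts the intended contact away from the
    visual/proprioceptive speed crossing; ``timing_jitter`` and
    ``amplitude_jitter`` are per-stroke Gaussian SDs.  ``adaptation_rate``
    linearly decays the effective offset per executed stroke (default off).
    """

    stroke_amplitude: float = 0.14    # m, out-stroke length
    stroke_duration: float = 0.45     # s, out-phase duration
    timing_offset: float = 0.0        # s, delta
    timing_jitter: float = 0.008      # s
    amplitude_jitter: float = 0.005   # m
    aim_jitter: float = 0.04          # m, SD of the contact point along the
                                      # hit axis ("on average" mid-court)
    direction_jitter: float = 0.12    # rad, SD of the stroke direction about
                                      # the hit axis
    adaptation_rate: float = 0.0      # per-stroke linear decay of delta

    def __post_init__(self) -> None:
        if self.stroke_duration <= 0:
            raise ValueError("stroke_duration must be positive")
        if abs(self.timing_offset) >= self.stroke_duration / 2:
            raise ValueError("|timing_offset| must be below stroke_duration/2")

    def effective_offset(self, n_strokes: int) -> float:
        decay = max(0.0, 1.0 - self.adaptation_rate * n_strokes)
        return self.timing_offset * decay

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class BallState:
    position: np.ndarray
    velocity: np.ndarray


@dataclass
class HitEvent:
    """One ball-paddle collision with both sensory channels at the hit."""

    t_hit: float
    hand_position: np.ndarray   # body frame, m
    q_hit: np.ndarray           # robot joint angles (filled in post-hoc)
    paddle_theta: float
    v_p: np.ndarray             # proprioceptive (true hand) velocity, m/s
    v_v: np.ndarray             # visual paddle velocity = hand at t_hit - tau
    delta_v_ball: np.ndarray    # ball velocity change, m/s


@dataclass(frozen=True)
class HapticPulse:
    force: np.ndarray      # N s-scale impulse amplitude, f = mb * dv
    duration: float        # s
    delay: float           # s; the pulse is time-shifted by tau when delayed


@dataclass
class SessionLog:
    """Complete synthetic pong record (in-memory form of the CSV+JSON log)."""

    header: dict
    trajectory: pd.DataFrame
    hits: list[HitEvent]
    per_minute_hits: list[int]
    misses: int

    @property
    def hit_table(self) -> pd.DataFrame:
        rows = [
            {
                "t_hit": h.t_hit,
                "q1": h.q_hit[0], "q2": h.q_hit[1],
                "theta": h.paddle_theta,
                "x": h.hand_position[0], "y": h.hand_position[1],
                "vpx": h.v_p[0], "vpy": h.v_p[1],
                "vvx": h.v_v[0], "vvy": h.v_v[1],
                "dvx": h.delta_v_ball[0], "dvy": h.delta_v_ball[1],
            }
            for h in self.hits
        ]
        return pd.DataFrame(
            rows,
            columns=["t_hit", "q1", "q2", "theta", "x", "y",
                     "vpx", "vpy", "vvx", "vvy", "dvx", "dvy"],
        )


# ----------------------------------------------------------------------
# elementary game operations
# ----------------------------------------------------------------------
def collision_response(
    v_ball_in: np.ndarray,
    v_paddle: np.ndarray,
    theta: float,
    restitution: float = RESTITUTION,
    paddle_coupling: float = PADDLE_COUPLING,
) -> np.ndarray:
    """Outgoing ball velocity after a paddle collision.

    Reflection about the paddle line at orientation ``theta`` scaled by the
    restitution factor, plus the paddle-velocity coupling term.
    """
    c, s = np.cos(2.0 * theta), np.sin(2.0 * theta)
    refl = np.array([[c, s], [s, -c]])
    return restitution * refl @ np.asarray(v_ball_in, dtype=float) + \
        paddle_coupling * np.asarray(v_paddle, dtype=float)


def apply_friction(v_ball: np.ndarray, dt: float, rate: float) -> np.ndarray:
    """Reduce ball speed by ``rate * dt`` along its heading (floored at zero)."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    v = np.asarray(v_ball, dtype=float)
    speed = float(np.hypot(*v))
    if speed == 0.0:
        return v.copy()
    new_speed = max(0.0, speed - rate * dt)
    return v * (new_speed / speed)


def bounce_perturbation(
    rng: np.random.Generator, halfwidth: float = BOUNCE_NOISE_HALFWIDTH
) -> float:
    """Uniform far-wall velocity perturbation on [-halfwidth, +halfwidth]."""
    return float(rng.uniform(-halfwidth, halfwidth))


def delayed_view(
    t_hist: np.ndarray,
    pos_hist: np.ndarray,
    vel_hist: np.ndarray,
    tau: float,
    t: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Visual paddle state at time ``t``: the hand state at ``t - tau``.

    Linear interpolation between samples; queries before the history start
    return the initial state (the screen shows the initial hand position for
    the first ``tau`` seconds).
    """
    t_hist = np.asarray(t_hist, dtype=float)
    if t_hist.size == 0:
        raise ValueError("empty trajectory history")
    tq = t - tau
    if tq <= t_hist[0]:
        return np.array(pos_hist[0], dtype=float), np.array(vel_hist[0], dtype=float)
    pos = np.array([np.interp(tq, t_hist, np.asarray(pos_hist)[:, k]) for k in range(2)])
    vel = np.array([np.interp(tq, t_hist, np.asarray(vel_hist)[:, k]) for k in range(2)])
    return pos, vel


def haptic_impulse(
    delta_v_ball: np.ndarray,
    mb: float = HAPTIC_MASS,
    duration: float = HAPTIC_DURATION,
    tau: float = 0.0,
) -> HapticPulse:
    """Haptic pulse ``f = mb * dv`` for 5 ms, delayed by ``tau`` when the
    session is delayed (all feedback channels share the delay)."""
    return HapticPulse(
        force=mb * np.asarray(delta_v_ball, dtype=float),
        duration=duration,
        delay=tau,
    )


# ----------------------------------------------------------------------
# player stroke planning
# ----------------------------------------------------------------------
@dataclass
class StrokePlan:
    segments: list          # MinJerkSegment list: [reposition?, out, back]
    t_out_start: float      # start of the out-phase
    t_contact: float        # intended visual-contact time
    contact_s: float        # hit-axis coordinate of the intended contact
    contact_tr: float       # transverse coordinate


def simulate_player_stroke(
    player: PlayerModel,
    court: CourtGeometry,
    intercept_s: float,
    intercept_tr: float,
    intercept_time: float,
    tau: float,
    hand_position: np.ndarray,
    t_now: float,
    timing_noise: float = 0.0,
    amplitude_noise: float = 0.0,
    direction_noise: float = 0.0,
    delta_effective: Optional[float] = None,
) -> Optional[StrokePlan]:
    """Plan a reciprocal out-and-back stroke meeting the ball at the intercept.

    The out-phase is a rest-to-rest minimum-jerk move of the stroke amplitude
    along the hit axis; its peak-speed instant sits at mid-phase.  The stroke
    is placed so the *visual* paddle reaches the intercept at
    ``peak + tau/2 + delta + noise``.  Returns ``None`` when there is not
    enough time to prepare, which the caller logs as a missed return.
    """
    if not (court.tr_lo - 1e-9 <= intercept_tr <= court.tr_hi + 1e-9):
        return None
    if not (court.s_near - 1e-9 <= intercept_s <= court.s_far + 1e-9):
        return None
    delta = player.timing_offset if delta_effective is None else delta_effective
    t_o = player.stroke_duration
    amp = max(0.02, player.stroke_amplitude + amplitude_noise)
    # proprioceptive phase of contact within the out-stroke
    phase_p = t_o / 2.0 + tau / 2.0 + delta + timing_noise
    # visual phase (the visual paddle lags by tau)
    phase_v = phase_p - tau
    if not (0.0 < phase_v < t_o and 0.0 < phase_p < 2.0 * t_o):
        return None
    t_out = intercept_time - phase_p
    # stroke direction: the hit axis plus a per-stroke angular wobble
    phi = float(np.clip(direction_noise, -0.3, 0.3))
    direction = np.cos(phi) * court.h + np.sin(phi) * court.tvec
    # place the stroke so the visual paddle is at the intercept at contact
    sv = phase_v / t_o
    frac = 10 * sv**3 - 15 * sv**4 + 6 * sv**5
    p_contact = court.point(intercept_s, intercept_tr)
    p_start = p_contact - amp * frac * direction
    p_end = p_start + amp * direction
    avail = t_out - t_now
    if avail < 0.1:
        return None
    rep_dur = float(np.clip(avail - 0.02, 0.1, 0.35))
    # the retraction carries the hand behind the near edge, out of the ball's
    # corridor (the court confines the ball, not the hand); the returning
    # ball therefore never meets a lingering paddle between strokes
    p_rest = court.point(court.s_near - 0.08, intercept_tr)
    segments = [
        MinJerkSegment(t0=t_out - rep_dur, duration=rep_dur,
                       p0=tuple(hand_position), p1=tuple(p_start)),
        MinJerkSegment(t0=t_out, duration=t_o,
                       p0=tuple(p_start), p1=tuple(p_end)),
        MinJerkSegment(t0=t_out + t_o, duration=max(0.35, 0.6 * t_o),
                       p0=tuple(p_end), p1=tuple(p_rest)),
    ]
    return StrokePlan(
        segments=segments, t_out_start=t_out, t_contact=intercept_time,
        contact_s=intercept_s, contact_tr=intercept_tr,
    )


class _HandSchedule:
    """Piecewise minimum-jerk hand trajectory with hold states in between."""

    def __init__(self, initial: np.ndarray):
        self.segments: list[MinJerkSegment] = []
        self.hold = np.array(initial, dtype=float)

    def state(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        # newest segment started by time t wins (replans may overlap an
        # active move; the replacement starts from a continuous position)
        active = None
        for seg in self.segments:
            if seg.t0 <= t:
                active = seg
        if active is None:
            return np.array(self.hold, dtype=float), np.zeros(2)
        if t < active.t1:
            return active.state(t)
        return np.array(active.p1, dtype=float), np.zeros(2)

    def prune(self, t: float) -> None:
        while self.segments and self.segments[0].t1 < t:
            self.hold = np.array(self.segments.pop(0).p1)

    def replace_future(self, t: float, segments: list[MinJerkSegment]) -> None:
        self.segments = [s for s in self.segments if s.t0 <= t] + list(segments)


# ----------------------------------------------------------------------
# ball arrival prediction (deterministic trace, no future far-wall noise)
# ----------------------------------------------------------------------
def _predict_arrival(
    config: PongConfig, court: CourtGeometry, pos: np.ndarray, vel: np.ndarray,
    target_s: float, horizon: float = 6.0,
):
    """Time and transverse coordinate at which the ball next crosses
    ``target_s`` moving toward the player.  Returns ``None`` if it never does
    (e.g. friction stalls the ball first)."""
    dt = 1.0 / config.sample_rate
    s = court.s_of(pos)
    tr = court.tr_of(pos)
    vs = float(vel @ court.h)
    vt = float(vel @ court.tvec)
    t = 0.0
    while t < horizon:
        speed = float(np.hypot(vs, vt))
        if speed < 0.02:
            return None
        scale = max(0.0, speed - config.friction_decay * dt) / speed
        vs *= scale
        vt *= scale
        s_new = s + vs * dt
        tr_new = tr + vt * dt
        if vs < 0 and s >= target_s >= s_new:
            alpha = (s - target_s) / (s - s_new) if s != s_new else 0.0
            return t + alpha * dt, tr + alpha * (tr_new - tr)
        # reflections
        if s_new > court.s_far:
            s_new = 2 * court.s_far - s_new
            vs = -vs
        if s_new < court.s_near:
            return None  # will be a miss
        if tr_new > court.tr_hi:
            tr_new = 2 * court.tr_hi - tr_new
            vt = -vt
        elif tr_new < court.tr_lo:
            tr_new = 2 * court.tr_lo - tr_new
            vt = -vt
        s, tr = s_new, tr_new
        t += dt
    return None


# ----------------------------------------------------------------------
# full session
# ----------------------------------------------------------------------
def run_pong_session(
    config: PongConfig,
    player: PlayerModel,
    duration: float = 300.0,
    seed: Optional[int] = None,
    linkage: Optional[FiveBarLinkage] = None,
) -> SessionLog:
    """Simulate a pong session and return the full :class:`SessionLog`.

    ``duration`` in seconds.  Identical ``(config, player, seed)`` reproduce
    identical logs.  Joint angles in the log are in robot coordinates of the
    (default) calibrated linkage.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    court = config.court
    tau = float(config.delay_tau)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    linkage = linkage or FiveBarLinkage(DEFAULT_LINKAGE)

    dt = 1.0 / config.sample_rate
    n = int(round(duration * config.sample_rate)) + 1
    t_grid = np.arange(n) * dt

    home = court.point(court.s_near - 0.08, court.tr_of(court.centre))
    sched = _HandSchedule(home)

    hand_pos = np.zeros((n, 2))
    hand_vel = np.zeros((n, 2))
    vis_pos = np.zeros((n, 2))
    vis_vel = np.zeros((n, 2))

    contact_s = court.s_of(court.contact_point)

    ball: Optional[BallState] = None
    serve_at = 0.0
    hits: list[HitEvent] = []
    misses = 0
    n_strokes = 0
    last_hit_t = -np.inf
    pending_plan: Optional[StrokePlan] = None

    def serve(t_now: float) -> BallState:
        phi = rng.uniform(-0.5, 0.5)
        direction = np.cos(phi) * court.h + np.sin(phi) * court.tvec
        return BallState(
            position=court.centre.copy(),
            velocity=config.ball_speed_init * direction,
        )

    def plan(t_now: float, b: BallState) -> None:
        nonlocal pending_plan, n_strokes
        aim_s = contact_s + float(
            np.clip(rng.normal(0.0, player.aim_jitter), -0.08, 0.08)
        )
        arr = _predict_arrival(config, court, b.position, b.velocity, aim_s)
        if arr is None:
            pending_plan = None
            return
        t_star, tr_star = arr
        tr_star = float(np.clip(tr_star, court.tr_lo + 0.01, court.tr_hi - 0.01))
        pos_now, _ = sched.state(t_now)
        planp = simulate_player_stroke(
            player, court, aim_s, tr_star, t_now + t_star, tau,
            pos_now, t_now,
            timing_noise=rng.normal(0.0, player.timing_jitter),
            amplitude_noise=rng.normal(0.0, player.amplitude_jitter),
            direction_noise=rng.normal(0.0, player.direction_jitter),
            delta_effective=player.effective_offset(n_strokes),
        )
        # preserve the follow-through: never let a new preparation move cut
        # into the hand trajectory right after a collision
        if planp is not None and planp.segments[0].t0 < last_hit_t + 0.25:
            planp = None
        if planp is not None:
            sched.replace_future(t_now, planp.segments)
            n_strokes += 1
        pending_plan = planp

    def interp_state(arr_p, arr_v, tq):
        if tq <= 0.0:
            return arr_p[0].copy(), arr_v[0].copy()
        i = min(int(tq / dt), n - 2)
        a = (tq - t_grid[i]) / dt
        return (
            (1 - a) * arr_p[i] + a * arr_p[i + 1],
            (1 - a) * arr_v[i] + a * arr_v[i + 1],
        )

    for i in range(n):
        t = t_grid[i]
        sched.prune(t)
        hand_pos[i], hand_vel[i] = sched.state(t)
        if tau == 0.0:
            vis_pos[i], vis_vel[i] = hand_pos[i], hand_vel[i]
        else:
            tq = t - tau
            if tq <= 0.0:
                vis_pos[i], vis_vel[i] = hand_pos[0], np.zeros(2)
            else:
                j = min(int(tq / dt), n - 2)
                a = (tq - t_grid[j]) / dt
                vis_pos[i] = (1 - a) * hand_pos[j] + a * hand_pos[j + 1]
                vis_vel[i] = (1 - a) * hand_vel[j] + a * hand_vel[j + 1]

        if i == 0:
            continue

        # ---------------- ball physics over [t-dt, t] ----------------
        if ball is None:
            if t >= serve_at:
                ball = serve(t)
                plan(t, ball)
            continue

        ball.velocity = apply_friction(ball.velocity, dt, config.friction_decay)
        p_prev = ball.position
        p_new = p_prev + ball.velocity * dt

        # paddle contact: ball crossing the (moving) visual paddle line
        g_prev = court.s_of(p_prev) - court.s_of(vis_pos[i - 1])
        g_new = court.s_of(p_new) - court.s_of(vis_pos[i])
        if (
            g_prev > 0.0 >= g_new
            and (t - last_hit_t) > config.hit_refractory
        ):
            alpha = g_prev / (g_prev - g_new)
            t_hit = t_grid[i - 1] + alpha * dt
            ball_at = p_prev + alpha * (p_new - p_prev)
            pad_at = (1 - alpha) * vis_pos[i - 1] + alpha * vis_pos[i]
            if abs(court.tr_of(ball_at) - court.tr_of(pad_at)) <= config.paddle_half_length:
                pad_vel = (1 - alpha) * vis_vel[i - 1] + alpha * vis_vel[i]
                v_out = collision_response(
                    ball.velocity, pad_vel, court.paddle_theta,
                    config.restitution, config.paddle_coupling,
                )
                dv = v_out - ball.velocity
                hp, hv = interp_state(hand_pos, hand_vel, t_hit)
                vv_pos, vv_vel = interp_state(hand_pos, hand_vel, t_hit - tau)
                hits.append(HitEvent(
                    t_hit=t_hit, hand_position=hp,
                    q_hit=np.full(2, np.nan), paddle_theta=court.paddle_theta,
                    v_p=hv, v_v=vv_vel, delta_v_ball=dv,
                ))
                last_hit_t = t_hit
                ball.velocity = v_out
                ball.position = ball_at + v_out * (1 - alpha) * dt
                plan(t, ball)
                continue

        # walls
        s_new = court.s_of(p_new)
        tr_new = court.tr_of(p_new)
        vs = float(ball.velocity @ court.h)
        vt = float(ball.velocity @ court.tvec)
        bounced_far = False
        if s_new > court.s_far:
            s_new = 2 * court.s_far - s_new
            vs = -vs
            vt += bounce_perturbation(rng, config.bounce_noise_halfwidth)
            bounced_far = True
        if tr_new > court.tr_hi:
            tr_new = 2 * court.tr_hi - tr_new
            vt = -vt
        elif tr_new < court.tr_lo:
            tr_new = 2 * court.tr_lo - tr_new
            vt = -vt
        ball.position = court.point(s_new, tr_new)
        ball.velocity = vs * court.h + vt * court.tvec

        if bounced_far:
            # the player sees the (post-bounce) return and adjusts, as long
            # as the stroke has not started yet
            if pending_plan is None or t < pending_plan.t_out_start - 0.05:
                plan(t, ball)

        speed = float(np.hypot(*ball.velocity))
        if s_new < court.s_near - 0.02 or speed < 0.02:
            misses += 1
            ball = None
            serve_at = t + config.serve_pause
            pending_plan = None

    # ---------------- assemble the log ----------------
    q = linkage.inverse_kinematics(body_to_robot(hand_pos))
    for h in hits:
        h.q_hit = linkage.inverse_kinematics(body_to_robot(h.hand_position))

    traj = pd.DataFrame({
        "t": t_grid,
        "q1": q[:, 0], "q2": q[:, 1],
        "x": hand_pos[:, 0], "y": hand_pos[:, 1],
        "vx": hand_vel[:, 0], "vy": hand_vel[:, 1],
        "xv": vis_pos[:, 0], "yv": vis_pos[:, 1],
        "vxv": vis_vel[:, 0], "vyv": vis_vel[:, 1],
    })
    minutes = int(np.ceil(duration / 60.0))
    per_minute = [0] * minutes
    for h in hits:
        per_minute[min(int(h.t_hit // 60.0), minutes - 1)] += 1
    header = {
        "config": config.to_dict(),
        "player": player.to_dict(),
        "seed": int(config.seed if seed is None else seed),
        "duration": float(duration),
        "n_hits": len(hits),
        "n_misses": int(misses),
    }
    return SessionLog(
        header=header, trajectory=traj, hits=hits,
        per_minute_hits=per_minute, misses=misses,
    )
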