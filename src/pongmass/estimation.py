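"""Event-based estimation of the perceived endpoint mass.

At each ball-paddle collision the player receives two velocity measurements
of the same paddle: the proprioceptive speed ``v_p`` (the hand, undelayed)
and the visual speed ``v_v`` (the on-screen paddle, the hand delayed by
``tau``).  Requiring the estimated kinetic energy exchanged at the collision
to be invariant across modalities turns the velocity mismatch into a mass
mismatch:

    m_v = m_r                 (vision sets the reference)
    m_p = m_r * v_v^2 / v_p^2 (proprioception absorbs the mismatch)

where ``m_r`` is the true effective endpoint mass at the hit configuration
along the motion direction.  The two per-hit samples are fused by
maximum-likelihood (inverse-variance) weighting over the analysis window,

    E(m) = w_v mean(m_v) + w_p mean(m_p),   w_i  proportional to 1/sigma_i^2,

and the *mass modifier* is the perceptual surplus ``m_hat = E(m) - m_r``.
Per-hit, ``m_hat = m_r (v_v^2 - v_p^2) / v_p^2``; its sign follows the sign
of ``|v_v| - |v_p|`` (hits while accelerating / at the crossing / while
decelerating give negative / zero / positive modifiers).

Velocities are smoothed with a zero-phase fifth-order Butterworth low-pass
at 20 Hz before hit-time interpolation, and hits whose proprioceptive mass
lies more than ten SDs of the visual-mass sample from its mean are removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .linkage import DEFAULT_LINKAGE, FiveBarLinkage, SAMPLE_RATE
from .pong import SessionLog

__all__ = [
    "FilterConfig",
    "VelocityPair",
    "MassEstimate",
    "smooth_velocity",
    "extract_hit_velocities",
    "effective_masses_at_hit",
    "filter_outlier_hits",
    "fuse_masses",
    "mass_modifier",
    "per_hit_modifier",
    "MassModifierEstimator",
    "SPEED_FLOOR",
]

#: hits with proprioceptive speed below this (m/s) are rejected before the
#: kinetic-energy ratio is formed (degenerate division guard)
SPEED_FLOOR = 0.02

#: outlier rule: remove hits with |m_p - mean(m_v)| > 10 SD(m_v)
OUTLIER_SD = 10.0


@dataclass(frozen=True)
class FilterConfig:
    """Zero-phase Butterworth smoothing of velocity signals."""

    order: int = 5
    cutoff: float = 20.0       # Hz
    sample_rate: float = SAMPLE_RATE

    def __post_init__(self) -> None:
        if not 0 < self.cutoff < self.sample_rate / 2:
            raise ValueError("cutoff must lie below the Nyquist frequency")


@dataclass
class VelocityPair:
    """Per-hit speeds projected on the instantaneous motion direction."""

    t_hit: float
    v_v: float        # visual speed along theta_dir (m/s)
    v_p: float        # proprioceptive speed along theta_dir (m/s)
    q_hit: np.ndarray
    theta_dir: float  # motion direction, CCW from +x (rad)


@dataclass
class MassEstimate:
    """Per-session fusion result."""

    m_r: float                  # reference effective mass (mean over hits, kg)
    mv_samples: np.ndarray      # per-hit visual effective masses (kg)
    mp_samples: np.ndarray      # per-hit proprioceptive effective masses (kg)
    sigma_v2: float             # sample variance of m_v (kg^2)
    sigma_p2: float             # sample variance of m_p (kg^2)
    w_v: float
    w_p: float
    E_m: float                  # fused (apparent) mass (kg)
    m_hat: float                # mass modifier, E_m - m_r (kg)
    n_hits_retained: int
    n_hits_removed: int

    def to_dict(self) -> dict:
        return {
            "m_r": self.m_r,
            "mean_mv": float(np.mean(self.mv_samples)),
            "mean_mp": float(np.mean(self.mp_samples)),
            "sigma_v2": self.sigma_v2,
            "sigma_p2": self.sigma_p2,
            "w_v": self.w_v,
            "w_p": self.w_p,
            "E_m": self.E_m,
            "m_hat": self.m_hat,
            "n_hits_retained": self.n_hits_retained,
            "n_hits_removed": self.n_hits_removed,
        }


# ----------------------------------------------------------------------
# smoothing
# ----------------------------------------------------------------------
def smooth_velocity(signal: np.ndarray, cfg: FilterConfig = FilterConfig()) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass of a velocity signal.

    Works on 1-D signals or (n, k) arrays column-wise; zero phase keeps
    hit-time values unshifted in time.
    """
    signal = np.asarray(signal, dtype=float)
    sos = butter(cfg.order, cfg.cutoff, fs=cfg.sample_rate, output="sos")
    padlen = 3 * (2 * cfg.order + 1)
    if signal.shape[0] <= padlen:
        raise ValueError(
            f"signal too short for the filter warm-up ({signal.shape[0]} <= {padlen})"
        )
    return sosfiltfilt(sos, signal, axis=0)


# ----------------------------------------------------------------------
# hit extraction
# ----------------------------------------------------------------------
def extract_hit_velocities(
    session: SessionLog,
    tau: Optional[float] = None,
    window_minutes: float = 5.0,
    cfg: FilterConfig = FilterConfig(),
    speed_floor: float = SPEED_FLOOR,
) -> list[VelocityPair]:
    """Per-hit visual/proprioceptive speeds from the last-minutes window.

    The hand velocity trace is smoothed once; ``v_p`` is its value at the hit
    time, ``v_v`` the smoothed hand velocity evaluated at ``t_hit - tau``,
    both projected on the instantaneous motion direction at the hit.  Hits
    earlier than ``tau`` after session start, or below the speed floor, are
    skipped.
    """
    if tau is None:
        tau = float(session.header["config"]["delay_tau"])
    traj = session.trajectory
    t = traj["t"].to_numpy()
    t_end = t[-1]
    t_start = max(t[0], t_end - window_minutes * 60.0)
    vel = smooth_velocity(traj[["vx", "vy"]].to_numpy(), cfg)

    pairs: list[VelocityPair] = []
    for h in session.hits:
        if h.t_hit < t_start or h.t_hit < t[0] + tau:
            continue
        vp_vec = np.array([np.interp(h.t_hit, t, vel[:, k]) for k in range(2)])
        vv_vec = np.array([np.interp(h.t_hit - tau, t, vel[:, k]) for k in range(2)])
        speed_p = float(np.hypot(*vp_vec))
        if speed_p < speed_floor:
            continue
        theta = float(np.arctan2(vp_vec[1], vp_vec[0]))
        u = np.array([np.cos(theta), np.sin(theta)])
        pairs.append(VelocityPair(
            t_hit=h.t_hit,
            v_v=float(vv_vec @ u),
            v_p=float(vp_vec @ u),
            q_hit=np.asarray(h.q_hit, dtype=float),
            theta_dir=theta,
        ))
    if not pairs:
        raise ValueError("no usable hits in the analysis window")
    return pairs


# ----------------------------------------------------------------------
# per-hit masses and the modifier
# ----------------------------------------------------------------------
def effective_masses_at_hit(
    m_r: float, pair: VelocityPair, speed_floor: float = SPEED_FLOOR
) -> tuple[float, float]:
    """Visual and proprioceptive effective masses for one hit.

    ``m_v = m_r``; ``m_p = m_r v_v^2 / v_p^2``.  Raises when the
    proprioceptive speed is degenerate.
    """
    if abs(pair.v_p) < speed_floor:
        raise ValueError("proprioceptive speed below the floor; hit rejected")
    return m_r, m_r * pair.v_v**2 / pair.v_p**2


def per_hit_modifier(m_r: float, v_v: float, v_p: float) -> float:
    """Mass modifier from a single hit: ``m_r (v_v^2 - v_p^2) / v_p^2``."""
    if v_p == 0:
        raise ValueError("v_p must be nonzero")
    return m_r * (v_v**2 - v_p**2) / v_p**2


def filter_outlier_hits(
    mv_samples: Sequence[float],
    mp_samples: Sequence[float],
    n_sd: float = OUTLIER_SD,
) -> np.ndarray:
    """Boolean mask retaining hits whose proprioceptive mass lies within
    ``n_sd`` SDs of the visual-mass sample mean.

    With a degenerate (zero-SD) visual sample only hits with ``m_p`` equal to
    the mean are retained.  Raises when every hit would be removed.
    """
    mv = np.asarray(mv_samples, dtype=float)
    mp = np.asarray(mp_samples, dtype=float)
    if mv.size < 2:
        raise ValueError("need at least two hits to filter outliers")
    centre = mv.mean()
    sd = mv.std(ddof=1)
    keep = np.abs(mp - centre) <= n_sd * sd
    if not keep.any():
        raise ValueError("outlier filter removed every hit")
    return keep


def fuse_masses(
    mv_samples: Sequence[float], mp_samples: Sequence[float]
) -> MassEstimate:
    """Maximum-likelihood fusion of the visual and proprioceptive masses.

    Weights are inverse sample variances over the window's hits; a channel
    with zero variance takes all the weight (both zero is an error).
    """
    mv = np.asarray(mv_samples, dtype=float)
    mp = np.asarray(mp_samples, dtype=float)
    if mv.size < 2 or mp.size < 2:
        raise ValueError("need at least two samples per channel")
    if not (np.all(np.isfinite(mv)) and np.all(np.isfinite(mp))):
        raise ValueError("non-finite mass samples")
    sv2 = float(mv.var(ddof=1))
    sp2 = float(mp.var(ddof=1))
    if sv2 == 0.0 and sp2 == 0.0:
        raise ValueError("zero variance in both channels; weights undefined")
    if sv2 == 0.0:
        w_v, w_p = 1.0, 0.0
    elif sp2 == 0.0:
        w_v, w_p = 0.0, 1.0
    else:
        w_v = (1.0 / sv2) / (1.0 / sv2 + 1.0 / sp2)
        w_p = 1.0 - w_v
    m_r = float(mv.mean())
    e_m = w_v * mv.mean() + w_p * mp.mean()
    return MassEstimate(
        m_r=m_r, mv_samples=mv, mp_samples=mp,
        sigma_v2=sv2, sigma_p2=sp2, w_v=w_v, w_p=w_p,
        E_m=float(e_m), m_hat=float(e_m - m_r),
        n_hits_retained=mv.size, n_hits_removed=0,
    )


def mass_modifier(estimate: MassEstimate, m_r: Optional[float] = None) -> float:
    """Mass modifier ``E(m) - m_r`` of a fused estimate."""
    ref = estimate.m_r if m_r is None else m_r
    return estimate.E_m - ref


# ----------------------------------------------------------------------
# session-level estimator
# ----------------------------------------------------------------------
class MassModifierEstimator:
    """Per-session mass-modifier inference (fit-style interface).

    Parameters
    ----------
    linkage : FiveBarLinkage, optional
        Robot model supplying the reference effective mass at each hit
        configuration; defaults to the calibrated package linkage.
    tau : float, optional
        Visuomotor delay; defaults to the session header value.
    window_minutes : float
        Length of the end-of-adaptation analysis window.

    After :meth:`fit`, the fused result is available as ``estimate_`` and the
    mass modifier as ``m_hat_``.
    """

    def __init__(
        self,
        linkage: Optional[FiveBarLinkage] = None,
        tau: Optional[float] = None,
        window_minutes: float = 5.0,
        filter_config: FilterConfig = FilterConfig(),
        speed_floor: float = SPEED_FLOOR,
        outlier_sd: float = OUTLIER_SD,
    ):
        self.linkage = linkage
        self.tau = tau
        self.window_minutes = window_minutes
        self.filter_config = filter_config
        self.speed_floor = speed_floor
        self.outlier_sd = outlier_sd

    def fit(self, session: SessionLog) -> "MassModifierEstimator":
        linkage = self.linkage or FiveBarLinkage(DEFAULT_LINKAGE)
        pairs = extract_hit_velocities(
            session, tau=self.tau, window_minutes=self.window_minutes,
            cfg=self.filter_config, speed_floor=self.speed_floor,
        )
        mv, mp = [], []
        for pair in pairs:
            m_r = linkage.effective_mass(pair.q_hit, pair.theta_dir)
            a, b = effective_masses_at_hit(m_r, pair, self.speed_floor)
            mv.append(a)
            mp.append(b)
        keep = filter_outlier_hits(mv, mp, self.outlier_sd)
        est = fuse_masses(np.asarray(mv)[keep], np.asarray(mp)[keep])
        est.n_hits_removed = int((~keep).sum())
        self.pairs_ = pairs
        self.estimate_ = est
        self.m_hat_ = est.m_hat
        return self

    def fit_estimate(self, session: SessionLog) -> MassEstimate:
        return self.fit(session).estimate_
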