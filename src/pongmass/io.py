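"""Plain-text persistence: session logs, estimates, parameter configs.

A session directory holds ``header.json`` plus two CSVs (``trajectory.csv``
at 200 Hz and ``hits.csv`` with one row per collision).  Linkage parameters
travel as flat key-value YAML in SI units; effective-mass polar profiles as
two-column CSV (angle_rad, mass_kg).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimation import MassEstimate
from .linkage import FiveBarLinkage, LinkageParameters
from .pong import HitEvent, PongConfig, PlayerModel, SessionLog

__all__ = [
    "save_session",
    "load_session",
    "save_mass_estimate",
    "save_linkage_params",
    "load_linkage_params",
    "save_polar_profile",
]


def save_session(session: SessionLog, out_dir: str | Path) -> Path:
    """Persist a session as header.json + trajectory.csv + hits.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "header.json", "w") as fh:
        json.dump(
            {**session.header,
             "per_minute_hits": session.per_minute_hits},
            fh, indent=2,
        )
    session.trajectory.to_csv(out / "trajectory.csv", index=False)
    session.hit_table.to_csv(out / "hits.csv", index=False)
    return out


def load_session(in_dir: str | Path) -> SessionLog:
    """Load a session directory written by :func:`save_session`."""
    src = Path(in_dir)
    with open(src / "header.json") as fh:
        header = json.load(fh)
    per_minute = header.pop("per_minute_hits", [])
    traj = pd.read_csv(src / "trajectory.csv")
    hit_df = pd.read_csv(src / "hits.csv")
    hits = [
        HitEvent(
            t_hit=float(r.t_hit),
            hand_position=np.array([r.x, r.y]),
            q_hit=np.array([r.q1, r.q2]),
            paddle_theta=float(r.theta),
            v_p=np.array([r.vpx, r.vpy]),
            v_v=np.array([r.vvx, r.vvy]),
            delta_v_ball=np.array([r.dvx, r.dvy]),
        )
        for r in hit_df.itertuples()
    ]
    return SessionLog(
        header=header, trajectory=traj, hits=hits,
        per_minute_hits=list(per_minute),
        misses=int(header.get("n_misses", 0)),
    )


def save_mass_estimate(estimate: MassEstimate, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(estimate.to_dict(), fh, indent=2)
    return path


def save_linkage_params(params: LinkageParameters, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
    return path


def load_linkage_params(path: str | Path) -> LinkageParameters:
    with open(path) as fh:
        return LinkageParameters.from_dict(yaml.safe_load(fh))


def save_polar_profile(
    linkage: FiveBarLinkage, q, path: str | Path, n_directions: int = 64
) -> Path:
    """Export an effective-mass polar profile as CSV (angle_rad, mass_kg)."""
    angles, masses = linkage.effective_mass_polar(q, n_directions)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"angle_rad": angles, "mass_kg": masses}).to_csv(
        path, index=False
    )
    return path
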