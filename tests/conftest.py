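import numpy as np
import pytest

from pongmass.geometry import body_to_robot, court_for_group
from pongmass.linkage import DEFAULT_LINKAGE, FiveBarLinkage, LinkageParameters
from pongmass.pong import PlayerModel, PongConfig, run_pong_session


@pytest.fixture(scope="session")
def linkage() -> FiveBarLinkage:
    return FiveBarLinkage(DEFAULT_LINKAGE)


@pytest.fixture(scope="session")
def point_mass_params() -> LinkageParameters:
    """Near-massless links with a 1 kg handle: the point-mass limit."""
    eps = 1e-9
    return LinkageParameters(
        base_separation=DEFAULT_LINKAGE.base_separation,
        proximal_lengths=DEFAULT_LINKAGE.proximal_lengths,
        distal_lengths=DEFAULT_LINKAGE.distal_lengths,
        link_masses=(eps, eps, eps, eps),
        link_com_offsets=DEFAULT_LINKAGE.link_com_offsets,
        link_inertias=(eps, eps, eps, eps),
        endpoint_mass=1.0,
    )


def random_workspace_q(linkage, rng, n=1):
    """Random reachable configurations drawn over the court region."""
    pts = rng.uniform([-0.2, 0.30], [0.2, 0.50], size=(n, 2))
    q = linkage.inverse_kinematics(body_to_robot(pts))
    return q if n > 1 else q[0]


@pytest.fixture(scope="session")
def delayed_session():
    """A short delayed lateral-pong session shared across tests."""
    cfg = PongConfig(court_side="LP_R", seed=42)
    return run_pong_session(cfg, PlayerModel(), duration=90.0, seed=42)


@pytest.fixture(scope="session")
def zero_delay_session():
    cfg = PongConfig(court_side="LP_R", delay_tau=0.0, seed=7)
    return run_pong_session(cfg, PlayerModel(), duration=90.0, seed=7)
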