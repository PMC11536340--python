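import numpy as np
import pytest

from enzloop.structure import Trajectory, make_topology


def build_trajectory(entries, frames):
    """Trajectory from (name, resname, chain, resid) entries + coordinate frames."""
    return Trajectory(make_topology(entries), np.asarray(frames, dtype=float))


@pytest.fixture
def loop_fixture():
    """9 loop residues (resid 39-47) x 4 heavy atoms + 1 hydrogen each,
    plus two scaffold CA atoms, 1 frame."""
    entries = []
    coords = []
    rng = np.random.default_rng(42)
    for resid in (10, 11):
        entries.append(("CA", "GLY", "A", resid))
        coords.append(rng.uniform(-5, 5, 3))
    for resid in range(39, 48):
        for name in ("N", "CA", "C", "O", "HA"):
            entries.append((name, "ALA", "A", resid))
            coords.append(rng.uniform(-5, 5, 3))
    return build_trajectory(entries, [coords])


@pytest.fixture
def pose_topology_entries():
    return (
        ("CA", "TYR", "A", 165),
        ("OH", "TYR", "A", 165),
        ("C1", "CHO", "A", 200),
        ("C2", "CHO", "A", 200),
        ("O1", "CHO", "A", 200),
        ("N1", "AZI", "A", 201),
        ("N2", "AZI", "A", 201),
        ("N3", "AZI", "A", 201),
    )


def pose_frame_coords(d_oy, d_nc1, ang1_deg):
    """Hand-placed pose with exact d(O1-OH), d(N3-C1) and angle(N2-N3-C1).

    Epoxide in the xz-plane, azide approach along -x from C1, tyrosine OH
    straight above O1. Matches the topology order of pose_topology_entries.
    """
    c1 = np.zeros(3)
    c2 = np.array([1.47, 0.0, 0.0])
    o1 = np.array([0.735, 0.0, np.sqrt(1.44**2 - 0.735**2)])
    n3 = c1 + np.array([-d_nc1, 0.0, 0.0])
    theta = np.deg2rad(ang1_deg)
    # unit vector from N3 toward C1 is +x; rotate by theta in the xy-plane
    v = np.array([np.cos(theta), np.sin(theta), 0.0])
    n2 = n3 + 1.13 * v
    n1 = n2 + 1.13 * v
    oh = o1 + np.array([0.0, 0.0, d_oy])
    ca = oh + np.array([0.0, 0.0, 1.4])
    return np.stack([ca, oh, c1, c2, o1, n1, n2, n3])
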