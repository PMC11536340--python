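"""Synthetic ground-truth generators for every analysis stage.

These generators emulate the four kinds of input the analyses consume, with
known truth attached so recovery can be checked end to end:

* a two-state flexible loop (closed vs open) sampled as Gaussian basins around
  two displaced coordinate templates,
* active-site ligand poses (cyclohexene-oxide analogue + azide + catalytic
  tyrosine) with prescribed fractions of catalytically competent pro-S and
  pro-R attack geometries,
* Hill-kinetic rate tables with multiplicative noise,
* screening plates with known per-variant conversion and product ee.

Everything is bit-reproducible given the config seed. Geometries are built so
that no measurement lands on a classification boundary (a margin of 0.05 A /
0.05 deg is kept from the 4 A and 80-120 deg thresholds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .kinetics import HillParams, RateDataset, hill_rate, EPOXIDE_CONCENTRATIONS_MM
from .structure import Trajectory, make_topology

__all__ = [
    "LoopSimConfig",
    "PoseSimConfig",
    "KineticSimConfig",
    "ScreenSimConfig",
    "gen_loop_trajectory",
    "gen_pose_frames",
    "gen_hill_dataset",
    "gen_screen_table",
    "LOOP_RESIDUE_RANGE",
]

#: Residue-id range of the flexible N-terminal loop (inclusive), mirroring the
#: T39-G47 active-site loop of a G-type halohydrin dehalogenase.
LOOP_RESIDUE_RANGE = (39, 47)

# Epoxide ring geometry used by the pose generator (A).
_CC_BOND = 1.47
_CO_BOND = 1.44
_NN_BOND = 1.13


@dataclass(frozen=True)
class LoopSimConfig:
    """Two-state loop trajectory: closed basin vs open basin.

    ``displacement`` is the shift (A) of the mid-loop residue between the two
    templates; ``displacement / basin_sd`` is the cluster separation that
    controls how hard the downstream landscape recovery is.
    """

    n_frames: int
    p_open: float = 0.3
    basin_sd: float = 1.0
    n_loop_residues: int = 9
    displacement: float = 6.0
    n_scaffold_residues: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0.0 <= self.p_open <= 1.0:
            raise ValueError("p_open must be in [0, 1]")
        if self.basin_sd <= 0:
            raise ValueError("basin_sd must be > 0")
        if self.n_loop_residues < 3:
            raise ValueError("need at least 3 loop residues")

    @property
    def separation(self) -> float:
        """Template separation in units of the basin spread."""
        return self.displacement / self.basin_sd


@dataclass(frozen=True)
class PoseSimConfig:
    """Active-site pose frames with prescribed competence-class fractions."""

    n_frames: int
    frac_proS: float = 0.3
    frac_proR: float = 0.1
    frac_noncompetent: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        fracs = (self.frac_proS, self.frac_proR, self.frac_noncompetent)
        if any(f < 0 for f in fracs):
            raise ValueError("class fractions must be >= 0")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(
                f"class fractions must sum to 1, got {sum(fracs):.6f}"
            )


@dataclass(frozen=True)
class KineticSimConfig:
    """Rate-vs-concentration dataset drawn from a known Hill curve."""

    true_params: HillParams
    concentrations: tuple[float, ...] = tuple(EPOXIDE_CONCENTRATIONS_MM)
    noise_cv: float = 0.02
    replicates: int = 2
    species: str = "epoxide"
    fixed_cosubstrate_mM: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.size < 1 or np.any(conc <= 0):
            raise ValueError("concentrations must be > 0")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class ScreenSimConfig:
    """Screening plate: per-variant true conversion and product ee + noise."""

    variants: tuple[tuple[str, float, float], ...]
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, conv, eep in self.variants:
            if not 0.0 <= conv <= 1.0:
                raise ValueError(f"{name}: conversion {conv} outside [0, 1]")
            if not -1.0 <= eep <= 1.0:
                raise ValueError(f"{name}: eeP {eep} outside [-1, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# Loop trajectory
# ---------------------------------------------------------------------------

_LOOP_RESNAMES = {39: "THR", 44: "THR", 45: "MET", 46: "VAL", 47: "GLY"}
_LOOP_ATOMS = ("N", "CA", "C", "O", "HA")


def _loop_templates(cfg: LoopSimConfig) -> tuple[tuple, np.ndarray, np.ndarray, np.ndarray]:
    """Synthetic geometric archetypes of the closed and open loop.

    These are not crystallographic coordinates: the scaffold is a ring of
    Calpha atoms, the closed loop an outward arc, and the open template
    displaces the loop toward a pocket point at the origin with a bell-shaped
    weight peaked at the mid-loop residue.
    """
    lo, _ = LOOP_RESIDUE_RANGE
    n_loop = cfg.n_loop_residues
    entries: list[tuple[str, str, str, int]] = []
    coords: list[np.ndarray] = []

    # Scaffold: fixed Calpha ring, radius 12 A, z = 0.
    for i in range(cfg.n_scaffold_residues):
        theta = 2 * np.pi * i / cfg.n_scaffold_residues
        entries.append(("CA", "GLY", "A", i + 1))
        coords.append(np.array([12.0 * np.cos(theta), 12.0 * np.sin(theta), 0.0]))

    # Loop: outward arc, radius 13 A, spanning a 100-degree wedge above z = 0.
    loop_mask = []
    for k in range(n_loop):
        resid = lo + k
        resname = _LOOP_RESNAMES.get(resid, "GLY")
        theta = np.deg2rad(40.0 + 100.0 * k / max(n_loop - 1, 1))
        base = np.array([13.0 * np.cos(theta), 13.0 * np.sin(theta), 2.0])
        for a, aname in enumerate(_LOOP_ATOMS):
            entries.append((aname, resname, "A", resid))
            # small intra-residue offsets so atoms are distinct
            offset = np.array([0.4 * a, 0.25 * a, 0.3 * (a % 2)])
            coords.append(base + offset)
            loop_mask.append(len(coords) - 1)

    closed = np.asarray(coords)
    # Open template: displace loop residues toward the pocket (origin), with a
    # Gaussian weight over residue index peaked at the mid-loop residue.
    open_t = closed.copy()
    mid = min(6.0, n_loop - 1.0)  # the residue-45 analogue (index 6 of 39..47)
    for k in range(n_loop):
        w = float(np.exp(-((k - mid) ** 2) / 8.0))
        w /= float(np.exp(0.0))
        for a in range(len(_LOOP_ATOMS)):
            idx = cfg.n_scaffold_residues + k * len(_LOOP_ATOMS) + a
            p = closed[idx]
            direction = -p / np.linalg.norm(p)
            open_t[idx] = p + cfg.displacement * w * direction
    loop_idx = np.asarray(loop_mask, dtype=int)
    return make_topology(entries), closed, open_t, loop_idx


def gen_loop_trajectory(cfg: LoopSimConfig) -> tuple[Trajectory, np.ndarray]:
    """Sample a two-state loop trajectory; returns (trajectory, state labels).

    Each frame draws its state from Bernoulli(``p_open``), takes the matching
    template, and adds isotropic Gaussian noise of ``basin_sd`` to the loop
    atoms only; scaffold atoms are held fixed. Labels are ``"closed"`` /
    ``"open"`` per frame.
    """
    rng = np.random.default_rng(cfg.seed)
    topo, closed, open_t, loop_idx = _loop_templates(cfg)
    states = rng.random(cfg.n_frames) < cfg.p_open
    coords = np.broadcast_to(closed, (cfg.n_frames,) + closed.shape).copy()
    coords[states] = open_t
    noise = rng.normal(0.0, cfg.basin_sd, size=(cfg.n_frames, loop_idx.size, 3))
    coords[:, loop_idx, :] += noise
    labels = np.where(states, "open", "closed")
    traj = Trajectory(
        topo,
        coords,
        metadata={
            "generator": "gen_loop_trajectory",
            "p_open": cfg.p_open,
            "basin_sd": cfg.basin_sd,
            "displacement": cfg.displacement,
            "separation": cfg.separation,
            "seed": cfg.seed,
        },
    )
    return traj, labels


# ---------------------------------------------------------------------------
# Active-site poses
# ---------------------------------------------------------------------------

#: Topology order of the pose frames (see :func:`gen_pose_frames`).
_POSE_ENTRIES = (
    ("CA", "TYR", "A", 165),
    ("OH", "TYR", "A", 165),
    ("C1", "CHO", "A", 200),
    ("C2", "CHO", "A", 200),
    ("O1", "CHO", "A", 200),
    ("N1", "AZI", "A", 201),
    ("N2", "AZI", "A", 201),
    ("N3", "AZI", "A", 201),
)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _cone_direction(axis: np.ndarray, max_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Unit vector within ``max_deg`` of ``axis``."""
    ang = np.deg2rad(rng.uniform(0.0, max_deg))
    psi = rng.uniform(0.0, 2 * np.pi)
    # orthonormal frame around axis
    a = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, a)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    p1 = np.cross(a, helper)
    p1 /= np.linalg.norm(p1)
    p2 = np.cross(a, p1)
    return np.cos(ang) * a + np.sin(ang) * (np.cos(psi) * p1 + np.sin(psi) * p2)


def _build_pose(
    attack_c1: bool,
    d_oy: float,
    d_nc: float,
    theta_deg: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Assemble one pose with exact prescribed geometry, then rigid-transform it.

    The azide's terminal nitrogen N3 is placed at ``d_nc`` from the attacked
    carbon, on the side opposite the other carbon (within a 10-degree cone),
    which guarantees the non-attacked carbon is > 4.05 A away for
    ``d_nc >= 2.7``. N2 sits at the exact N2-N3-C attack angle ``theta_deg``.
    """
    c1 = np.zeros(3)
    c2 = np.array([_CC_BOND, 0.0, 0.0])
    h = np.sqrt(_CO_BOND**2 - (_CC_BOND / 2.0) ** 2)
    o1 = np.array([_CC_BOND / 2.0, 0.0, h])

    target, away = (c1, np.array([-1.0, 0.0, 0.0])) if attack_c1 else (
        c2,
        np.array([1.0, 0.0, 0.0]),
    )
    u = _cone_direction(away, 10.0, rng)
    n3 = target + d_nc * u

    w = (target - n3) / np.linalg.norm(target - n3)
    p = _cone_direction(w, 90.0, rng)  # any direction; orthogonalize below
    p = p - np.dot(p, w) * w
    norm = np.linalg.norm(p)
    if norm < 1e-8:  # pathological draw, use a deterministic perpendicular
        p = np.cross(w, np.array([0.0, 0.0, 1.0]))
        norm = np.linalg.norm(p)
    p /= norm
    theta = np.deg2rad(theta_deg)
    v = np.cos(theta) * w + np.sin(theta) * p
    n2 = n3 + _NN_BOND * v
    n1 = n2 + _NN_BOND * v

    s = _cone_direction(np.array([0.0, 0.0, 1.0]), 15.0, rng)
    oh = o1 + d_oy * s
    ca = oh + 1.4 * s

    pose = np.stack([ca, oh, c1, c2, o1, n1, n2, n3])
    rot = _random_rotation(rng)
    shift = rng.uniform(-20.0, 20.0, size=3)
    return pose @ rot.T + shift


def gen_pose_frames(cfg: PoseSimConfig) -> tuple[Trajectory, np.ndarray]:
    """Generate pose frames with known competence classes.

    Returns (trajectory, labels) with labels in {"proS", "proR",
    "noncompetent"}. pro-S frames satisfy d(O1-OH) < 4 A, d(N3-C1) < 4 A and
    80 <= angle(N2-N3-C1) <= 120 deg while failing the pro-R criteria (the
    azide sits anti to C2); pro-R frames are the mirror case; noncompetent
    frames violate at least one criterion of both classes.
    """
    rng = np.random.default_rng(cfg.seed)
    classes = rng.choice(
        3,
        size=cfg.n_frames,
        p=[cfg.frac_proS, cfg.frac_proR, cfg.frac_noncompetent],
    )
    coords = np.empty((cfg.n_frames, len(_POSE_ENTRIES), 3))
    for i, cls in enumerate(classes):
        if cls in (0, 1):
            d_oy = rng.uniform(2.6, 3.95)
            d_nc = rng.uniform(2.7, 3.95)
            theta = rng.uniform(80.05, 119.95)
            coords[i] = _build_pose(cls == 0, d_oy, d_nc, theta, rng)
        else:
            # choose which criterion to break; keep others in range
            attack_c1 = bool(rng.integers(2))
            mode = rng.integers(4)
            d_oy = rng.uniform(2.6, 3.95)
            d_nc = rng.uniform(2.7, 3.95)
            theta = rng.uniform(80.05, 119.95)
            if mode == 0:
                d_oy = rng.uniform(4.05, 6.0)
            elif mode == 1:
                d_nc = rng.uniform(4.05, 6.0)
            elif mode == 2:
                theta = rng.uniform(125.0, 170.0) if rng.integers(2) else rng.uniform(20.0, 75.0)
            else:
                d_nc = rng.uniform(4.05, 6.0)
                theta = rng.uniform(125.0, 170.0)
            coords[i] = _build_pose(attack_c1, d_oy, d_nc, theta, rng)
    labels = np.array(["proS", "proR", "noncompetent"])[classes]
    traj = Trajectory(
        make_topology(_POSE_ENTRIES),
        coords,
        metadata={
            "generator": "gen_pose_frames",
            "frac_proS": cfg.frac_proS,
            "frac_proR": cfg.frac_proR,
            "frac_noncompetent": cfg.frac_noncompetent,
            "seed": cfg.seed,
        },
    )
    return traj, labels


# ---------------------------------------------------------------------------
# Kinetics and screening tables
# ---------------------------------------------------------------------------

def gen_hill_dataset(cfg: KineticSimConfig) -> RateDataset:
    """Noisy rates on a Hill curve: rate = v(S) * (1 + eps), eps ~ N(0, cv)."""
    rng = np.random.default_rng(cfg.seed)
    conc = np.repeat(np.asarray(cfg.concentrations, dtype=float), cfg.replicates)
    replicate = np.tile(np.arange(cfg.replicates), len(cfg.concentrations))
    clean = hill_rate(conc, cfg.true_params)
    eps = rng.normal(0.0, cfg.noise_cv, size=conc.size) if cfg.noise_cv > 0 else 0.0
    rates = clean * (1.0 + eps)
    return RateDataset(
        concentrations_mM=conc,
        rates_per_s=rates,
        replicate=replicate,
        species=cfg.species,
        fixed_cosubstrate_mM=cfg.fixed_cosubstrate_mM,
    )


def gen_screen_table(cfg: ScreenSimConfig) -> pd.DataFrame:
    """Noisy screening plate: columns (variant, conversion, eeP), clamped."""
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for name, conv, eep in cfg.variants:
        if cfg.noise_sd > 0:
            conv = conv + rng.normal(0.0, cfg.noise_sd)
            eep = eep + rng.normal(0.0, cfg.noise_sd)
        rows.append(
            {
                "variant": name,
                "conversion": float(np.clip(conv, 0.0, 1.0)),
                "eeP": float(np.clip(eep, -1.0, 1.0)),
            }
        )
    return pd.DataFrame(rows, columns=["variant", "conversion", "eeP"])
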