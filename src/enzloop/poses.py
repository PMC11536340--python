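"""Near-attack-conformation filtering of active-site poses.

A trajectory frame counts as a catalytically competent pose for the azide
ring-opening of the epoxide when (i) the epoxide oxygen sits within 4 A of
the catalytic tyrosine hydroxyl (oxyanion stabilization), (ii) the azide's
terminal nitrogen sits within 4 A of the attacked epoxide carbon, and (iii)
the N-N-C attack angle lies in 80-120 degrees. Attack at C1 leads to the
(S)-configured product (pro-S); attack at C2 is the pro-R channel. Distances
are compared strictly (< 4 A); angle bounds are inclusive.

Quantum-chemical reference geometries anchor the thresholds: the attack
distance at the transition state is ~2.2 A at an N-N-C angle of ~109 deg, and
~3.2 A / 85 deg in the reactant complex — both classify as competent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .structure import Frame, Trajectory, measure

__all__ = [
    "PoseCriteria",
    "PoseGeometry",
    "PoseClass",
    "CompetenceSummary",
    "TS_REFERENCE_GEOMETRY",
    "REACTANT_REFERENCE_GEOMETRY",
    "ATOM_ROLES",
    "resolve_atom_map",
    "extract_pose_geometry",
    "classify_frame",
    "summarize_competence",
]

#: Attack distance (A) and N-N-C angle (deg) at the transition state.
TS_REFERENCE_GEOMETRY = (2.2, 109.0)
#: Attack distance (A) and N-N-C angle (deg) in the reactant complex.
REACTANT_REFERENCE_GEOMETRY = (3.2, 85.0)

#: Atom roles the geometry extraction needs, with the default
#: (residue_name, atom_name) convention used to resolve them.
ATOM_ROLES = {
    "O1": ("CHO", "O1"),  # epoxide oxygen
    "C1": ("CHO", "C1"),  # epoxide carbon, pro-S attack site
    "C2": ("CHO", "C2"),  # epoxide carbon, pro-R attack site
    "N2": ("AZI", "N2"),  # azide middle nitrogen (defines the azide axis)
    "N3": ("AZI", "N3"),  # azide terminal (attacking) nitrogen
    "OH": ("TYR", "OH"),  # catalytic tyrosine hydroxyl oxygen
}


@dataclass(frozen=True)
class PoseCriteria:
    """Geometric competence thresholds.

    Distances use a strict ``<`` comparison; the angle window is inclusive at
    both ends.
    """

    max_dist_OY: float = 4.0
    max_dist_NC: float = 4.0
    angle_range: tuple[float, float] = (80.0, 120.0)

    def __post_init__(self) -> None:
        if self.max_dist_OY <= 0 or self.max_dist_NC <= 0:
            raise ValueError("distance thresholds must be > 0")
        lo, hi = self.angle_range
        if not 0 <= lo < hi <= 180:
            raise ValueError("angle_range must satisfy 0 <= lo < hi <= 180")


@dataclass(frozen=True)
class PoseGeometry:
    """The five measurements the competence criteria are evaluated on."""

    d_OY: float
    d_N_C1: float
    d_N_C2: float
    ang_NNC1: float
    ang_NNC2: float

    def __post_init__(self) -> None:
        if min(self.d_OY, self.d_N_C1, self.d_N_C2) <= 0:
            raise ValueError("distances must be > 0")
        for a in (self.ang_NNC1, self.ang_NNC2):
            if not 0.0 <= a <= 180.0:
                raise ValueError(f"angle {a} outside [0, 180]")


class PoseClass(NamedTuple):
    proS: bool
    proR: bool


@dataclass(frozen=True)
class CompetenceSummary:
    """Fractions of competent frames with bootstrap confidence intervals."""

    n_frames: int
    frac_proS: float
    frac_proR: float
    frac_any: float
    proS_to_proR_ratio: Optional[float]
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    per_frame: Optional[pd.DataFrame] = None

    def summary(self) -> str:
        def _ci(key: str) -> str:
            lo, hi = self.ci95.get(key, (float("nan"), float("nan")))
            return f"[{lo:.4f}, {hi:.4f}]"

        ratio = (
            f"{self.proS_to_proR_ratio:.3f}"
            if self.proS_to_proR_ratio is not None
            else "undefined (no pro-R frames)"
        )
        return "\n".join(
            [
                "Catalytic competence summary",
                "=" * 48,
                f"frames            {self.n_frames}",
                f"pro-S fraction    {self.frac_proS:.4f}  CI95 {_ci('proS')}",
                f"pro-R fraction    {self.frac_proR:.4f}  CI95 {_ci('proR')}",
                f"any competent     {self.frac_any:.4f}  CI95 {_ci('any')}",
                f"pro-S : pro-R     {ratio}",
                "=" * 48,
            ]
        )

    def write_frames_tsv(self, path) -> None:
        if self.per_frame is None:
            raise ValueError("per-frame table not retained")
        self.per_frame.to_csv(path, sep="\t", index=False)


def resolve_atom_map(
    traj: Trajectory, overrides: dict[str, tuple[str, str]] | None = None
) -> dict[str, int]:
    """Map atom roles (O1, C1, C2, N2, N3, OH) to atom indices.

    The default convention (epoxide CHO: C1/C2/O1, azide AZI: N1/N2/N3 with
    N3 terminal/attacking, tyrosine hydroxyl OH) can be overridden per role
    with ``{"role": (residue_name, atom_name)}``.
    """
    spec = dict(ATOM_ROLES)
    if overrides:
        spec.update(overrides)
    amap: dict[str, int] = {}
    for role, (resname, name) in spec.items():
        hits = [
            i
            for i, m in enumerate(traj.topology)
            if m.residue_name == resname and m.name == name
        ]
        if not hits:
            raise KeyError(
                f"atom for role {role!r} ({resname}/{name}) not found in topology"
            )
        amap[role] = hits[0]
    return amap


def extract_pose_geometry(frame: Frame, atom_map: dict[str, int]) -> PoseGeometry:
    """Measure the five competence observables of one frame."""
    for role in ("O1", "C1", "C2", "N2", "N3", "OH"):
        if role not in atom_map:
            raise KeyError(f"atom_map is missing the {role!r} role")
    a = atom_map
    return PoseGeometry(
        d_OY=measure(frame, "distance", (a["O1"], a["OH"])),
        d_N_C1=measure(frame, "distance", (a["N3"], a["C1"])),
        d_N_C2=measure(frame, "distance", (a["N3"], a["C2"])),
        ang_NNC1=measure(frame, "angle", (a["N2"], a["N3"], a["C1"])),
        ang_NNC2=measure(frame, "angle", (a["N2"], a["N3"], a["C2"])),
    )


def classify_frame(
    geom: PoseGeometry, criteria: PoseCriteria | None = None
) -> PoseClass:
    """Evaluate the pro-S and pro-R competence criteria independently.

    A frame may satisfy both; dual-satisfying frames are counted in both
    classes by the summary (an exclusive assignment, when wanted, can pick
    the nearer carbon from the geometry).
    """
    c = criteria or PoseCriteria()
    lo, hi = c.angle_range
    pro_s = (
        geom.d_OY < c.max_dist_OY
        and geom.d_N_C1 < c.max_dist_NC
        and lo <= geom.ang_NNC1 <= hi
    )
    pro_r = (
        geom.d_OY < c.max_dist_OY
        and geom.d_N_C2 < c.max_dist_NC
        and lo <= geom.ang_NNC2 <= hi
    )
    return PoseClass(proS=pro_s, proR=pro_r)


def summarize_competence(
    traj: Trajectory,
    atom_map: dict[str, int] | None = None,
    criteria: PoseCriteria | None = None,
    n_bootstrap: int = 1000,
    seed: int = 0,
    exclusive: bool = False,
    keep_per_frame: bool = True,
) -> CompetenceSummary:
    """Classify every frame and report competent-pose fractions.

    Fractions are taken over all frames; the 95% confidence intervals are
    percentile bootstrap over frames with the given seed. With
    ``exclusive=True``, a frame satisfying both channels is assigned to the
    one with the shorter attack distance.
    """
    if n_bootstrap < 100:
        warnings.warn(
            f"n_bootstrap={n_bootstrap} is small; confidence intervals will "
            "be unstable",
            stacklevel=2,
        )
    amap = atom_map or resolve_atom_map(traj)
    crit = criteria or PoseCriteria()

    rows = []
    pro_s = np.zeros(traj.n_frames, dtype=bool)
    pro_r = np.zeros(traj.n_frames, dtype=bool)
    for i, frame in enumerate(traj):
        g = extract_pose_geometry(frame, amap)
        cls = classify_frame(g, crit)
        s, r = cls.proS, cls.proR
        if exclusive and s and r:
            if g.d_N_C1 <= g.d_N_C2:
                r = False
            else:
                s = False
        pro_s[i], pro_r[i] = s, r
        if keep_per_frame:
            rows.append(
                {
                    "replica": traj.replica_id,
                    "frame": i,
                    "d_OY": g.d_OY,
                    "d_N_C1": g.d_N_C1,
                    "ang_NNC1": g.ang_NNC1,
                    "d_N_C2": g.d_N_C2,
                    "ang_NNC2": g.ang_NNC2,
                    "proS": s,
                    "proR": r,
                }
            )

    any_c = pro_s | pro_r
    n = traj.n_frames
    frac_s = float(pro_s.mean())
    frac_r = float(pro_r.mean())
    ratio = frac_s / frac_r if frac_r > 0 else None

    rng = np.random.default_rng(seed)
    boot = {"proS": [], "proR": [], "any": []}
    for _ in range(n_bootstrap):
        take = rng.integers(0, n, size=n)
        boot["proS"].append(pro_s[take].mean())
        boot["proR"].append(pro_r[take].mean())
        boot["any"].append(any_c[take].mean())
    ci95 = {
        k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        for k, v in boot.items()
    }
    return CompetenceSummary(
        n_frames=n,
        frac_proS=frac_s,
        frac_proR=frac_r,
        frac_any=float(any_c.mean()),
        proS_to_proR_ratio=ratio,
        ci95=ci95,
        per_frame=pd.DataFrame(rows) if keep_per_frame else None,
    )
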