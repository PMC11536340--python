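"""Loop-conformation free-energy landscapes from pairwise-distance PCA.

Workflow: featurize each frame as the pairwise distances between the flexible
loop's heavy atoms and a reference atom set on the rest of the protein,
project by PCA onto the two leading components, histogram the projection, and
convert bin populations into free energies

    dG(bin) = -kT * ln(count / count_max),   kT = 0.0019872 kcal/mol/K * T

so the most populated bin sits at 0 by construction. Conformational states
are the persistent minima of this surface; frames are assigned to the nearest
minimum and per-state populations are reported with a bootstrap standard
error.

:class:`LoopLandscapeModel` wraps the full pipeline statsmodels-style; the
stage functions (:func:`featurize_loop_contacts`, :func:`pca_project`,
:func:`estimate_fel`, :func:`assign_states`) remain usable on their own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .structure import Selection, Trajectory, select_atoms

__all__ = [
    "FeatureMatrix",
    "Projection",
    "FreeEnergySurface",
    "StateAssignment",
    "LoopLandscapeModel",
    "LoopLandscapeResults",
    "featurize_loop_contacts",
    "pca_project",
    "estimate_fel",
    "assign_states",
    "BOLTZMANN_KCAL",
]

logger = logging.getLogger(__name__)

#: Boltzmann constant in kcal/mol/K.
BOLTZMANN_KCAL = 0.0019872


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-frame loop-contact distances: (n_frames, n_pairs) in Angstrom."""

    values: np.ndarray
    pair_labels: tuple[tuple[int, int], ...]
    frame_provenance: tuple[tuple[int, int], ...]  # (replica_id, frame_index)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"d_{i}_{j}" for i, j in self.pair_labels]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "replica", [p[0] for p in self.frame_provenance])
        df.insert(1, "frame", [p[1] for p in self.frame_provenance])
        return df


@dataclass(frozen=True)
class Projection:
    """Two leading principal components of the feature matrix."""

    coordinates: np.ndarray  # (n_frames, 2)
    explained_variance_fraction: np.ndarray  # (2,)
    component_loadings: np.ndarray  # (2, n_pairs); dropped columns carry 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coordinates, columns=["PC1", "PC2"])


@dataclass(frozen=True)
class Minimum:
    pc1: float
    pc2: float
    dG: float
    label: str


@dataclass(frozen=True)
class FreeEnergySurface:
    """Gridded dG over (PC1, PC2); unsampled bins are NaN, never 0."""

    grid: np.ndarray  # (n_bins, n_bins) dG in kcal/mol, NaN = unsampled
    counts: np.ndarray
    bin_edges: tuple[np.ndarray, np.ndarray]
    temperature: float
    kT: float
    minima: tuple[Minimum, ...]

    def to_frame(self) -> pd.DataFrame:
        e1, e2 = self.bin_edges
        c1 = 0.5 * (e1[:-1] + e1[1:])
        c2 = 0.5 * (e2[:-1] + e2[1:])
        g1, g2 = np.meshgrid(c1, c2, indexing="ij")
        return pd.DataFrame(
            {
                "PC1_center": g1.ravel(),
                "PC2_center": g2.ravel(),
                "dG_kcal_mol": self.grid.ravel(),
                "count": self.counts.ravel().astype(int),
            }
        )


@dataclass(frozen=True)
class StateAssignment:
    """Per-frame state labels and per-state populations (+ bootstrap SE)."""

    labels: np.ndarray
    populations: dict[str, float]
    method: str
    bootstrap_se: dict[str, float]


# ---------------------------------------------------------------------------
# Stage functions
# ---------------------------------------------------------------------------

def featurize_loop_contacts(
    traj: Trajectory | Sequence[Trajectory],
    loop_sel: Selection,
    reference_sel: Selection,
    chunk: int = 2048,
) -> FeatureMatrix:
    """Distances between every loop atom and every reference atom, per frame.

    Accepts one trajectory or a list of replicas sharing a topology (frames
    are pooled; provenance records the replica id of each row). Selections
    must be non-empty and disjoint.
    """
    trajs = [traj] if isinstance(traj, Trajectory) else list(traj)
    li = np.asarray(loop_sel.resolved_indices, dtype=int)
    ri = np.asarray(reference_sel.resolved_indices, dtype=int)
    if li.size == 0 or ri.size == 0:
        raise ValueError("loop and reference selections must be non-empty")
    if set(li) & set(ri):
        raise ValueError("loop and reference selections must be disjoint")

    blocks: list[np.ndarray] = []
    prov: list[tuple[int, int]] = []
    for t in trajs:
        if t.n_atoms != trajs[0].n_atoms:
            raise ValueError("all pooled trajectories must share a topology")
        coords = t.coordinates
        for s in range(0, t.n_frames, chunk):
            c = coords[s : s + chunk]
            diff = c[:, li, None, :] - c[:, None, ri, :]
            d = np.sqrt(np.einsum("fijk,fijk->fij", diff, diff))
            blocks.append(d.reshape(c.shape[0], -1))
        prov.extend((t.replica_id, f) for f in range(t.n_frames))
    values = np.vstack(blocks)
    pair_labels = tuple((int(i), int(j)) for i in li for j in ri)
    return FeatureMatrix(values=values, pair_labels=pair_labels,
                         frame_provenance=tuple(prov))


def pca_project(
    features: FeatureMatrix, center: bool = True, scale: bool = True
) -> Projection:
    """Project the feature matrix onto its two leading principal components.

    Features are centered and z-scored by default; zero-variance columns are
    dropped with a logged warning. The component sign is fixed so the loading
    of largest magnitude on each component is positive, making projections
    deterministic across runs.
    """
    X = np.asarray(features.values, dtype=float)
    if X.shape[0] <= 2:
        raise ValueError("PCA needs more frames than components (2)")
    std = X.std(axis=0, ddof=0)
    # constant columns have std ~1e-16 from rounding, which would explode
    # under z-scoring; treat anything below a relative floor as zero-variance
    keep = std > 1e-10 * max(1.0, float(std.max(initial=0.0)))
    if not np.all(keep):
        logger.warning(
            "dropping %d zero-variance feature column(s) before PCA",
            int(np.sum(~keep)),
        )
    Xk = X[:, keep]
    if center:
        Xk = Xk - Xk.mean(axis=0)
    if scale:
        Xk = Xk / std[keep]
    pca = PCA(n_components=2, svd_solver="covariance_eigh")
    coords = pca.fit_transform(Xk)
    comps = pca.components_.copy()
    for c in range(2):
        imax = int(np.argmax(np.abs(comps[c])))
        if comps[c, imax] < 0:
            comps[c] = -comps[c]
            coords[:, c] = -coords[:, c]
    loadings = np.zeros((2, X.shape[1]))
    loadings[:, keep] = comps
    return Projection(
        coordinates=coords,
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
        component_loadings=loadings,
    )


def _persistent_minima(
    values: np.ndarray, occupied: np.ndarray, min_prominence: float
) -> list[tuple[int, int]]:
    """Locate basin minima on a grid by topographic persistence.

    Flood the grid from low to high; unsampled cells enter at a ceiling just
    above the highest occupied value, so disconnected occupied patches still
    merge through them. A basin whose depth below its merge saddle is less
    than ``min_prominence`` is absorbed; the global minimum always survives.
    """
    ceiling = float(np.nanmax(np.where(occupied, values, np.nan))) + 1e-9
    work = np.where(occupied, values, ceiling)
    nb, mb = work.shape
    order = np.argsort(work, axis=None, kind="stable")
    parent = {}
    birth: dict[int, float] = {}
    seed: dict[int, tuple[int, int]] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    confirmed: list[tuple[int, int]] = []
    processed = np.zeros_like(work, dtype=bool)
    for flat in order:
        i, j = divmod(int(flat), mb)
        val = work[i, j]
        roots = set()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                ii, jj = i + di, j + dj
                if 0 <= ii < nb and 0 <= jj < mb and processed[ii, jj]:
                    roots.add(find(ii * mb + jj))
        processed[i, j] = True
        me = int(flat)
        if not roots:
            parent[me] = me
            birth[me] = val
            seed[me] = (i, j)
            continue
        deepest = min(roots, key=lambda r: (birth[r], r))
        parent[me] = deepest
        for r in roots:
            if r == deepest:
                continue
            pers = val - birth[r]
            si, sj = seed[r]
            if pers >= min_prominence and occupied[si, sj]:
                confirmed.append((si, sj))
            parent[r] = deepest
    # surviving root = global minimum
    root = find(int(order[0]))
    si, sj = seed[root]
    if occupied[si, sj]:
        confirmed.append((si, sj))
    return confirmed


def estimate_fel(
    proj: Projection,
    n_bins: int = 60,
    temperature: float = 300.0,
    smoothing_sigma: float = 0.0,
    min_prominence: float = 1.0,
    pad_fraction: float = 0.05,
) -> FreeEnergySurface:
    """Histogram the projection and convert populations to free energies.

    Bins span the data range padded by ``pad_fraction`` per side. Minima are
    detected by topographic persistence with threshold ``min_prominence``
    (kcal/mol); set ``smoothing_sigma`` (in bins) to Gaussian-smooth the
    histogram for detection only — the reported grid is always unsmoothed.
    """
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    xy = proj.coordinates
    edges = []
    for d in range(2):
        lo, hi = float(xy[:, d].min()), float(xy[:, d].max())
        span = hi - lo
        if span == 0.0:
            lo, hi = lo - 0.5, hi + 0.5
        else:
            lo, hi = lo - pad_fraction * span, hi + pad_fraction * span
        edges.append(np.linspace(lo, hi, n_bins + 1))
    counts, e1, e2 = np.histogram2d(xy[:, 0], xy[:, 1], bins=edges)
    kT = BOLTZMANN_KCAL * temperature
    occupied = counts > 0
    grid = np.full_like(counts, np.nan)
    cmax = counts.max()
    grid[occupied] = -kT * np.log(counts[occupied] / cmax) + 0.0  # kill -0.0

    if smoothing_sigma > 0:
        from scipy.ndimage import gaussian_filter

        sm = gaussian_filter(counts, sigma=smoothing_sigma)
        det_occ = sm > 0
        det = np.full_like(sm, np.nan)
        det[det_occ] = -kT * np.log(sm[det_occ] / sm.max())
    else:
        det, det_occ = grid, occupied

    cells = _persistent_minima(det, det_occ, min_prominence)
    # keep only occupied cells on the raw grid, report raw dG
    c1 = 0.5 * (e1[:-1] + e1[1:])
    c2 = 0.5 * (e2[:-1] + e2[1:])
    raw = []
    for (i, j) in cells:
        if occupied[i, j]:
            raw.append((float(grid[i, j]), float(c1[i]), float(c2[j])))
    raw.sort()
    minima = tuple(
        Minimum(pc1=p1, pc2=p2, dG=g, label=f"S{k}")
        for k, (g, p1, p2) in enumerate(raw)
    )
    return FreeEnergySurface(
        grid=grid,
        counts=counts,
        bin_edges=(e1, e2),
        temperature=temperature,
        kT=kT,
        minima=minima,
    )


def assign_states(
    proj: Projection,
    fel: FreeEnergySurface,
    method: str = "nearest_minimum",
    n_bootstrap: int = 200,
    seed: int = 0,
) -> StateAssignment:
    """Assign each frame to a conformational state and report populations.

    ``nearest_minimum`` assigns frames to the closest surface minimum in PC
    space; ``two_means`` runs a seeded 2-means clustering instead. The
    population standard errors come from a percentile-free bootstrap over
    frames (std of resampled populations).
    """
    xy = proj.coordinates
    if method == "nearest_minimum":
        if not fel.minima:
            raise ValueError("the surface has no minima to assign frames to")
        centers = np.array([[m.pc1, m.pc2] for m in fel.minima])
        names = [m.label for m in fel.minima]
        d2 = ((xy[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        idx = np.argmin(d2, axis=1)
        labels = np.array(names, dtype=object)[idx].astype(str)
    elif method == "two_means":
        if xy.shape[0] < 2:
            raise ValueError("two_means requires at least 2 frames")
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=2, n_init=10, random_state=seed)
        raw = km.fit_predict(xy)
        # name clusters by population, largest first
        counts = np.bincount(raw, minlength=2)
        order = np.argsort(-counts)
        remap = {int(order[k]): f"S{k}" for k in range(2)}
        labels = np.array([remap[int(r)] for r in raw])
        names = sorted(set(labels))
    else:
        raise ValueError(f"unknown method {method!r}")

    n = labels.size
    populations = {s: float(np.mean(labels == s)) for s in names}
    rng = np.random.default_rng(seed)
    boot = {s: np.empty(n_bootstrap) for s in names}
    for b in range(n_bootstrap):
        take = rng.integers(0, n, size=n)
        lb = labels[take]
        for s in names:
            boot[s][b] = np.mean(lb == s)
    se = {s: float(np.std(boot[s], ddof=1)) for s in names}
    return StateAssignment(
        labels=labels, populations=populations, method=method, bootstrap_se=se
    )


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class LoopLandscapeModel:
    """Free-energy-landscape pipeline bound to one or more trajectories.

    Parameters
    ----------
    traj
        A trajectory or a list of replica trajectories (pooled).
    loop, reference
        Selection expressions for the flexible loop's heavy atoms and the
        reference atoms on the rest of the protein. The default reference is
        one Calpha per non-loop residue, the reduced feature set; pass a
        heavy-atom expression for the full mode.
    center, scale
        Feature standardization before PCA (both on by default).
    """

    def __init__(
        self,
        traj: Trajectory | Sequence[Trajectory],
        loop: str = "resid 39-47 and not element H",
        reference: str = "name CA and not resid 39-47",
        center: bool = True,
        scale: bool = True,
    ) -> None:
        self.trajectories = [traj] if isinstance(traj, Trajectory) else list(traj)
        if not self.trajectories:
            raise ValueError("need at least one trajectory")
        self.loop_sel = select_atoms(self.trajectories[0], loop)
        self.reference_sel = select_atoms(self.trajectories[0], reference)
        self.center = center
        self.scale = scale

    def fit(
        self,
        n_bins: int = 60,
        temperature: float = 300.0,
        smoothing_sigma: float = 0.0,
        min_prominence: float = 1.0,
        method: str = "nearest_minimum",
        n_bootstrap: int = 200,
        seed: int = 0,
    ) -> "LoopLandscapeResults":
        features = featurize_loop_contacts(
            self.trajectories, self.loop_sel, self.reference_sel
        )
        projection = pca_project(features, center=self.center, scale=self.scale)
        surface = estimate_fel(
            projection,
            n_bins=n_bins,
            temperature=temperature,
            smoothing_sigma=smoothing_sigma,
            min_prominence=min_prominence,
        )
        states = assign_states(
            projection, surface, method=method, n_bootstrap=n_bootstrap, seed=seed
        )
        return LoopLandscapeResults(
            model=self,
            features=features,
            projection=projection,
            surface=surface,
            states=states,
        )


@dataclass(frozen=True)
class LoopLandscapeResults:
    """Fitted landscape: features, projection, surface, state assignment."""

    model: LoopLandscapeModel
    features: FeatureMatrix
    projection: Projection
    surface: FreeEnergySurface
    states: StateAssignment

    @property
    def populations(self) -> dict[str, float]:
        return self.states.populations

    def summary(self) -> str:
        evf = self.projection.explained_variance_fraction
        lines = [
            "Loop free-energy landscape",
            "=" * 50,
            f"frames              {self.features.n_frames}",
            f"feature pairs       {len(self.features.pair_labels)}",
            f"explained variance  PC1 {evf[0]:.3f}  PC2 {evf[1]:.3f}",
            f"temperature (K)     {self.surface.temperature:g}",
            f"minima              {len(self.surface.minima)}",
            "-" * 50,
        ]
        for m in self.surface.minima:
            pop = self.states.populations.get(m.label, float("nan"))
            se = self.states.bootstrap_se.get(m.label, float("nan"))
            lines.append(
                f"{m.label}: dG {m.dG:6.3f} kcal/mol at "
                f"({m.pc1:+.2f}, {m.pc2:+.2f})  population "
                f"{pop:.3f} +/- {se:.3f}"
            )
        lines.append("=" * 50)
        return "\n".join(lines)

    def write_features(self, path) -> None:
        self.features.to_frame().to_csv(path, sep="\t", index=False)

    def write_projection(self, path) -> None:
        self.projection.to_frame().to_csv(path, sep="\t", index=False)

    def write_surface(self, path) -> None:
        self.surface.to_frame().to_csv(path, sep="\t", index=False)

    def write_states(self, path) -> None:
        df = pd.DataFrame(
            {
                "replica": [p[0] for p in self.features.frame_provenance],
                "frame": [p[1] for p in self.features.frame_provenance],
                "state": self.states.labels,
            }
        )
        df.to_csv(path, sep="\t", index=False)

    def plot_surface(self, ax=None):
        """Filled-contour rendering of the free-energy surface."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        e1, e2 = self.surface.bin_edges
        c1 = 0.5 * (e1[:-1] + e1[1:])
        c2 = 0.5 * (e2[:-1] + e2[1:])
        ax.contourf(c1, c2, self.surface.grid.T, levels=20, cmap="jet_r")
        for m in self.surface.minima:
            ax.plot(m.pc1, m.pc2, "k*", markersize=10)
            ax.annotate(m.label, (m.pc1, m.pc2))
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        return ax
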