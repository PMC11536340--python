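"""Multi-frame structure I/O, atom selection and geometry primitives.

The in-memory model is deliberately lightweight: a :class:`Trajectory` holds a
single shared topology (per-atom metadata) plus a dense ``(n_frames, n_atoms, 3)``
coordinate array in Angstrom, and :class:`Frame` objects are thin views into it.
Supported on-disk dialects are multi-MODEL PDB (fixed columns, MODEL/ENDMDL
records) and plain XYZ (count line, comment line, ``element x y z``).

Residue numbering is 1-based as printed in PDB files; selection ranges are
inclusive; coordinates are Angstrom everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "Selection",
    "StructureError",
    "StructureParseError",
    "SelectionSyntaxError",
    "read_frames",
    "write_frames",
    "select_atoms",
    "measure",
]

# Standard amino-acid residue names -> written as ATOM records; everything else
# (ligands such as CHO/AZI) as HETATM.
_AMINO3 = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP "
    "TYR VAL".split()
)


class StructureError(Exception):
    """Base error for structure I/O and geometry."""


class StructureParseError(StructureError):
    """A file could not be parsed; carries the offending line number."""


class SelectionSyntaxError(StructureError):
    """A selection expression is malformed."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of one frame, with PDB-style identity and a position in A."""

    serial: int
    name: str
    residue_name: str
    chain: str
    residue_id: int
    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        if self.residue_id < 1:
            raise ValueError(f"residue_id must be >= 1, got {self.residue_id}")
        if not self.element:
            raise ValueError("element must be non-empty")


@dataclass(frozen=True)
class _AtomMeta:
    """Per-atom metadata shared by all frames of a trajectory."""

    serial: int
    name: str
    residue_name: str
    chain: str
    residue_id: int
    element: str


def infer_element(name: str) -> str:
    """Infer an element symbol from a PDB atom name (leniency for blank columns).

    Leading digits are stripped; a remaining leading ``H`` means hydrogen,
    otherwise the first letter is taken (``CA`` -> C, ``OH`` -> O, ``N3`` -> N).
    """
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    if stripped[0].upper() == "H":
        return "H"
    return stripped[0].upper()


class Frame:
    """A single coordinate frame: shared topology + an ``(n_atoms, 3)`` view."""

    __slots__ = ("_topology", "coordinates", "frame_index")

    def __init__(
        self,
        topology: Sequence[_AtomMeta],
        coordinates: np.ndarray,
        frame_index: int = 0,
    ) -> None:
        coordinates = np.asarray(coordinates, dtype=float)
        if coordinates.shape != (len(topology), 3):
            raise ValueError(
                f"coordinates shape {coordinates.shape} does not match "
                f"{len(topology)} atoms"
            )
        if frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        self._topology = tuple(topology)
        self.coordinates = coordinates
        self.frame_index = frame_index

    @property
    def n_atoms(self) -> int:
        return len(self._topology)

    @property
    def topology(self) -> tuple[_AtomMeta, ...]:
        return self._topology

    @property
    def atoms(self) -> list[AtomRecord]:
        """Materialize full atom records (metadata + current positions)."""
        return [
            AtomRecord(
                serial=m.serial,
                name=m.name,
                residue_name=m.residue_name,
                chain=m.chain,
                residue_id=m.residue_id,
                element=m.element,
                position=self.coordinates[i].copy(),
            )
            for i, m in enumerate(self._topology)
        ]


class Trajectory:
    """An ordered stack of frames over one topology.

    Parameters
    ----------
    topology
        Per-atom metadata, identical for every frame.
    coordinates
        Array of shape ``(n_frames, n_atoms, 3)`` in Angstrom.
    replica_id
        Bookkeeping index for independent replicas (>= 0).
    metadata
        Free-form key/value annotations (e.g. generator ground truth).
    """

    def __init__(
        self,
        topology: Sequence[_AtomMeta],
        coordinates: np.ndarray,
        replica_id: int = 0,
        metadata: dict | None = None,
    ) -> None:
        coordinates = np.asarray(coordinates, dtype=float)
        if coordinates.ndim != 3 or coordinates.shape[0] < 1:
            raise ValueError("need at least one frame of (n_atoms, 3) coordinates")
        if coordinates.shape[1] != len(topology) or coordinates.shape[2] != 3:
            raise ValueError(
                f"coordinate array {coordinates.shape} inconsistent with "
                f"{len(topology)} atoms"
            )
        if replica_id < 0:
            raise ValueError("replica_id must be >= 0")
        serials = [m.serial for m in topology]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique within a frame")
        self.topology = tuple(topology)
        self.coordinates = coordinates
        self.replica_id = replica_id
        self.metadata = dict(metadata or {})

    def __len__(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_frames(self) -> int:
        return len(self)

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def frames(self) -> list[Frame]:
        return list(self)

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield Frame(self.topology, self.coordinates[i], frame_index=i)

    def __getitem__(self, i: int) -> Frame:
        return Frame(self.topology, self.coordinates[i], frame_index=i)

    def with_coordinates(self, coordinates: np.ndarray) -> "Trajectory":
        return Trajectory(
            self.topology, coordinates, replica_id=self.replica_id,
            metadata=dict(self.metadata),
        )


def make_topology(
    entries: Sequence[tuple[str, str, str, int]] | Sequence[_AtomMeta],
) -> tuple[_AtomMeta, ...]:
    """Build a topology from ``(name, residue_name, chain, residue_id)`` tuples.

    Serials are assigned 1..n in order; elements inferred from atom names.
    """
    metas: list[_AtomMeta] = []
    for i, e in enumerate(entries):
        if isinstance(e, _AtomMeta):
            metas.append(replace(e, serial=i + 1))
        else:
            name, resname, chain, resid = e
            metas.append(
                _AtomMeta(
                    serial=i + 1,
                    name=name,
                    residue_name=resname,
                    chain=chain,
                    residue_id=resid,
                    element=infer_element(name),
                )
            )
    return tuple(metas)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _parse_pdb(lines: list[str], path: str) -> tuple[tuple[_AtomMeta, ...], np.ndarray]:
    frames_meta: list[list[_AtomMeta]] = []
    frames_xyz: list[list[list[float]]] = []
    model_ids: list[int] = []
    cur_meta: list[_AtomMeta] | None = None
    cur_xyz: list[list[float]] | None = None
    cur_model = 0
    saw_model = False

    def _close() -> None:
        nonlocal cur_meta, cur_xyz
        if cur_meta is not None and cur_meta:
            frames_meta.append(cur_meta)
            frames_xyz.append(cur_xyz)  # type: ignore[arg-type]
            model_ids.append(cur_model)
        cur_meta, cur_xyz = None, None

    for lineno, line in enumerate(lines, start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            _close()
            saw_model = True
            try:
                cur_model = int(line[6:].split()[0])
            except (IndexError, ValueError):
                cur_model = len(frames_meta) + 1
            cur_meta, cur_xyz = [], []
        elif rec.startswith("ENDMDL"):
            _close()
        elif rec.startswith(("ATOM  ", "HETATM")):
            if cur_meta is None:
                if saw_model:
                    raise StructureParseError(
                        f"{path}: line {lineno}: ATOM record outside MODEL block"
                    )
                cur_meta, cur_xyz = [], []
                cur_model = 1
            try:
                serial = int(line[6:11])
                name = line[12:16].strip()
                resname = line[17:20].strip()
                chain = line[21].strip() or "A"
                resid = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except (ValueError, IndexError) as exc:
                raise StructureParseError(
                    f"{path}: line {lineno}: unparseable ATOM/HETATM record "
                    f"({exc})"
                ) from exc
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                element = infer_element(name)
            cur_meta.append(
                _AtomMeta(serial, name, resname, chain, resid, element.upper())
            )
            cur_xyz.append([x, y, z])  # type: ignore[union-attr]
    _close()

    if not frames_meta:
        raise StructureParseError(f"{path}: no ATOM/HETATM records found")

    n0 = len(frames_meta[0])
    for k, meta in enumerate(frames_meta):
        if len(meta) != n0:
            raise StructureParseError(
                f"{path}: frame {model_ids[k]} has {len(meta)} atoms, "
                f"expected {n0} (inconsistent atom count across frames)"
            )
    coords = np.asarray(frames_xyz, dtype=float)
    return tuple(frames_meta[0]), coords


def _parse_xyz(lines: list[str], path: str) -> tuple[tuple[_AtomMeta, ...], np.ndarray]:
    frames: list[list[list[float]]] = []
    elements0: list[str] | None = None
    i = 0
    block = 0
    n_lines = len(lines)
    while i < n_lines:
        if not lines[i].strip():
            i += 1
            continue
        block += 1
        try:
            n_atoms = int(lines[i].strip())
        except ValueError as exc:
            raise StructureParseError(
                f"{path}: line {i + 1}: expected atom count, got "
                f"{lines[i].strip()!r}"
            ) from exc
        if i + 1 + n_atoms >= n_lines + 1:
            raise StructureParseError(
                f"{path}: frame {block} truncated (expected {n_atoms} atoms)"
            )
        elems: list[str] = []
        xyz: list[list[float]] = []
        for j in range(n_atoms):
            lineno = i + 2 + j
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise StructureParseError(
                    f"{path}: line {lineno + 1}: expected 'element x y z'"
                )
            try:
                xyz.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError as exc:
                raise StructureParseError(
                    f"{path}: line {lineno + 1}: bad coordinate ({exc})"
                ) from exc
            elems.append(parts[0])
        if elements0 is None:
            elements0 = elems
        elif len(elems) != len(elements0):
            raise StructureParseError(
                f"{path}: frame {block} has {len(elems)} atoms, expected "
                f"{len(elements0)} (inconsistent atom count across frames)"
            )
        frames.append(xyz)
        i += 2 + n_atoms
    if not frames or elements0 is None:
        raise StructureParseError(f"{path}: no coordinate blocks found")
    topo = tuple(
        _AtomMeta(k + 1, el, "UNK", "A", 1, el.upper())
        for k, el in enumerate(elements0)
    )
    return topo, np.asarray(frames, dtype=float)


def read_frames(path, dialect: str = "pdb_models") -> Trajectory:
    """Read a multi-frame structure file into a :class:`Trajectory`.

    ``dialect`` is ``"pdb_models"`` (one frame per MODEL block; a MODEL-less
    file is a single frame) or ``"xyz"`` (one frame per block). Errors carry
    the offending line number; an atom-count mismatch names the frame.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if dialect == "pdb_models":
        topo, coords = _parse_pdb(lines, str(path))
    elif dialect == "xyz":
        topo, coords = _parse_xyz(lines, str(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return Trajectory(topo, coords)


def write_frames(traj: Trajectory, path, dialect: str = "pdb_models") -> None:
    """Write a trajectory as multi-MODEL PDB (3-decimal coords) or XYZ."""
    if traj.n_frames < 1:
        raise ValueError("cannot write an empty trajectory")
    with open(path, "w") as fh:
        if dialect == "pdb_models":
            for fi in range(traj.n_frames):
                fh.write(f"MODEL {fi + 1:8d}\n")
                for m, pos in zip(traj.topology, traj.coordinates[fi]):
                    rec = "ATOM  " if m.residue_name in _AMINO3 else "HETATM"
                    name = m.name if len(m.name) == 4 else f" {m.name:<3s}"
                    fh.write(
                        f"{rec}{m.serial:5d} {name:<4s} {m.residue_name:<3s} "
                        f"{m.chain:1s}{m.residue_id:4d}    "
                        f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
                        f"{1.00:6.2f}{0.00:6.2f}          {m.element:>2s}\n"
                    )
                fh.write("ENDMDL\n")
            fh.write("END\n")
        elif dialect == "xyz":
            for fi in range(traj.n_frames):
                fh.write(f"{traj.n_atoms}\n")
                fh.write(f"frame {fi}\n")
                for m, pos in zip(traj.topology, traj.coordinates[fi]):
                    fh.write(
                        f"{m.element:<2s} {pos[0]:14.6f} {pos[1]:14.6f} "
                        f"{pos[2]:14.6f}\n"
                    )
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Selection mini-language
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Selection:
    """A resolved atom selection: expression + sorted unique atom indices."""

    expression: str
    resolved_indices: tuple[int, ...]
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.resolved_indices)


def _predicate(tokens: list[str], pos: int, meta: tuple[_AtomMeta, ...]):
    """Parse one predicate; returns (mask, next_pos)."""
    if pos >= len(tokens):
        raise SelectionSyntaxError("unexpected end of selection expression")
    tok = tokens[pos]
    if tok == "not":
        mask, nxt = _predicate(tokens, pos + 1, meta)
        return ~mask, nxt
    if tok == "resid":
        if pos + 1 >= len(tokens):
            raise SelectionSyntaxError("'resid' requires an argument")
        arg = tokens[pos + 1]
        try:
            if "-" in arg[1:]:  # allow negative? resids are >= 1, split on dash
                lo_s, hi_s = arg.split("-", 1)
                lo, hi = int(lo_s), int(hi_s)
            else:
                lo = hi = int(arg)
        except ValueError as exc:
            raise SelectionSyntaxError(f"bad resid range {arg!r}") from exc
        mask = np.array([lo <= m.residue_id <= hi for m in meta])
        return mask, pos + 2
    if tok == "name":
        if pos + 1 >= len(tokens):
            raise SelectionSyntaxError("'name' requires an argument")
        arg = tokens[pos + 1]
        mask = np.array([m.name == arg for m in meta])
        return mask, pos + 2
    if tok == "element":
        if pos + 1 >= len(tokens):
            raise SelectionSyntaxError("'element' requires an argument")
        arg = tokens[pos + 1].upper()
        mask = np.array([m.element.upper() == arg for m in meta])
        return mask, pos + 2
    if tok == "resname":
        if pos + 1 >= len(tokens):
            raise SelectionSyntaxError("'resname' requires an argument")
        arg = tokens[pos + 1]
        mask = np.array([m.residue_name == arg for m in meta])
        return mask, pos + 2
    raise SelectionSyntaxError(f"unknown selection keyword {tok!r}")


def select_atoms(traj: Trajectory, expression: str) -> Selection:
    """Resolve a selection expression against a trajectory's topology.

    Grammar: predicates ``resid A-B`` / ``resid N`` / ``name X`` /
    ``resname X`` / ``element X``, optionally negated with ``not``, joined by
    ``and``. Ranges are inclusive. An empty result is a warning, not an error.
    """
    tokens = expression.split()
    if not tokens:
        raise SelectionSyntaxError("empty selection expression")
    meta = traj.topology
    mask, pos = _predicate(tokens, 0, meta)
    while pos < len(tokens):
        if tokens[pos] != "and":
            raise SelectionSyntaxError(
                f"expected 'and' at token {pos}, got {tokens[pos]!r}"
            )
        m2, pos = _predicate(tokens, pos + 1, meta)
        mask = mask & m2
    indices = tuple(int(i) for i in np.flatnonzero(mask))
    warns: tuple[str, ...] = ()
    if not indices:
        msg = f"selection {expression!r} matched no atoms"
        warnings.warn(msg, stacklevel=2)
        warns = (msg,)
    return Selection(expression=expression, resolved_indices=indices, warnings=warns)


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------

def measure(frame: Frame, kind: str, indices: Sequence[int]) -> float:
    """Measure a distance (A, two indices) or angle (degrees, vertex = middle).

    Angles are in [0, 180]; coincident points make the angle undefined and
    raise :class:`StructureError`.
    """
    pos = frame.coordinates
    n = pos.shape[0]
    for i in indices:
        if not 0 <= i < n:
            raise IndexError(f"atom index {i} out of range (0..{n - 1})")
    if kind == "distance":
        if len(indices) != 2:
            raise ValueError("distance requires exactly 2 indices")
        i, j = indices
        return float(np.linalg.norm(pos[i] - pos[j]))
    if kind == "angle":
        if len(indices) != 3:
            raise ValueError("angle requires exactly 3 indices")
        i, j, k = indices
        v1 = pos[i] - pos[j]
        v2 = pos[k] - pos[j]
        n1 = np.linalg.norm(v1)
        n2 = np.linalg.norm(v2)
        if n1 == 0.0 or n2 == 0.0:
            raise StructureError(
                "angle undefined: coincident points at the vertex"
            )
        cosang = float(np.dot(v1, v2) / (n1 * n2))
        cosang = min(1.0, max(-1.0, cosang))
        return float(np.degrees(np.arccos(cosang)))
    raise ValueError(f"unknown measurement kind {kind!r}")
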