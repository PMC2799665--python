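"""Readers and writers for every external representation the pipeline touches.

Internal conventions, applied uniformly across the analysis layer:

* lengths are **nm** (PDB angstroms are divided by 10 on read),
* times are **ns**,
* residue indices are 1-based (PDB convention).

Structures travel as PDB (one ``MODEL`` per frame for trajectories; parsing
and serialisation delegated to :mod:`gemmi`) or multi-frame XYZ; scalar time
series as two-column CSV ``time_ns,value`` with a one-line header; fit
reports as JSON (written by the fitting modules themselves).
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field
from typing import Sequence

import gemmi
import numpy as np

from .errors import GridError, ParseError, TopologyError

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "TimeSeries",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "read_timeseries",
    "write_timeseries",
]

#: relative tolerance on time-grid uniformity accepted by read_timeseries
GRID_RTOL = 1e-6


@dataclass(frozen=True)
class Atom:
    """One atom record; ``position`` is an (x, y, z) triplet in nm."""

    name: str
    element: str
    residue_index: int  # 1-based
    residue_name: str
    chain_id: str
    position: tuple[float, float, float]


@dataclass
class Structure:
    """A single conformation: a flat list of atoms plus a coordinate array.

    ``positions`` (n_atoms, 3) in nm is the mutable working copy; the
    ``atoms`` tuple carries the constant topology.  Residue indices must be
    non-decreasing, which every reader and builder guarantees.
    """

    atoms: tuple[Atom, ...]
    positions: np.ndarray  # (n_atoms, 3), nm

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.atoms), 3):
            raise TopologyError(
                f"positions shape {self.positions.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.positions)):
            raise TopologyError("non-finite coordinates")
        idx = [a.residue_index for a in self.atoms]
        if any(b < a for a, b in zip(idx, idx[1:])):
            raise TopologyError("residue indices must be non-decreasing")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residue_indices(self) -> list[int]:
        return sorted({a.residue_index for a in self.atoms})

    def atom_index(self, residue_index: int, name: str) -> int:
        """Index of the first atom called ``name`` in residue ``residue_index``."""
        for i, a in enumerate(self.atoms):
            if a.residue_index == residue_index and a.name == name:
                return i
        raise TopologyError(f"residue {residue_index} has no atom {name!r}")

    def has_atom(self, residue_index: int, name: str) -> bool:
        return any(
            a.residue_index == residue_index and a.name == name for a in self.atoms
        )

    def position_of(self, residue_index: int, name: str) -> np.ndarray:
        return self.positions[self.atom_index(residue_index, name)]

    def with_positions(self, positions: np.ndarray) -> "Structure":
        return Structure(self.atoms, np.array(positions, dtype=float))


@dataclass
class Trajectory:
    """Ordered frames with identical topology, ``dt`` ns apart."""

    frames: list[Structure]
    dt: float  # ns between stored frames
    origin_time: float = 0.0  # ns

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise TopologyError("a trajectory needs at least one frame")
        n0 = self.frames[0].n_atoms
        for k, f in enumerate(self.frames):
            if f.n_atoms != n0:
                raise TopologyError(
                    f"frame {k} has {f.n_atoms} atoms, frame 0 has {n0}"
                )
        if self.dt <= 0:
            raise GridError("trajectory dt must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def times(self) -> np.ndarray:
        return self.origin_time + self.dt * np.arange(self.n_frames)


@dataclass
class TimeSeries:
    """Uniformly sampled scalar signal (``dt`` in ns)."""

    dt: float
    values: np.ndarray
    t0: float = 0.0
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise GridError("a time series needs >= 2 samples")
        if self.dt <= 0:
            raise GridError("dt must be positive")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        """Record length in ns (n*dt, the span the correlator may use)."""
        return self.n * self.dt

    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)


# ---------------------------------------------------------------------------
# PDB via gemmi
# ---------------------------------------------------------------------------

def _structure_from_gemmi_model(model: "gemmi.Model") -> Structure:
    atoms: list[Atom] = []
    pos: list[tuple[float, float, float]] = []
    for chain in model:
        for res in chain:
            for at in res:
                atoms.append(
                    Atom(
                        name=at.name,
                        element=at.element.name,
                        residue_index=res.seqid.num,
                        residue_name=res.name,
                        chain_id=chain.name,
                        position=(at.pos.x / 10.0, at.pos.y / 10.0, at.pos.z / 10.0),
                    )
                )
                pos.append(atoms[-1].position)
    if not atoms:
        raise ParseError("no atoms in model")
    return Structure(tuple(atoms), np.array(pos))


def _gemmi_structure_from(structures: Sequence[Structure]) -> "gemmi.Structure":
    st = gemmi.Structure()
    st.name = "looplab"
    for struct in structures:
        model = gemmi.Model(str(len(st) + 1))
        chain_map: dict[str, gemmi.Chain] = {}
        res_map: dict[tuple[str, int], gemmi.Residue] = {}
        for atom, xyz in zip(struct.atoms, struct.positions):
            if atom.chain_id not in chain_map:
                chain_map[atom.chain_id] = gemmi.Chain(atom.chain_id)
            chain = chain_map[atom.chain_id]
            key = (atom.chain_id, atom.residue_index)
            if key not in res_map:
                res = gemmi.Residue()
                res.name = atom.residue_name
                res.seqid = gemmi.SeqId(atom.residue_index, " ")
                chain.add_residue(res)
                res_map[key] = chain[-1]
            g_at = gemmi.Atom()
            g_at.name = atom.name
            g_at.element = gemmi.Element(atom.element)
            g_at.pos = gemmi.Position(*(10.0 * np.asarray(xyz)))  # nm -> A
            res_map[key].add_atom(g_at)
        for chain in chain_map.values():
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    return st


def _read_pdb_models(path: str) -> list[Structure]:
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:  # gemmi raises RuntimeError
        raise ParseError(f"cannot parse PDB {path}: {exc}") from exc
    frames = [_structure_from_gemmi_model(m) for m in st]
    if not frames:
        raise ParseError(f"no MODEL/atom records in {path}")
    return frames


# ---------------------------------------------------------------------------
# XYZ (multi-frame). Coordinates stored in nm.
# ---------------------------------------------------------------------------

def _read_xyz_frames(path: str) -> list[Structure]:
    frames: list[Structure] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise ParseError(f"{path}:{i + 1}: expected atom count") from exc
        if i + 1 + n >= len(lines) + 1 and n > 0:
            raise ParseError(f"{path}:{i + 1}: truncated frame")
        atoms: list[Atom] = []
        pos: list[list[float]] = []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{i + 3 + j}: malformed XYZ atom line")
            elem = parts[0]
            try:
                xyz = [float(v) for v in parts[1:4]]
            except ValueError as exc:
                raise ParseError(f"{path}:{i + 3 + j}: bad coordinate") from exc
            atoms.append(
                Atom(
                    name=elem,
                    element=elem,
                    residue_index=j + 1,
                    residue_name="UNK",
                    chain_id="A",
                    position=tuple(xyz),
                )
            )
            pos.append(xyz)
        frames.append(Structure(tuple(atoms), np.array(pos)))
        i += 2 + n
    if not frames:
        raise ParseError(f"no frames in {path}")
    return frames


def _write_xyz_frames(frames: Sequence[Structure], path: str) -> None:
    with open(path, "w") as fh:
        for k, f in enumerate(frames):
            fh.write(f"{f.n_atoms}\n")
            fh.write(f"frame {k} (coordinates in nm)\n")
            for atom, xyz in zip(f.atoms, f.positions):
                fh.write(
                    f"{atom.element or atom.name} "
                    f"{xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n"
                )


def _detect_format(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".pdb", ".ent"):
        return "pdb"
    if ext == ".xyz":
        return "xyz"
    raise ParseError(f"unrecognised structure format: {path}")


def read_structure(path: str) -> Structure:
    """Read a single conformation (first MODEL/frame) from PDB or XYZ."""
    fmt = _detect_format(path)
    frames = _read_pdb_models(path) if fmt == "pdb" else _read_xyz_frames(path)
    return frames[0]


def read_trajectory(path: str, dt: float, origin_time: float = 0.0) -> Trajectory:
    """Read a multi-MODEL PDB or multi-frame XYZ as a trajectory.

    ``dt`` is the time between stored frames in ns (formats do not carry it).
    """
    fmt = _detect_format(path)
    frames = _read_pdb_models(path) if fmt == "pdb" else _read_xyz_frames(path)
    return Trajectory(frames, dt=dt, origin_time=origin_time)


def write_structure(struct: Structure, path: str) -> None:
    write_trajectory(Trajectory([struct], dt=1.0), path)


def write_trajectory(traj: Trajectory, path: str) -> None:
    """Write frames as multi-MODEL PDB or multi-frame XYZ (by extension)."""
    fmt = _detect_format(path)
    if fmt == "pdb":
        st = _gemmi_structure_from(traj.frames)
        doc = st.make_pdb_string()
        with open(path, "w") as fh:
            fh.write(doc)
    else:
        _write_xyz_frames(traj.frames, path)


# ---------------------------------------------------------------------------
# CSV time series
# ---------------------------------------------------------------------------

def read_timeseries(path: str) -> TimeSeries:
    """Read a 2-column CSV (time_ns, value); dt inferred from median spacing.

    Non-uniform grids (relative jitter above ``GRID_RTOL``) are rejected with
    :class:`~looplab.errors.GridError`.
    """
    try:
        data = np.genfromtxt(path, delimiter=",", names=True)
    except (OSError, ValueError, IndexError) as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    if data.size == 0 or data.dtype.names is None or len(data.dtype.names) < 2:
        raise ParseError(f"{path}: expected a header and two columns")
    tcol, vcol = data.dtype.names[:2]
    t = np.atleast_1d(data[tcol]).astype(float)
    v = np.atleast_1d(data[vcol]).astype(float)
    if t.size < 2:
        raise ParseError(f"{path}: need at least two rows")
    steps = np.diff(t)
    if np.any(steps <= 0):
        raise GridError(f"{path}: times must be strictly increasing")
    dt = float(np.median(steps))
    if np.max(np.abs(steps - dt)) > GRID_RTOL * max(dt, 1.0) + GRID_RTOL * dt:
        raise GridError(f"{path}: non-uniform sampling (tolerance {GRID_RTOL:g})")
    label = vcol
    return TimeSeries(dt=dt, values=v, t0=float(t[0]), label=label)


def write_timeseries(series: TimeSeries, path: str, value_label: str | None = None) -> None:
    """Write ``time_ns,<label>`` CSV at 12 significant digits."""
    label = value_label or series.label or "value"
    t = series.times()
    with open(path, "w") as fh:
        fh.write(f"time_ns,{label}\n")
        for ti, vi in zip(t, series.values):
            fh.write(f"{ti:.12g},{vi:.12g}\n")


def timeseries_to_csv_string(series: TimeSeries) -> str:
    buf = io.StringIO()
    buf.write("time_ns,value\n")
    for ti, vi in zip(series.times(), series.values):
        buf.write(f"{ti:.12g},{vi:.12g}\n")
    return buf.getvalue()


def asdict(obj) -> dict:
    """JSON-friendly dict view of any of the dataclasses in this module."""
    return dataclasses.asdict(obj)
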