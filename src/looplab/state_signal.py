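"""From structures or distance series to the binary open/closed signal I(t).

The fluorescence signal of a contact-quenched dye is modelled as all-or-none:
a frame is *closed* (quenched, I = 0) when the minimum distance between the
two reporter groups is at or below a cutoff, *open* (fluorescent, I = 1)
otherwise.  The cutoffs used for the peptide systems are 0.45 nm (dye-labelled,
dye ring / Trp ring distance) and 0.58 nm (unlabelled, Trp rings + C-terminal
carboxylate vs N-terminal amino group); both are exposed as named constants in
:mod:`looplab.free_energy`, which can also select a cutoff from the
free-energy barrier position.

Boundary convention: distance **equal** to the cutoff counts as closed.  The
choice is measure-zero on continuous data but is pinned for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, SelectionError
from .io_formats import TimeSeries, Trajectory

__all__ = [
    "StateSeries",
    "GroupSpec",
    "labelled_preset",
    "unlabelled_preset",
    "min_distance_series",
    "binarize",
    "dwell_times",
    "DwellTimes",
]

#: ring heavy atoms of tryptophan (the quencher side of the contact)
TRP_RING_ATOMS = ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2")
#: C-terminal carboxylate atoms
CTERM_ATOMS = ("C", "O", "OXT")
#: N-terminal amino-group atoms (united-atom inputs expose N only)
NTERM_ATOMS = ("N", "H")


@dataclass
class StateSeries:
    """Uniformly sampled binary signal; 1 = open/fluorescent, 0 = closed."""

    dt: float  # ns
    states: np.ndarray  # int8 in {0, 1}
    cutoff_nm: float | None = None
    group_spec: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states)
        if self.states.ndim != 1 or self.states.size < 2:
            raise InputError("a state series needs >= 2 samples")
        vals = np.unique(self.states)
        if not np.all(np.isin(vals, (0, 1))):
            raise InputError("states must be binary {0,1}")
        self.states = self.states.astype(np.int8)
        if self.dt <= 0:
            raise InputError("dt must be positive")

    @property
    def n(self) -> int:
        return int(self.states.size)

    @property
    def mean(self) -> float:
        """Time-average of I(t) = fraction of open frames."""
        return float(self.states.mean())

    @property
    def duration(self) -> float:
        return self.n * self.dt

    def to_timeseries(self) -> TimeSeries:
        return TimeSeries(dt=self.dt, values=self.states.astype(float),
                          t0=self.t0, label="state", units="")


@dataclass
class GroupSpec:
    """Two disjoint atom groups whose minimum distance defines the signal.

    Each group is a list of ``(residue_index, atom_name)`` pairs.  The named
    presets interpret the reporter systems: the *labelled* preset pairs dye
    ring atoms with Trp ring atoms; the *unlabelled* preset pairs the Trp
    rings plus the C-terminal carboxylate against the N-terminal amino group
    (the exact Trp atom list is an interpretation: all ring heavy atoms plus
    the terminal carboxylate atoms).
    """

    group_a: list[tuple[int, str]]
    group_b: list[tuple[int, str]]
    name: str = "custom"

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise SelectionError("both atom groups must be non-empty")
        if set(self.group_a) & set(self.group_b):
            raise SelectionError("atom groups must be disjoint")


def _ring_selection(struct: Trajectory | None, residue_index: int,
                    names: tuple[str, ...]) -> list[tuple[int, str]]:
    return [(residue_index, n) for n in names]


def unlabelled_preset(struct_or_traj) -> GroupSpec:
    """Trp rings + C-terminal carboxylate vs N-terminal amino group.

    The tryptophan is assumed to be the C-terminal residue (the reporter
    placement in the GS-repeat constructs); atoms missing from the topology
    are dropped from the selection.
    """
    frame = struct_or_traj.frames[0] if isinstance(struct_or_traj, Trajectory) else struct_or_traj
    residues = frame.residue_indices
    first, last = residues[0], residues[-1]
    group_a = [(last, n) for n in TRP_RING_ATOMS + CTERM_ATOMS if frame.has_atom(last, n)]
    group_b = [(first, n) for n in NTERM_ATOMS if frame.has_atom(first, n)]
    if not group_a or not group_b:
        raise SelectionError("unlabelled preset: terminal groups not found in topology")
    return GroupSpec(group_a, group_b, name="preset:unlabelled")


def labelled_preset(struct_or_traj, dye_residue_name: str = "MR1") -> GroupSpec:
    """Dye ring atoms vs Trp ring atoms (dye residue matched by name)."""
    frame = struct_or_traj.frames[0] if isinstance(struct_or_traj, Trajectory) else struct_or_traj
    dye_res = sorted({a.residue_index for a in frame.atoms
                      if a.residue_name == dye_residue_name})
    trp_res = sorted({a.residue_index for a in frame.atoms if a.residue_name == "TRP"})
    if not dye_res or not trp_res:
        raise SelectionError("labelled preset needs a dye residue and a TRP residue")
    ring_names = [a.name for a in frame.atoms
                  if a.residue_index == dye_res[0] and a.element != "H"]
    group_a = [(dye_res[0], n) for n in ring_names]
    group_b = [(trp_res[-1], n) for n in TRP_RING_ATOMS if frame.has_atom(trp_res[-1], n)]
    return GroupSpec(group_a, group_b, name="preset:labelled")


def min_distance_series(traj: Trajectory, groups: GroupSpec) -> TimeSeries:
    """Per-frame minimum distance (nm) over all inter-group atom pairs.

    Periodic images are ignored: inputs are expected to be whole, non-periodic
    molecules (pre-imaged if they came from a periodic simulation).
    """
    frame0 = traj.frames[0]
    try:
        idx_a = [frame0.atom_index(r, n) for r, n in groups.group_a]
        idx_b = [frame0.atom_index(r, n) for r, n in groups.group_b]
    except Exception as exc:
        raise SelectionError(f"selection refers to missing atoms: {exc}") from exc
    values = np.empty(traj.n_frames)
    for k, frame in enumerate(traj.frames):
        pa = frame.positions[idx_a]  # (A, 3)
        pb = frame.positions[idx_b]  # (B, 3)
        d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
        values[k] = d.min()
    if traj.n_frames == 1:  # TimeSeries requires >= 2 samples
        values = np.repeat(values, 2)
    return TimeSeries(dt=traj.dt, values=values, t0=traj.origin_time,
                      label="min_distance", units="nm")


def binarize(series: TimeSeries, cutoff_nm: float,
             group_spec: str = "") -> StateSeries:
    """Threshold a distance series: distance <= cutoff is closed (0)."""
    if cutoff_nm <= 0:
        raise InputError("cutoff must be positive")
    states = (series.values > cutoff_nm).astype(np.int8)
    return StateSeries(dt=series.dt, states=states, cutoff_nm=cutoff_nm,
                       group_spec=group_spec or series.label, t0=series.t0)


@dataclass
class DwellTimes:
    """Interior dwell durations (ns) plus the truncated boundary runs.

    Boundary runs are cut by the start/end of the record, so their durations
    are censored; they are reported separately and excluded from means.
    """

    open_dwells: np.ndarray
    closed_dwells: np.ndarray
    boundary_runs: list[tuple[int, float]] = field(default_factory=list)

    @property
    def mean_open(self) -> float:
        return float(np.mean(self.open_dwells)) if self.open_dwells.size else float("nan")

    @property
    def mean_closed(self) -> float:
        return float(np.mean(self.closed_dwells)) if self.closed_dwells.size else float("nan")


def dwell_times(series: StateSeries) -> DwellTimes:
    """Run-length decomposition of the binary signal into dwell durations.

    A run of k consecutive samples corresponds to k*dt ns.  The first and
    last runs touch the record boundary and are returned under
    ``boundary_runs`` as ``(state, duration)`` pairs.
    """
    s = series.states
    change = np.flatnonzero(np.diff(s) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [s.size]))
    lengths = (ends - starts) * series.dt
    states_of_run = s[starts]
    if starts.size == 1:  # constant series: single boundary run, no full dwell
        return DwellTimes(np.empty(0), np.empty(0),
                          [(int(states_of_run[0]), float(lengths[0]))])
    interior = slice(1, starts.size - 1)
    o = lengths[interior][states_of_run[interior] == 1]
    c = lengths[interior][states_of_run[interior] == 0]
    boundary = [(int(states_of_run[0]), float(lengths[0])),
                (int(states_of_run[-1]), float(lengths[-1]))]
    return DwellTimes(np.asarray(o, dtype=float), np.asarray(c, dtype=float), boundary)
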