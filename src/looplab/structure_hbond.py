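"""Backbone hydrogen bonds, beta-segments, and Ramachandran statistics.

Two hydrogen-bond criteria are provided:

* **geometric** — donor-acceptor heavy-atom (N...O) distance <= 0.35 nm and
  the angle at N between N->H and N->O <= 30 deg (a common trajectory-analysis
  default; used for plain bond counting),
* **kabsch_sander** — the DSSP electrostatic energy

      E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol,

  distances in A, with a bond when E < -0.5 kcal/mol (the DSSP default
  cutoff).  This criterion backs the beta-segment definition.

A *beta-segment* is a ladder of >= 2 consecutive inter-strand hydrogen
bonds between two strands (register shifting uniformly along both strands,
antiparallel or parallel) — the operational secondary-structure definition
used here instead of full DSSP state assignment.

Donors and acceptors must be >= 2 residues apart in sequence; bonds between
residues >= 3 apart count as inter-strand candidates for ladders.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .correlation import HBondExistenceMatrix
from .errors import EmptyStateError, GeometryError, InputError, TopologyError
from .io_formats import Atom, Structure, Trajectory
from .state_signal import StateSeries

__all__ = [
    "GEOMETRIC_DISTANCE_CUTOFF_NM",
    "GEOMETRIC_ANGLE_CUTOFF_DEG",
    "KABSCH_SANDER_CUTOFF_KCAL",
    "HBondRecord",
    "BetaSegment",
    "RamaHistogram",
    "ensure_amide_hydrogens",
    "detect_hbonds_geometric",
    "kabsch_sander_energy",
    "detect_hbonds_kabsch_sander",
    "hbond_existence_matrix",
    "beta_segments",
    "measure_phi_psi",
    "phi_psi",
    "region_fractions",
    "open_state_structure_stats",
]

GEOMETRIC_DISTANCE_CUTOFF_NM = 0.35
GEOMETRIC_ANGLE_CUTOFF_DEG = 30.0
#: DSSP default hydrogen-bond energy cutoff (kcal/mol)
KABSCH_SANDER_CUTOFF_KCAL = -0.5
_KS_PREFACTOR = 0.084 * 332.0  # kcal/mol * A

#: Ramachandran region centres (phi, psi) in degrees, +/- half-width boxes
RAMA_REGIONS = {"beta": (-135.0, 135.0), "ppii": (-75.0, 140.0)}
RAMA_HALF_WIDTH_DEG = 30.0


@dataclass(frozen=True)
class HBondRecord:
    """One donor->acceptor backbone hydrogen bond (residue indices, 1-based)."""

    donor_residue: int  # provides N-H
    acceptor_residue: int  # provides C=O
    criterion: str  # "geometric" | "kabsch_sander"
    energy: float | None = None  # kcal/mol under the energy criterion

    def __post_init__(self) -> None:
        if abs(self.donor_residue - self.acceptor_residue) < 2:
            raise InputError("donor and acceptor must be >= 2 residues apart")

    @property
    def pair(self) -> tuple[int, int]:
        return (min(self.donor_residue, self.acceptor_residue),
                max(self.donor_residue, self.acceptor_residue))


def ensure_amide_hydrogens(struct: Structure) -> Structure:
    """Reconstruct missing amide H at 1.0 A from N, anti to the C(i-1)=O bond.

    The N-terminal residue is left without H (it has no preceding carbonyl).
    """
    residues = struct.residue_indices
    new_atoms: list[Atom] = []
    new_pos: list[np.ndarray] = []
    for i, r in enumerate(residues):
        for a, p in zip(struct.atoms, struct.positions):
            if a.residue_index == r:
                new_atoms.append(a)
                new_pos.append(np.asarray(p))
        if i > 0 and not struct.has_atom(r, "H") and struct.has_atom(r, "N"):
            prev = residues[i - 1]
            if struct.has_atom(prev, "C") and struct.has_atom(prev, "O"):
                n = struct.position_of(r, "N")
                u = struct.position_of(prev, "C") - struct.position_of(prev, "O")
                h = n + 0.100 * u / np.linalg.norm(u)
                ref = next(a for a in struct.atoms if a.residue_index == r)
                new_atoms.append(Atom("H", "H", r, ref.residue_name,
                                      ref.chain_id, tuple(h)))
                new_pos.append(h)
    return Structure(tuple(new_atoms), np.array(new_pos))


def _backbone(struct: Structure, residue: int, names: tuple[str, ...]) -> dict[str, np.ndarray]:
    out = {}
    for n in names:
        try:
            out[n] = struct.position_of(residue, n)
        except TopologyError as exc:
            raise TopologyError(f"residue {residue} misses backbone atom {n}") from exc
    return out


def _candidate_pairs(residues: list[int], min_sep: int = 2):
    for d, a in itertools.permutations(residues, 2):
        if abs(d - a) >= min_sep:
            yield d, a


def detect_hbonds_geometric(
    frame: Structure,
    candidates: list[tuple[int, int]] | None = None,
    distance_cutoff_nm: float = GEOMETRIC_DISTANCE_CUTOFF_NM,
    angle_cutoff_deg: float = GEOMETRIC_ANGLE_CUTOFF_DEG,
) -> list[HBondRecord]:
    """Geometric-criterion bonds present in the frame.

    ``candidates`` are (donor_residue, acceptor_residue) pairs; by default
    all ordered pairs >= 2 apart.  Donors without an H atom (the N-terminus)
    get one reconstructed on the fly.
    """
    frame = ensure_amide_hydrogens(frame)
    residues = frame.residue_indices
    pairs = candidates if candidates is not None else list(_candidate_pairs(residues))
    found: list[HBondRecord] = []
    for d, a in pairs:
        if not frame.has_atom(d, "H"):
            continue  # N-terminal donor has no amide H
        don = _backbone(frame, d, ("N", "H"))
        acc = _backbone(frame, a, ("O",))
        r_no = np.linalg.norm(acc["O"] - don["N"])
        if r_no > distance_cutoff_nm:
            continue
        v_h = don["H"] - don["N"]
        v_o = acc["O"] - don["N"]
        cosang = np.dot(v_h, v_o) / (np.linalg.norm(v_h) * np.linalg.norm(v_o))
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if ang <= angle_cutoff_deg:
            found.append(HBondRecord(d, a, "geometric"))
    return found


def kabsch_sander_energy(frame: Structure, donor_residue: int,
                         acceptor_residue: int) -> float:
    """DSSP electrostatic hydrogen-bond energy (kcal/mol), distances in A."""
    frame = ensure_amide_hydrogens(frame)
    don = _backbone(frame, donor_residue, ("N", "H"))
    acc = _backbone(frame, acceptor_residue, ("C", "O"))
    r = {
        "ON": np.linalg.norm(acc["O"] - don["N"]),
        "CH": np.linalg.norm(acc["C"] - don["H"]),
        "OH": np.linalg.norm(acc["O"] - don["H"]),
        "CN": np.linalg.norm(acc["C"] - don["N"]),
    }
    if min(r.values()) < 1e-6:
        raise GeometryError("coincident atoms in Kabsch-Sander evaluation")
    ang = {k: v * 10.0 for k, v in r.items()}  # nm -> A
    return _KS_PREFACTOR * (1.0 / ang["ON"] + 1.0 / ang["CH"]
                            - 1.0 / ang["OH"] - 1.0 / ang["CN"])


def detect_hbonds_kabsch_sander(
    frame: Structure,
    candidates: list[tuple[int, int]] | None = None,
    cutoff_kcal: float = KABSCH_SANDER_CUTOFF_KCAL,
) -> list[HBondRecord]:
    """Energy-criterion bonds (E < cutoff) present in the frame."""
    frame = ensure_amide_hydrogens(frame)
    residues = frame.residue_indices
    pairs = candidates if candidates is not None else list(_candidate_pairs(residues))
    found: list[HBondRecord] = []
    for d, a in pairs:
        if not frame.has_atom(d, "H"):
            continue
        e = kabsch_sander_energy(frame, d, a)
        if e < cutoff_kcal:
            found.append(HBondRecord(d, a, "kabsch_sander", energy=float(e)))
    return found


def hbond_existence_matrix(
    traj: Trajectory,
    criterion: str = "kabsch_sander",
    candidates: list[tuple[int, int]] | None = None,
) -> tuple[HBondExistenceMatrix, list[tuple[int, int]]]:
    """Per-frame existence matrix over every bond observed in the trajectory.

    Returns the matrix (frames x bonds) and the (donor, acceptor) pair each
    column refers to.
    """
    detect = (detect_hbonds_kabsch_sander if criterion == "kabsch_sander"
              else detect_hbonds_geometric)
    per_frame: list[set[tuple[int, int]]] = []
    seen: dict[tuple[int, int], int] = {}
    for frame in traj.frames:
        bonds = {(b.donor_residue, b.acceptor_residue)
                 for b in detect(frame, candidates)}
        for key in bonds:
            seen.setdefault(key, len(seen))
        per_frame.append(bonds)
    if not seen:
        raise InputError("no hydrogen bond observed in any frame")
    H = np.zeros((traj.n_frames, len(seen)), dtype=np.int8)
    for k, bonds in enumerate(per_frame):
        for key in bonds:
            H[k, seen[key]] = 1
    pairs = sorted(seen, key=seen.get)
    return HBondExistenceMatrix(dt=traj.dt, existence=H), pairs


# ---------------------------------------------------------------------------
# beta segments
# ---------------------------------------------------------------------------

@dataclass
class BetaSegment:
    """A ladder of >= 2 consecutive inter-strand hydrogen bonds."""

    ladder: list[tuple[int, int]]  # (donor, acceptor) per rung, ordered
    strand_a: tuple[int, int]  # residue range (lo, hi) of the first strand
    strand_b: tuple[int, int]
    orientation: str  # "antiparallel" | "parallel"

    @property
    def n_bonds(self) -> int:
        return len(self.ladder)


def beta_segments(bonds: list[HBondRecord] | list[tuple[int, int]],
                  min_strand_separation: int = 3,
                  max_ladder: int | None = None) -> list[BetaSegment]:
    """Group inter-strand bonds into ladders of consecutive rungs.

    Bonds are collapsed to unordered residue pairs {i, j}; two rungs are
    consecutive when moving one or two residues along one strand moves the
    same amount along the other, toward each other (antiparallel) or the
    same way (parallel).  Ladders of >= 2 rungs are returned; ``max_ladder``
    truncates reported ladders (the operational definition speaks of two to
    six consecutive bonds).
    """
    pairs = set()
    for b in bonds:
        d, a = (b.donor_residue, b.acceptor_residue) if isinstance(b, HBondRecord) else b
        lo, hi = min(d, a), max(d, a)
        if hi - lo >= min_strand_separation:
            pairs.add((lo, hi))
    pairs = sorted(pairs)
    segments: list[BetaSegment] = []
    used: set[tuple[tuple[int, int], tuple[int, int], str]] = set()
    for start in pairs:
        for orientation, (di, dj) in (("antiparallel", (1, -1)),
                                      ("antiparallel", (2, -2)),
                                      ("parallel", (1, 1)),
                                      ("parallel", (2, 2))):
            ladder = [start]
            cur = start
            while True:
                nxt = (cur[0] + di, cur[1] + dj)
                if nxt in pairs and nxt[0] < nxt[1]:
                    ladder.append(nxt)
                    cur = nxt
                else:
                    break
            prev = (start[0] - di, start[1] - dj)
            if prev in pairs:
                continue  # not the ladder start; avoid duplicates
            if len(ladder) < 2:
                continue
            if max_ladder is not None:
                ladder = ladder[:max_ladder]
            key = (ladder[0], ladder[-1], orientation)
            if key in used:
                continue
            used.add(key)
            a_res = [p[0] for p in ladder]
            b_res = [p[1] for p in ladder]
            segments.append(BetaSegment(
                ladder=ladder,
                strand_a=(min(a_res), max(a_res)),
                strand_b=(min(b_res), max(b_res)),
                orientation=orientation,
            ))
    return segments


# ---------------------------------------------------------------------------
# dihedrals and Ramachandran statistics
# ---------------------------------------------------------------------------

def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees (IUPAC convention)."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def measure_phi_psi(frame: Structure) -> dict[int, tuple[float, float]]:
    """(phi, psi) per internal residue; terminal residues are skipped."""
    residues = frame.residue_indices
    out: dict[int, tuple[float, float]] = {}
    for k in range(1, len(residues) - 1):
        r, prev, nxt = residues[k], residues[k - 1], residues[k + 1]
        c_prev = frame.position_of(prev, "C")
        n = frame.position_of(r, "N")
        ca = frame.position_of(r, "CA")
        c = frame.position_of(r, "C")
        n_next = frame.position_of(nxt, "N")
        out[r] = (_dihedral(c_prev, n, ca, c), _dihedral(n, ca, c, n_next))
    return out


@dataclass
class RamaHistogram:
    """2-D (phi, psi) occupancy for non-glycine internal residues."""

    counts: np.ndarray  # (n_bins, n_bins)
    bin_width: float  # deg
    n_samples: int
    region_counts: dict[str, int] = field(default_factory=dict)

    @property
    def edges(self) -> np.ndarray:
        return np.arange(-180.0, 180.0 + self.bin_width / 2, self.bin_width)


def phi_psi(traj: Trajectory | Structure, bin_width: float = 10.0,
            exclude_glycine: bool = True) -> RamaHistogram:
    """Ramachandran occupancy histogram over all frames and internal residues."""
    frames = traj.frames if isinstance(traj, Trajectory) else [traj]
    n_bins = int(round(360.0 / bin_width))
    counts = np.zeros((n_bins, n_bins), dtype=int)
    region_counts = {name: 0 for name in RAMA_REGIONS}
    n_samples = 0
    for frame in frames:
        names = {a.residue_index: a.residue_name for a in frame.atoms}
        for r, (ph, ps) in measure_phi_psi(frame).items():
            if exclude_glycine and names.get(r) == "GLY":
                continue
            i = min(int((ph + 180.0) / bin_width), n_bins - 1)
            j = min(int((ps + 180.0) / bin_width), n_bins - 1)
            counts[i, j] += 1
            n_samples += 1
            for name, (c_phi, c_psi) in RAMA_REGIONS.items():
                if (abs(ph - c_phi) <= RAMA_HALF_WIDTH_DEG
                        and abs(ps - c_psi) <= RAMA_HALF_WIDTH_DEG):
                    region_counts[name] += 1
    if n_samples == 0:
        raise InputError("no internal non-glycine residues to histogram")
    return RamaHistogram(counts, bin_width, n_samples, region_counts)


def region_fractions(hist: RamaHistogram) -> dict[str, float]:
    """Named region occupancies plus the 'other' remainder; sums to 1."""
    fr = {name: c / hist.n_samples for name, c in hist.region_counts.items()}
    fr["other"] = max(0.0, 1.0 - sum(fr.values()))
    return fr


# ---------------------------------------------------------------------------
# open-state aggregation
# ---------------------------------------------------------------------------

def open_state_structure_stats(
    traj: Trajectory,
    states: StateSeries,
    criterion: str = "kabsch_sander",
) -> dict:
    """Structural statistics over open (I = 1) frames only.

    Reports the fraction of open frames with >= 1 intra-backbone hydrogen
    bond, the fraction with >= 1 beta-segment, the mean bond count, and an
    in-beta/not-in-beta label per observed bond (majority over open frames)
    for grouping existence autocorrelations.
    """
    if states.n != traj.n_frames:
        raise InputError("states must align frame-by-frame with the trajectory")
    open_idx = np.flatnonzero(states.states == 1)
    if open_idx.size == 0:
        raise EmptyStateError("no open frames")
    detect = (detect_hbonds_kabsch_sander if criterion == "kabsch_sander"
              else detect_hbonds_geometric)
    n_with_bond = 0
    n_with_beta = 0
    counts = []
    in_beta_votes: dict[tuple[int, int], list[int]] = {}
    for k in open_idx:
        bonds = detect(traj.frames[k])
        counts.append(len(bonds))
        if bonds:
            n_with_bond += 1
        segs = beta_segments(bonds)
        if segs:
            n_with_beta += 1
        rungs = {p for s in segs for p in s.ladder}
        for b in bonds:
            in_beta_votes.setdefault(b.pair, []).append(int(b.pair in rungs))
    labels = {pair: ("in_beta" if np.mean(v) > 0.5 else "not_in_beta")
              for pair, v in in_beta_votes.items()}
    return {
        "criterion": criterion,
        "n_open_frames": int(open_idx.size),
        "fraction_with_hbond": n_with_bond / open_idx.size,
        "fraction_with_beta_segment": n_with_beta / open_idx.size,
        "mean_hbond_count": float(np.mean(counts)),
        "bond_labels": labels,
    }
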