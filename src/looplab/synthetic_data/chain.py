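"""Coarse-grained bead-spring chain under overdamped Langevin dynamics.

One bead per residue; harmonic bonds of rest length b (default 0.38 nm, the
C-alpha virtual-bond spacing); optional harmonic-cosine bending stiffness;
optional short-range pairwise attraction between beads at least three apart
in sequence — the minimal surrogate for intra-backbone hydrogen bonding
("sticky" vs "non-sticky" chains); optional WCA excluded volume.  This is a
statistical surrogate for peptide dynamics, not a molecular force field:
no solvent, no electrostatics, no directional bonding term.

Units: nm, ps, kJ/mol, kB = 0.0083145 kJ/mol/K.  The ``friction`` parameter
is the overdamped drag coefficient zeta in amu/ps (1 amu nm^2/ps^2 =
1 kJ/mol closes the unit system); the bead diffusion constant is kB*T/zeta.

Brownian (Euler-Maruyama) update per bead and step:

    x <- x + (dt/zeta) F(x) + sqrt(2 kB T dt / zeta) xi,   xi ~ N(0, 1)^3

The integrator advances a whole ensemble of replicas in one numba-compiled
kernel; a single master seed determines both the equilibrium initial
configurations and the noise stream, so runs are bit-reproducible and two
parameter sets sharing a seed see *identical* noise (paired comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np

from ..errors import IntegrationError, ParameterError
from ..free_energy import KB_KJ_PER_MOL_K
from ..io_formats import Atom, Structure, TimeSeries, Trajectory

__all__ = [
    "ChainModelParams",
    "ChainEnsembleResult",
    "simulate_chain_ensemble",
    "gen_chain_trajectory",
    "sample_phantom_equilibrium",
    "closure_first_passage_times",
]

#: WCA repulsion strength used when excluded_volume_sigma > 0 (kJ/mol)
WCA_EPSILON = 2.5


@dataclass
class ChainModelParams:
    """Parameters of the bead-spring chain; defaults are artifact choices.

    The underlying peptide systems fix only the residue spacing (0.38 nm)
    and the temperature (293 K); every other default is a documented choice
    of this package (see the methods note), sized so that bond-length
    fluctuations stay small (sigma_bond = sqrt(kBT/k) ~ 0.035 nm keeps the
    chain connected at < 1.5 b) while the Euler step dt*k/zeta stays ~0.1.
    """

    n_beads: int
    n_steps: int
    seed: int
    bond_length: float = 0.38  # nm
    bond_stiffness: float = 2000.0  # kJ/mol/nm^2
    bending_stiffness: float = 0.0  # kJ/mol; 0 = freely jointed
    attraction_eps: float = 0.0  # kJ/mol well depth; 0 = no-hydrogen-bond analog
    attraction_range: float = 0.5  # nm
    excluded_volume_sigma: float = 0.3  # nm; 0 = phantom chain
    temperature: float = 293.0  # K
    friction: float = 1.0  # drag coefficient zeta, amu/ps
    dt: float = 5e-5  # ps

    def validate(self) -> None:
        if self.n_beads < 3:
            raise ParameterError("n_beads must be >= 3")
        for name in ("bond_length", "bond_stiffness", "temperature", "friction", "dt"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("bending_stiffness", "attraction_eps", "excluded_volume_sigma"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.attraction_eps > 0 and self.attraction_range <= 0:
            raise ParameterError("attraction_range must be positive")
        if self.n_steps < 1:
            raise ParameterError("n_steps must be >= 1")

    @property
    def kbt(self) -> float:
        return KB_KJ_PER_MOL_K * self.temperature

    @property
    def is_phantom(self) -> bool:
        return (self.excluded_volume_sigma == 0 and self.attraction_eps == 0
                and self.bending_stiffness == 0)


@numba.njit(cache=True)
def _run_kernel(x, n_steps, a, noise_scale, kbond, b, kappa, eps, ra,
                sigma, eps_rep, record_stride, dists, frame_stride, frames,
                cutoff, fpt, seed):  # pragma: no cover - exercised via wrappers
    """Advance the ensemble in place.

    Returns 0 on success or the (positive) step index at which coordinates
    became non-finite.  ``dists`` (M, n_rec) collects terminal-bead
    separations every ``record_stride`` steps; ``frames`` (n_f, N, 3)
    collects replica-0 snapshots every ``frame_stride`` steps; with
    ``cutoff > 0``, ``fpt`` (M,) receives the first step at which each
    replica's end separation reached the cutoff (-1 = not yet), and the
    kernel stops once every replica has closed.
    """
    np.random.seed(seed)
    M, N = x.shape[0], x.shape[1]
    F = np.zeros((M, N, 3))
    rc_wca = 1.122462048309373 * sigma
    ra2 = ra * ra
    irec = 0
    ifr = 0
    for step in range(1, n_steps + 1):
        for m in range(M):
            if cutoff > 0.0 and fpt[m] >= 0:
                continue  # closed replicas are frozen in first-passage mode
            for i in range(N):
                F[m, i, 0] = 0.0
                F[m, i, 1] = 0.0
                F[m, i, 2] = 0.0
            # harmonic bonds
            for i in range(N - 1):
                dx = x[m, i + 1, 0] - x[m, i, 0]
                dy = x[m, i + 1, 1] - x[m, i, 1]
                dz = x[m, i + 1, 2] - x[m, i, 2]
                r = np.sqrt(dx * dx + dy * dy + dz * dz)
                f = kbond * (r - b) / r
                F[m, i, 0] += f * dx
                F[m, i, 1] += f * dy
                F[m, i, 2] += f * dz
                F[m, i + 1, 0] -= f * dx
                F[m, i + 1, 1] -= f * dy
                F[m, i + 1, 2] -= f * dz
            # bending U = kappa (1 - cos theta) on consecutive bond pairs
            if kappa > 0.0:
                for i in range(N - 2):
                    ux = x[m, i + 1, 0] - x[m, i, 0]
                    uy = x[m, i + 1, 1] - x[m, i, 1]
                    uz = x[m, i + 1, 2] - x[m, i, 2]
                    vx = x[m, i + 2, 0] - x[m, i + 1, 0]
                    vy = x[m, i + 2, 1] - x[m, i + 1, 1]
                    vz = x[m, i + 2, 2] - x[m, i + 1, 2]
                    ru = np.sqrt(ux * ux + uy * uy + uz * uz)
                    rv = np.sqrt(vx * vx + vy * vy + vz * vz)
                    c = (ux * vx + uy * vy + uz * vz) / (ru * rv)
                    gux = vx / (ru * rv) - c * ux / (ru * ru)
                    guy = vy / (ru * rv) - c * uy / (ru * ru)
                    guz = vz / (ru * rv) - c * uz / (ru * ru)
                    gvx = ux / (ru * rv) - c * vx / (rv * rv)
                    gvy = uy / (ru * rv) - c * vy / (rv * rv)
                    gvz = uz / (ru * rv) - c * vz / (rv * rv)
                    # F = +kappa * d(cos)/dx
                    F[m, i, 0] -= kappa * gux
                    F[m, i, 1] -= kappa * guy
                    F[m, i, 2] -= kappa * guz
                    F[m, i + 1, 0] += kappa * (gux - gvx)
                    F[m, i + 1, 1] += kappa * (guy - gvy)
                    F[m, i + 1, 2] += kappa * (guz - gvz)
                    F[m, i + 2, 0] += kappa * gvx
                    F[m, i + 2, 1] += kappa * gvy
                    F[m, i + 2, 2] += kappa * gvz
            # non-bonded pairs, |i-j| >= 3
            if sigma > 0.0 or eps > 0.0:
                for i in range(N - 3):
                    for j in range(i + 3, N):
                        dx = x[m, i, 0] - x[m, j, 0]
                        dy = x[m, i, 1] - x[m, j, 1]
                        dz = x[m, i, 2] - x[m, j, 2]
                        r2 = dx * dx + dy * dy + dz * dz
                        r = np.sqrt(r2)
                        dU = 0.0  # dU/dr
                        if sigma > 0.0 and r < rc_wca:
                            s6 = (sigma / r) ** 6
                            dU += 24.0 * eps_rep * (s6 - 2.0 * s6 * s6) / r
                        if eps > 0.0 and r2 < ra2:
                            q2 = r2 / ra2
                            dU += 4.0 * eps * (r / ra2) * (1.0 - q2)
                        if dU != 0.0:
                            f = -dU / r  # force on i along +d
                            F[m, i, 0] += f * dx
                            F[m, i, 1] += f * dy
                            F[m, i, 2] += f * dz
                            F[m, j, 0] -= f * dx
                            F[m, j, 1] -= f * dy
                            F[m, j, 2] -= f * dz
        # Euler-Maruyama update; noise drawn in fixed replica/bead order
        for m in range(M):
            if cutoff > 0.0 and fpt[m] >= 0:
                continue
            for i in range(N):
                for c in range(3):
                    x[m, i, c] += a * F[m, i, c] \
                        + noise_scale * np.random.standard_normal()
        if record_stride > 0 and step % record_stride == 0 and irec < dists.shape[1]:
            for m in range(M):
                dx = x[m, N - 1, 0] - x[m, 0, 0]
                dy = x[m, N - 1, 1] - x[m, 0, 1]
                dz = x[m, N - 1, 2] - x[m, 0, 2]
                dists[m, irec] = np.sqrt(dx * dx + dy * dy + dz * dz)
            irec += 1
        if frame_stride > 0 and step % frame_stride == 0 and ifr < frames.shape[0]:
            for i in range(N):
                for c in range(3):
                    frames[ifr, i, c] = x[0, i, c]
            ifr += 1
        if cutoff > 0.0:
            n_open = 0
            for m in range(M):
                if fpt[m] < 0:
                    dx = x[m, N - 1, 0] - x[m, 0, 0]
                    dy = x[m, N - 1, 1] - x[m, 0, 1]
                    dz = x[m, N - 1, 2] - x[m, 0, 2]
                    if np.sqrt(dx * dx + dy * dy + dz * dz) <= cutoff:
                        fpt[m] = step
                    else:
                        n_open += 1
            if n_open == 0:
                return 0
        if step % 4096 == 0:
            ok = True
            for m in range(M):
                for i in range(N):
                    for c in range(3):
                        if not np.isfinite(x[m, i, c]):
                            ok = False
            if not ok:
                return step
    return 0


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


def _launch(x: np.ndarray, p: ChainModelParams, n_steps: int,
            record_stride: int = 0, n_frames: int = 0, frame_stride: int = 0,
            cutoff: float = 0.0, seed: int = 0):
    """Allocate outputs and call the kernel; raise on integration failure."""
    M, N = x.shape[0], x.shape[1]
    n_rec = n_steps // record_stride if record_stride > 0 else 0
    dists = np.empty((M, n_rec))
    frames = np.empty((n_frames, N, 3))
    fpt = np.full(M, -1.0)
    bad_step = _run_kernel(
        x, n_steps, p.dt / p.friction,
        np.sqrt(2.0 * p.kbt * p.dt / p.friction),
        p.bond_stiffness, p.bond_length, p.bending_stiffness,
        p.attraction_eps, p.attraction_range, p.excluded_volume_sigma,
        WCA_EPSILON, record_stride, dists, frame_stride, frames,
        cutoff, fpt, seed,
    )
    if bad_step:
        raise IntegrationError(
            f"non-finite coordinates at step {bad_step} "
            f"(dt={p.dt} ps may be too large for the requested stiffness)")
    return dists, frames, fpt


def sample_phantom_equilibrium(p: ChainModelParams, n_replicas: int,
                               rng: np.random.Generator) -> np.ndarray:
    """Initial configurations drawn from the freely-jointed equilibrium.

    Bond directions uniform on the sphere, bond lengths ~ N(b, kBT/k)
    (exact for a phantom chain up to the small radial l^2 weight).  Used as
    a cheap, already-equilibrated start for phantom chains and as a generic
    start (to be equilibrated) otherwise.
    """
    sigma = np.sqrt(p.kbt / p.bond_stiffness)
    nb = p.n_beads - 1
    lengths = np.abs(rng.normal(p.bond_length, sigma, size=(n_replicas, nb, 1)))
    z = rng.uniform(-1.0, 1.0, size=(n_replicas, nb))
    phi = rng.uniform(0.0, 2.0 * np.pi, size=(n_replicas, nb))
    s = np.sqrt(1.0 - z**2)
    dirs = np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=-1)
    x = np.zeros((n_replicas, p.n_beads, 3))
    x[:, 1:] = np.cumsum(lengths * dirs, axis=1)
    return x


@dataclass
class ChainEnsembleResult:
    params: ChainModelParams
    distances: np.ndarray  # (n_replicas, n_records), nm
    record_dt_ps: float
    final_positions: np.ndarray  # (n_replicas, n_beads, 3)

    def distance_series(self, replica: int = 0) -> TimeSeries:
        return TimeSeries(dt=self.record_dt_ps * 1e-3,  # ps -> ns
                          values=self.distances[replica],
                          label="end_to_end_distance", units="nm")


def simulate_chain_ensemble(
    params: ChainModelParams,
    n_replicas: int = 1,
    record_stride: int = 10,
    equilibration_steps: int = 0,
    initial_positions: np.ndarray | None = None,
) -> ChainEnsembleResult:
    """Run ``n_replicas`` chains in one kernel, recording end-to-end distances.

    Phantom parameter sets start from exact equilibrium draws; interacting
    chains should request ``equilibration_steps`` (discarded) or pass their
    own ``initial_positions``.
    """
    params.validate()
    ss = np.random.SeedSequence(params.seed)
    rng = np.random.default_rng(ss)
    if initial_positions is None:
        x = sample_phantom_equilibrium(params, n_replicas, rng)
    else:
        x = np.array(initial_positions, dtype=float)
        if x.shape != (n_replicas, params.n_beads, 3):
            raise ParameterError("initial_positions shape mismatch")
    if equilibration_steps > 0:
        _launch(x, params, equilibration_steps, seed=_child_seed(ss))
    dists, _, _ = _launch(x, params, params.n_steps,
                          record_stride=record_stride, seed=_child_seed(ss))
    return ChainEnsembleResult(params, dists, record_stride * params.dt, x)


def _bead_structure(params: ChainModelParams, positions: np.ndarray) -> Structure:
    atoms = tuple(
        Atom(name="CA", element="C", residue_index=i + 1, residue_name="GSB",
             chain_id="A", position=tuple(positions[i]))
        for i in range(params.n_beads)
    )
    return Structure(atoms, positions.copy())


def gen_chain_trajectory(
    params: ChainModelParams,
    frame_stride: int | None = None,
    record_stride: int = 10,
    equilibration_steps: int = 0,
) -> tuple[Trajectory, TimeSeries]:
    """Single chain: stored frames plus the end-to-end distance series.

    ``frame_stride`` defaults to n_steps//200 (about 200 stored frames).
    The distance series is the separation of the two terminal beads (for
    single-bead "groups" the minimum distance is the bead distance itself).
    """
    params.validate()
    if frame_stride is None:
        frame_stride = max(params.n_steps // 200, 1)
    ss = np.random.SeedSequence(params.seed)
    rng = np.random.default_rng(ss)
    x = sample_phantom_equilibrium(params, 1, rng)
    if equilibration_steps > 0:
        _launch(x, params, equilibration_steps, seed=_child_seed(ss))
    n_frames = params.n_steps // frame_stride
    first = _bead_structure(params, x[0])
    dists, frames, _ = _launch(x, params, params.n_steps,
                               record_stride=record_stride,
                               n_frames=n_frames, frame_stride=frame_stride,
                               seed=_child_seed(ss))
    structs = [first] + [first.with_positions(f) for f in frames]
    traj = Trajectory(structs, dt=frame_stride * params.dt * 1e-3)  # ps -> ns
    series = TimeSeries(dt=record_stride * params.dt * 1e-3, values=dists[0],
                        label="end_to_end_distance", units="nm")
    return traj, series


def closure_first_passage_times(
    params: ChainModelParams,
    n_replicas: int,
    cutoff_nm: float = 0.45,
    max_steps: int | None = None,
    equilibration_steps: int = 0,
    initial_positions: np.ndarray | None = None,
) -> np.ndarray:
    """First-passage times (ps) from open equilibrium configurations to contact.

    Closure = terminal-bead separation first reaching ``cutoff_nm``.
    Initial configurations are equilibrium draws conditioned on being open;
    replicas that never close within ``max_steps`` get +inf.  The closure
    *rate* for scaling studies is 1/mean(FPT): dwell-based rates from a
    binarised equilibrium record are dominated by recrossings of the cutoff
    and lose the polymer-physics length dependence this quantity targets.

    Two parameter sets run with the same seed, replica count and step budget
    see identical initial configurations and a shared noise stream, so
    comparisons between them are closely paired (replicas freeze once
    closed, so the streams stay aligned only until closure times diverge).
    """
    params.validate()
    if max_steps is None:
        max_steps = params.n_steps
    ss = np.random.SeedSequence(params.seed)
    rng = np.random.default_rng(ss)
    if initial_positions is None:
        x = sample_phantom_equilibrium(params, n_replicas, rng)
        for _ in range(100):  # condition on starting open
            ee = np.linalg.norm(x[:, -1] - x[:, 0], axis=-1)
            bad = ee <= cutoff_nm
            if not np.any(bad):
                break
            x[bad] = sample_phantom_equilibrium(params, int(bad.sum()), rng)
    else:
        x = np.array(initial_positions, dtype=float)
    if equilibration_steps > 0:
        _launch(x, params, equilibration_steps, seed=_child_seed(ss))
    _, _, fpt = _launch(x, params, max_steps, cutoff=cutoff_nm,
                        seed=_child_seed(ss))
    fpt = np.where(fpt < 0, np.inf, fpt * params.dt)
    return fpt
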