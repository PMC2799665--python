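import numpy as np
import pytest

from looplab.errors import ParameterError
from looplab.synthetic_data import (
    ChainModelParams,
    closure_first_passage_times,
    gen_chain_trajectory,
    sample_phantom_equilibrium,
    simulate_chain_ensemble,
)


def _phantom(n_beads=8, n_steps=50_000, seed=3, **kw):
    kw.setdefault("excluded_volume_sigma", 0.0)
    return ChainModelParams(n_beads=n_beads, n_steps=n_steps, seed=seed, **kw)


class TestValidation:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            ChainModelParams(n_beads=2, n_steps=10, seed=0).validate()
        with pytest.raises(ParameterError):
            ChainModelParams(n_beads=5, n_steps=10, seed=0,
                             bond_length=-1.0).validate()
        with pytest.raises(ParameterError):
            ChainModelParams(n_beads=5, n_steps=10, seed=0,
                             attraction_eps=-0.1).validate()


class TestDynamics:
    def test_near_zero_temperature_freezes_equilibrium_chain(self):
        """Without thermal noise and at equilibrium bond lengths, nothing moves."""
        p = _phantom(temperature=1e-12, n_steps=2000)
        x0 = np.zeros((1, p.n_beads, 3))
        x0[0, :, 0] = np.arange(p.n_beads) * p.bond_length
        res = simulate_chain_ensemble(p, n_replicas=1, record_stride=100,
                                      initial_positions=x0)
        expected = p.bond_length * (p.n_beads - 1)
        np.testing.assert_allclose(res.distances, expected, rtol=1e-6)

    def test_fixed_seed_reproducible(self):
        p = _phantom(n_steps=5000)
        a = simulate_chain_ensemble(p, n_replicas=2, record_stride=50)
        b = simulate_chain_ensemble(p, n_replicas=2, record_stride=50)
        np.testing.assert_array_equal(a.distances, b.distances)

    def test_connectivity_preserved_at_default_stiffness(self):
        p = ChainModelParams(n_beads=12, n_steps=100_000, seed=9)
        traj, _ = gen_chain_trajectory(p, frame_stride=1000)
        for frame in traj.frames:
            bonds = np.linalg.norm(np.diff(frame.positions, axis=0), axis=1)
            assert bonds.max() < 1.5 * p.bond_length

    def test_unstable_step_raises_integration_error(self):
        from looplab.errors import IntegrationError
        p = _phantom(n_steps=50_000, dt=0.05)  # dt*k/zeta = 100: diverges
        with pytest.raises(IntegrationError, match="step"):
            simulate_chain_ensemble(p, n_replicas=1)

    def test_trajectory_and_series_shapes(self):
        p = _phantom(n_steps=10_000)
        traj, series = gen_chain_trajectory(p, frame_stride=1000,
                                            record_stride=10)
        assert traj.n_frames == 11  # initial frame + 10 stored
        assert series.n == 1000
        assert series.dt == pytest.approx(10 * p.dt * 1e-3)
        assert traj.frames[0].n_atoms == p.n_beads


class TestPolymerStatistics:
    def test_phantom_r2_matches_freely_jointed_chain(self):
        """Short-run <R^2> of a stiff-bond phantom chain ~ (N-1) b^2,
        cross-checked against a direct random-walk Monte-Carlo oracle.
        (A tighter 5% check on a longer run lives in the acceptance suite.)"""
        p = _phantom(n_beads=10, n_steps=400_000, seed=77,
                     bond_stiffness=8000.0, dt=1.25e-5)
        res = simulate_chain_ensemble(p, n_replicas=24, record_stride=200)
        sim_r2 = float((res.distances ** 2).mean())
        ideal = (p.n_beads - 1) * p.bond_length ** 2
        rng = np.random.default_rng(123)
        walk = sample_phantom_equilibrium(p, 200_000, rng)
        mc_r2 = float(((walk[:, -1] - walk[:, 0]) ** 2).sum(axis=1).mean())
        assert mc_r2 == pytest.approx(ideal, rel=0.02)  # oracle sanity
        assert sim_r2 == pytest.approx(ideal, rel=0.10)
        assert sim_r2 == pytest.approx(mc_r2, rel=0.10)

    def test_equilibrium_sampler_open_conditioning(self):
        p = _phantom(n_beads=8)
        fpt = closure_first_passage_times(p, n_replicas=16, cutoff_nm=0.45,
                                          max_steps=200_000)
        assert np.all(np.isfinite(fpt))
        assert np.all(fpt > 0)

    def test_sticky_chain_closes_faster_paired_seeds(self):
        """2 kBT short-range attraction accelerates closure (paired noise)."""
        kbt = ChainModelParams(n_beads=12, n_steps=1, seed=0).kbt
        wins = 0
        n_pairs = 6
        for k in range(n_pairs):
            base = dict(n_beads=12, n_steps=1, seed=500 + k,
                        excluded_volume_sigma=0.25)
            p0 = ChainModelParams(**{**base, "attraction_eps": 0.0})
            p1 = ChainModelParams(**{**base, "attraction_eps": 2.0 * kbt})
            f0 = closure_first_passage_times(p0, n_replicas=8, cutoff_nm=0.45,
                                             max_steps=400_000)
            f1 = closure_first_passage_times(p1, n_replicas=8, cutoff_nm=0.45,
                                             max_steps=400_000)
            if np.mean(f1) < np.mean(f0):
                wins += 1
        assert wins >= n_pairs - 2
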