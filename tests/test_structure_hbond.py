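import numpy as np
import pytest

from looplab.errors import EmptyStateError, InputError
from looplab.io_formats import Atom, Structure, Trajectory
from looplab.state_signal import StateSeries
from looplab.structure_hbond import (
    KABSCH_SANDER_CUTOFF_KCAL,
    beta_segments,
    detect_hbonds_geometric,
    detect_hbonds_kabsch_sander,
    ensure_amide_hydrogens,
    kabsch_sander_energy,
    measure_phi_psi,
    open_state_structure_stats,
    phi_psi,
    region_fractions,
)
from looplab.synthetic_data import IdealGeometrySpec, build_ideal_geometry


def _nh_o_probe(r_no_nm, angle_deg=0.0):
    """Two-residue probe: donor N-H of residue 3 aimed at acceptor C=O of 1."""
    ang = np.deg2rad(angle_deg)
    o = np.array([r_no_nm * np.cos(ang), r_no_nm * np.sin(ang), 0.0])
    c = o + np.array([0.123, 0.0, 0.0])
    atoms = (
        Atom("C", "C", 1, "GLY", "A", tuple(c)),
        Atom("O", "O", 1, "GLY", "A", tuple(o)),
        Atom("N", "N", 3, "GLY", "A", (0.0, 0.0, 0.0)),
        Atom("H", "H", 3, "GLY", "A", (0.1, 0.0, 0.0)),
    )
    pos = np.array([c, o, [0, 0, 0], [0.1, 0, 0]])
    return Structure(atoms, pos)


class TestGeometricCriterion:
    def test_ideal_linear_bond_detected(self):
        s = _nh_o_probe(0.29, 0.0)
        bonds = detect_hbonds_geometric(s, candidates=[(3, 1)])
        assert [(b.donor_residue, b.acceptor_residue) for b in bonds] == [(3, 1)]

    def test_long_distance_rejected(self):
        s = _nh_o_probe(0.40, 0.0)
        assert detect_hbonds_geometric(s, candidates=[(3, 1)]) == []

    def test_bent_geometry_rejected(self):
        s = _nh_o_probe(0.29, 45.0)
        assert detect_hbonds_geometric(s, candidates=[(3, 1)]) == []

    def test_random_decoys_match_exhaustive_recheck(self, rng):
        for _ in range(30):
            r = float(rng.uniform(0.2, 0.5))
            ang = float(rng.uniform(0.0, 90.0))
            s = _nh_o_probe(r, ang)
            got = bool(detect_hbonds_geometric(s, candidates=[(3, 1)]))
            expect = (r <= 0.35) and (ang <= 30.0)
            assert got == expect, (r, ang)


class TestKabschSander:
    def test_formula_matches_hand_computation(self):
        s = _nh_o_probe(0.29, 0.0)
        r_on, r_ch, r_oh, r_cn = 2.9, 2.9 + 1.23 - 1.0, 1.9, 2.9 + 1.23
        expected = 27.888 * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
        assert kabsch_sander_energy(s, 3, 1) == pytest.approx(expected,
                                                              abs=1e-6)

    def test_distant_pair_above_cutoff(self):
        s = _nh_o_probe(1.0, 0.0)
        assert kabsch_sander_energy(s, 3, 1) > KABSCH_SANDER_CUTOFF_KCAL
        assert detect_hbonds_kabsch_sander(s, candidates=[(3, 1)]) == []

    def test_cutoff_constant_pinned(self):
        assert KABSCH_SANDER_CUTOFF_KCAL == -0.5

    def test_energy_and_geometric_criteria_agree_on_hairpin_core(self, hairpin12):
        """Both criteria detect the innermost turn-adjacent rungs; the energy
        criterion may accept additional bonds (it has no hard distance or
        angle gate), so only the shared core is asserted."""
        ks = {(b.donor_residue, b.acceptor_residue)
              for b in detect_hbonds_kabsch_sander(hairpin12)}
        geom = {(b.donor_residue, b.acceptor_residue)
                for b in detect_hbonds_geometric(hairpin12)}
        assert {(5, 8), (8, 5)} <= ks
        assert {(5, 8), (8, 5)} <= geom


class TestAmideReconstruction:
    def test_h_placed_anti_to_carbonyl(self, extended8):
        stripped = Structure(
            tuple(a for a in extended8.atoms if a.name != "H"),
            extended8.positions[[i for i, a in enumerate(extended8.atoms)
                                 if a.name != "H"]],
        )
        rebuilt = ensure_amide_hydrogens(stripped)
        for r in rebuilt.residue_indices[1:]:
            h = rebuilt.position_of(r, "H")
            n = rebuilt.position_of(r, "N")
            assert np.linalg.norm(h - n) == pytest.approx(0.100, abs=1e-9)
            co = (rebuilt.position_of(r - 1, "C")
                  - rebuilt.position_of(r - 1, "O"))
            cos = np.dot(h - n, co) / (np.linalg.norm(h - n) * np.linalg.norm(co))
            assert cos == pytest.approx(1.0, abs=1e-9)


class TestBetaSegments:
    def test_hairpin_yields_antiparallel_ladder(self, hairpin12):
        bonds = detect_hbonds_kabsch_sander(hairpin12)
        segs = beta_segments(bonds)
        assert segs
        best = max(segs, key=lambda s: s.n_bonds)
        assert best.n_bonds >= 2
        assert best.orientation == "antiparallel"

    def test_extended_chain_has_no_segments(self, extended8):
        assert beta_segments(detect_hbonds_kabsch_sander(extended8)) == []

    def test_hand_built_parallel_ladder(self):
        """Three bonds at constant register shift (+2,+2) form one parallel ladder."""
        pairs = [(2, 11), (4, 13), (6, 15)]
        segs = beta_segments(pairs)
        assert len(segs) == 1
        assert segs[0].orientation == "parallel"
        assert segs[0].n_bonds == 3

    def test_invariant_under_strand_relabelling(self):
        pairs = [(2, 11), (4, 9), (6, 7)]
        swapped = [(b, a) for a, b in pairs]
        s1 = beta_segments(pairs)
        s2 = beta_segments(swapped)
        assert [(s.ladder, s.orientation) for s in s1] == \
            [(s.ladder, s.orientation) for s in s2]


class TestRamachandran:
    def test_extended_chain_is_a_point_mass(self, extended8):
        hist = phi_psi(extended8)
        assert hist.counts.sum() == hist.n_samples
        i, j = np.unravel_index(np.argmax(hist.counts), hist.counts.shape)
        # (180, 180) wraps into the last bin in both axes
        assert (i, j) == (hist.counts.shape[0] - 1, hist.counts.shape[1] - 1)

    def test_ppii_chain_fills_ppii_region(self, ppii8):
        fr = region_fractions(phi_psi(ppii8))
        assert fr["ppii"] == 1.0
        assert fr["beta"] == 0.0

    def test_mirror_image_flips_dihedral_signs(self, ppii8):
        mirrored = ppii8.with_positions(ppii8.positions * np.array([1, 1, -1]))
        orig = measure_phi_psi(ppii8)
        mirr = measure_phi_psi(mirrored)
        for r in orig:
            assert mirr[r][0] == pytest.approx(-orig[r][0], abs=1e-9)
            assert mirr[r][1] == pytest.approx(-orig[r][1], abs=1e-9)

    def test_glycine_excluded_from_region_statistics(self):
        s = build_ideal_geometry(
            IdealGeometrySpec("custom_phi_psi", 8, phi=-75.0, psi=140.0,
                              sequence="GGGGGGGG"))
        with pytest.raises(InputError):
            phi_psi(s)


class TestOpenStateStats:
    def _traj(self, hairpin12, extended8):
        # alternate beta-containing and extended frames
        ext12 = build_ideal_geometry(IdealGeometrySpec("extended", 12))
        frames = [hairpin12, ext12, hairpin12, ext12]
        return Trajectory(frames, dt=1.0)

    def test_alternating_fixture_gives_half_beta_fraction(self, hairpin12,
                                                          extended8):
        traj = self._traj(hairpin12, extended8)
        states = StateSeries(dt=1.0, states=np.array([1, 1, 1, 0]))
        stats = open_state_structure_stats(traj, states)
        assert stats["n_open_frames"] == 3
        assert stats["fraction_with_beta_segment"] == pytest.approx(2 / 3)

    def test_all_closed_raises_empty_state(self, hairpin12, extended8):
        traj = self._traj(hairpin12, extended8)
        states = StateSeries(dt=1.0, states=np.zeros(4, dtype=int))
        with pytest.raises(EmptyStateError):
            open_state_structure_stats(traj, states)

    def test_fractions_invariant_under_frame_reordering(self, hairpin12,
                                                        extended8):
        traj = self._traj(hairpin12, extended8)
        states = StateSeries(dt=1.0, states=np.array([1, 1, 1, 1]))
        a = open_state_structure_stats(traj, states)
        rev = Trajectory(list(reversed(traj.frames)), dt=1.0)
        b = open_state_structure_stats(rev, states)
        assert a["fraction_with_beta_segment"] == b["fraction_with_beta_segment"]
        assert a["fraction_with_hbond"] == b["fraction_with_hbond"]
        assert a["mean_hbond_count"] == b["mean_hbond_count"]
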