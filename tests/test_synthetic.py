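"""Generator contracts: kinetics, geometry fidelity, constructed fixtures."""

import math

import numpy as np
import pytest

from methyldyn.constants import K_BOLTZMANN_KCAL
from methyldyn.geometry import dihedral, dihedral_series, superpose_rmsd, wrap_degrees
from methyldyn.rotamer import STATE_LABELS
from methyldyn.structures import Trajectory, Frame
from methyldyn.synthetic import (
    HBondFixtureSpec,
    KineticsError,
    NoiseModel,
    PocketSpec,
    RotamerKinetics,
    make_hbond_fixture,
    make_peptide_fixture,
    make_pocket_frame,
    simulate_rotamer_trajectory,
)
from conftest import head_indices


class TestKinetics:
    def test_barrier_below_uphill_rejected(self):
        with pytest.raises(KineticsError):
            RotamerKinetics(
                state_energies={"g+": 0.0, "g-": 2.0, "t": 0.0},
                barrier_energies={
                    (a, b): 0.5 for a in STATE_LABELS for b in STATE_LABELS if a != b
                },
            )

    def test_transition_probability_over_one_rejected(self):
        kin = RotamerKinetics.symmetric(0.0)  # barrierless
        with pytest.raises(KineticsError):
            kin.transition_matrix(kappa=0.6)  # 2 * 0.6 > 1

    def test_stationary_uniform_for_symmetric(self):
        pi = RotamerKinetics.symmetric(1.0).stationary_distribution()
        assert np.allclose(pi, 1 / 3, atol=1e-10)

    def test_stationary_is_boltzmann_under_detailed_balance(self):
        kT = K_BOLTZMANN_KCAL * 310.0
        energies = {"g+": 0.0, "g-": 0.616, "t": 0.616}
        kin = RotamerKinetics.from_energies(energies, transition_state_energy=2.0)
        pi = kin.stationary_distribution()
        boltz = np.array([math.exp(-energies[s] / kT) for s in STATE_LABELS])
        boltz /= boltz.sum()
        assert np.allclose(pi, boltz, atol=1e-8)


class TestSimulate:
    def test_same_seed_bitwise_identical(self):
        kin = RotamerKinetics.symmetric(1.0)
        pocket = PocketSpec.symmetric(3)
        t1, s1 = simulate_rotamer_trajectory(kin, pocket, NoiseModel(), 500, 2.0, seed=9)
        t2, s2 = simulate_rotamer_trajectory(kin, pocket, NoiseModel(), 500, 2.0, seed=9)
        assert np.array_equal(t1.xyz, t2.xyz)
        assert np.array_equal(s1, s2)

    def test_forbidden_transition_never_occurs(self):
        barriers = {
            (a, b): 1.0 for a in STATE_LABELS for b in STATE_LABELS if a != b
        }
        barriers[("g-", "g+")] = float("inf")
        kin = RotamerKinetics(
            state_energies={s: 0.0 for s in STATE_LABELS}, barrier_energies=barriers
        )
        _, states = simulate_rotamer_trajectory(
            kin, PocketSpec.symmetric(2), NoiseModel(), 50_000, 2.0, seed=3
        )
        direct = sum(
            1 for a, b in zip(states[:-1], states[1:]) if (a, b) == ("g-", "g+")
        )
        assert direct == 0

    def test_stationary_distribution_recovered(self):
        """Long-run state fractions converge on the analytic stationary law."""
        kT = K_BOLTZMANN_KCAL * 310.0
        energies = {"g+": 0.0, "g-": 0.616, "t": 0.616}
        kin = RotamerKinetics.from_energies(energies, transition_state_energy=1.8)
        _, states = simulate_rotamer_trajectory(
            kin, PocketSpec.symmetric(3), NoiseModel(), 100_000, 2.0, seed=11
        )
        pi = kin.stationary_distribution()
        emp = np.array([np.mean(states == s) for s in STATE_LABELS])
        assert 0.5 * np.abs(emp - pi).sum() < 0.02  # total variation
        # the population ratio between the ground and excited wells is ~e
        ratio = emp[0] / emp[2]
        assert ratio == pytest.approx(math.e, rel=0.10)

    def test_torsion_fidelity_without_jitter(self):
        kin = RotamerKinetics.symmetric(1.0)
        pocket = PocketSpec.symmetric(3)
        traj, states = simulate_rotamer_trajectory(
            kin, pocket, NoiseModel(jitter_sigma=0.0, dihedral_sigma=8.0),
            2000, 2.0, seed=4,
        )
        series = dihedral_series(traj, head_indices(traj.structure))
        centers = {"g+": 60.0, "g-": -60.0, "t": 180.0}
        wobble = np.array(
            [wrap_degrees(v - centers[s]) for v, s in zip(series.values, states)]
        )
        # wobble is the only deviation and it is bounded well inside a bin
        assert np.abs(wobble).max() < 60.0
        assert np.std(wobble) == pytest.approx(8.0, rel=0.1)

    def test_torsion_error_small_with_default_jitter(self):
        kin = RotamerKinetics.symmetric(1.0)
        pocket = PocketSpec.symmetric(3)
        nm = NoiseModel(jitter_sigma=0.05, dihedral_sigma=0.0)
        traj, states = simulate_rotamer_trajectory(kin, pocket, nm, 2000, 2.0, seed=4)
        series = dihedral_series(traj, head_indices(traj.structure))
        centers = {"g+": 60.0, "g-": -60.0, "t": 180.0}
        err = np.array(
            [wrap_degrees(v - centers[s]) for v, s in zip(series.values, states)]
        )
        # 0.05 Å jitter on each of the four quad atoms, with ~1.4 Å lever
        # arms, propagates to ~5 degrees RMS of torsion noise
        assert np.sqrt(np.mean(err**2)) < 6.0

    def test_title_embeds_seed(self):
        traj, _ = simulate_rotamer_trajectory(
            RotamerKinetics.symmetric(1.0), PocketSpec.symmetric(3), NoiseModel(),
            10, 2.0, seed=123,
        )
        assert "seed=123" in traj.structure.title


class TestPocketGeometry:
    @pytest.mark.parametrize("count", [1, 2, 3])
    def test_head_tetrahedral_geometry(self, count):
        pocket = PocketSpec.symmetric(count)
        s, frame = make_pocket_frame(pocket, state="t", include_hydrogens=True)
        nz = frame.coordinates[s.index_of("B", 9, "NZ")]
        ce = frame.coordinates[s.index_of("B", 9, "CE")]
        assert np.linalg.norm(ce - nz) == pytest.approx(1.49, abs=1e-9)
        for k in range(1, count + 1):
            cz = frame.coordinates[s.index_of("B", 9, f"CZ{k}")]
            assert np.linalg.norm(cz - nz) == pytest.approx(1.49, abs=1e-9)
            cos = np.dot(ce - nz, cz - nz) / (
                np.linalg.norm(ce - nz) * np.linalg.norm(cz - nz)
            )
            assert np.degrees(np.arccos(cos)) == pytest.approx(109.5, abs=1e-6)

    def test_successive_methyls_offset_120(self):
        s, frame = make_pocket_frame(PocketSpec.symmetric(3), state="g+")
        quad = [s.index_of("B", 9, n) for n in ("CD", "CE", "NZ")]
        taus = [
            dihedral(*frame.coordinates[quad + [s.index_of("B", 9, f"CZ{k}")]])
            for k in (1, 2, 3)
        ]
        assert wrap_degrees(taus[1] - taus[0]) == pytest.approx(120.0, abs=1e-9)
        assert wrap_degrees(taus[2] - taus[1]) == pytest.approx(120.0, abs=1e-9)

    def test_symmetric_cage_nz_oxygen_distances(self):
        pocket = PocketSpec.symmetric(3)
        nz = np.array(pocket.nz_position)
        for xyz in pocket.pocket_oxygen_positions.values():
            assert np.linalg.norm(np.array(xyz) - nz) == pytest.approx(4.2, abs=1e-9)

    def test_asymmetric_cage_pulled_in_oxygens(self):
        pocket = PocketSpec.asymmetric(2)
        nz = np.array(pocket.nz_position)
        for label in ("Asn290:OD1", "Gly170:O"):
            d = np.linalg.norm(np.array(pocket.pocket_oxygen_positions[label]) - nz)
            assert d == pytest.approx(3.1, abs=1e-9)

    def test_invalid_ce_nz_bond_rejected(self):
        with pytest.raises(ValueError):
            PocketSpec(
                fe_position=(0, 0, 0),
                pocket_oxygen_positions={},
                ce_position=(0.0, 0.0, 2.5),
            )


class TestHBondFixture:
    def test_exact_satisfied_count(self):
        traj = make_hbond_fixture(HBondFixtureSpec(fraction=0.6, n_frames=500, seed=0))
        from methyldyn.hbonds import HBondCriteria, detect_frame
        n_sat = sum(
            bool(detect_frame(fr, [(0, 1, 2)], HBondCriteria.strict()))
            for fr in traj.frames
        )
        assert n_sat == 300

    def test_fraction_bounds_checked(self):
        with pytest.raises(ValueError):
            HBondFixtureSpec(fraction=1.2, n_frames=10)


class TestPeptideFixture:
    def test_residue_and_atom_counts(self):
        s, frame = make_peptide_fixture(8)
        assert s.n_atoms == 32
        assert len({a.residue_number for a in s.atoms}) == 8
        assert all(a.backbone_flag for a in s.atoms)

    def test_w_shape_has_two_ca_z_minima(self):
        s, frame = make_peptide_fixture(8, w_shape=True)
        z = [
            frame.coordinates[i][2]
            for i, a in enumerate(s.atoms)
            if a.name == "CA"
        ]
        minima = sum(
            1 for i in range(1, len(z) - 1) if z[i] < z[i - 1] and z[i] < z[i + 1]
        )
        assert minima == 2

    def test_rotated_copy_superposes_to_zero(self):
        from scipy.spatial.transform import Rotation

        s, frame = make_peptide_fixture(6, w_shape=True)
        rot = Rotation.from_euler("xyz", [75, -20, 140], degrees=True)
        moved = rot.apply(frame.coordinates) + np.array([1.0, 2.0, 3.0])
        rmsd, _ = superpose_rmsd(frame.coordinates, moved)
        assert rmsd <= 1e-8
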