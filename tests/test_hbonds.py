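"""Hydrogen-bond enumeration, detection, occupancy and classification."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from methyldyn.hbonds import (
    HBondCriteria,
    classify_bond,
    detect_frame,
    enumerate_dha_triples,
    hbond_occupancy,
)
from methyldyn.structures import AtomRecord, Frame, StructureModel, StructureError, Trajectory
from methyldyn.synthetic import HBondFixtureSpec, make_hbond_fixture


def build(atom_specs, coords):
    atoms = [
        AtomRecord(i + 1, name, elem, res, num, chain,
                   backbone_flag=(name in ("N", "CA", "C", "O", "H", "HA")
                                  and res not in ("HOH", "WAT")))
        for i, (name, elem, res, num, chain) in enumerate(atom_specs)
    ]
    return StructureModel(atoms), Frame(np.asarray(coords, float))


class TestEnumerate:
    def test_backbone_nh_to_o(self):
        s, _ = build(
            [("N", "N", "ALA", 1, "B"), ("H", "H", "ALA", 1, "B"),
             ("O", "O", "GLY", 2, "A")],
            np.zeros((3, 3)),
        )
        triples = enumerate_dha_triples(s, "strict")
        assert triples == [(0, 1, 2)]

    def test_water_two_donor_pairs_one_acceptor(self):
        s, _ = build(
            [("O", "O", "HOH", 401, "A"), ("H1", "H", "HOH", 401, "A"),
             ("H2", "H", "HOH", 401, "A"), ("O", "O", "GLY", 2, "A")],
            np.zeros((4, 3)),
        )
        triples = enumerate_dha_triples(s, "strict")
        donors = {(d, h) for d, h, _ in triples}
        assert donors == {(0, 1), (0, 2)}
        # the water O also serves as acceptor for no donor here except itself
        acceptors = {a for _, _, a in triples}
        assert acceptors == {3}

    def test_cho_mode_methyl_three_ch_pairs(self):
        s, _ = build(
            [("CZ1", "C", "M3L", 9, "B"),
             ("HZ11", "H", "M3L", 9, "B"), ("HZ12", "H", "M3L", 9, "B"),
             ("HZ13", "H", "M3L", 9, "B"), ("OD1", "O", "ASN", 290, "A")],
            np.zeros((5, 3)),
        )
        cho = enumerate_dha_triples(s, "cho")
        assert {(d, h) for d, h, _ in cho} == {(0, 1), (0, 2), (0, 3)}
        strict = enumerate_dha_triples(s, "strict")
        assert strict == []  # carbon donors need cho mode

    def test_no_hydrogens_is_explicit_error(self):
        s, _ = build([("O", "O", "GLY", 2, "A"), ("N", "N", "ALA", 1, "B")],
                     np.zeros((2, 3)))
        with pytest.raises(StructureError, match="no hydrogens"):
            enumerate_dha_triples(s, "strict")


class TestDetectFrame:
    def _dha(self, acceptor):
        s, frame = build(
            [("N", "N", "ALA", 1, "B"), ("H", "H", "ALA", 1, "B"),
             ("O", "O", "GLY", 2, "A")],
            [[0, 0, 0], [1, 0, 0], acceptor],
        )
        return s, frame

    def test_linear_29_satisfied(self):
        s, frame = self._dha([2.9, 0, 0])
        assert detect_frame(frame, [(0, 1, 2)], HBondCriteria.strict())

    def test_31_rejected_on_distance(self):
        s, frame = self._dha([3.1, 0, 0])
        assert not detect_frame(frame, [(0, 1, 2)], HBondCriteria.strict())

    def test_110_degrees_rejected_on_angle(self):
        ang = np.radians(110.0)
        r_ha = 1.6
        acc = [1 - r_ha * np.cos(ang), r_ha * np.sin(ang), 0.0]
        s, frame = self._dha(acc)
        # distance is comfortably under the cutoff; the angle rejects it
        assert np.linalg.norm(np.array(acc)) < 3.0
        assert not detect_frame(frame, [(0, 1, 2)], HBondCriteria.strict())


class TestOccupancy:
    def test_constructed_fraction_exact(self):
        traj = make_hbond_fixture(HBondFixtureSpec(fraction=0.6, n_frames=500, seed=1))
        triples = enumerate_dha_triples(traj.structure, "strict")
        records = hbond_occupancy(traj, triples, HBondCriteria.strict())
        assert len(records) == 1
        assert records[0].occupancy == 0.600

    @pytest.mark.parametrize("fraction,expect", [(1.0, 1.0), (0.0, None)])
    def test_extreme_fractions(self, fraction, expect):
        traj = make_hbond_fixture(HBondFixtureSpec(fraction=fraction, n_frames=40, seed=2))
        triples = enumerate_dha_triples(traj.structure, "strict")
        records = hbond_occupancy(traj, triples, HBondCriteria.strict())
        if expect is None:
            assert records == []  # never satisfied -> absent from output
        else:
            assert records[0].occupancy == expect

    def test_matches_triple_loop_oracle(self):
        """Random 50-atom, 200-frame system vs an exhaustive python-loop census."""
        rng = np.random.default_rng(21)
        specs = []
        for r in range(10):
            chain = "B" if r < 5 else "A"
            specs += [
                ("N", "N", "ALA", r + 1, chain),
                ("H", "H", "ALA", r + 1, chain),
                ("CA", "C", "ALA", r + 1, chain),
                ("O", "O", "ALA", r + 1, chain),
                ("HA", "H", "ALA", r + 1, chain),
            ]
        s, _ = build(specs, np.zeros((50, 3)))
        coords = rng.uniform(0, 8, size=(200, 50, 3))
        traj = Trajectory(s, [Frame(c, time=i) for i, c in enumerate(coords)], 1.0)
        criteria = HBondCriteria.strict()
        triples = enumerate_dha_triples(s, "strict")
        records = hbond_occupancy(traj, triples, criteria)
        got = {(r.donor, r.hydrogen, r.acceptor): r for r in records}

        for d, h, a in triples:
            count, dsum, devsum = 0, 0.0, 0.0
            for f in range(200):
                rd = np.linalg.norm(coords[f, a] - coords[f, d])
                v1 = coords[f, d] - coords[f, h]
                v2 = coords[f, a] - coords[f, h]
                theta = np.degrees(
                    np.arccos(np.clip(np.dot(v1, v2)
                                      / np.linalg.norm(v1) / np.linalg.norm(v2), -1, 1))
                )
                if rd < 3.0 and 120.0 < theta <= 180.0:
                    count += 1
                    dsum += rd
                    devsum += 180.0 - theta
            if count == 0:
                assert (d, h, a) not in got
            else:
                rec = got[(d, h, a)]
                assert rec.occupancy == pytest.approx(count / 200, abs=1e-12)
                assert rec.mean_distance == pytest.approx(dsum / count, abs=1e-9)
                assert rec.mean_linearity_deviation == pytest.approx(
                    devsum / count, abs=1e-9
                )

    def test_tightening_criteria_never_raises_occupancy(self):
        traj = make_hbond_fixture(HBondFixtureSpec(fraction=0.7, n_frames=100, seed=5))
        triples = enumerate_dha_triples(traj.structure, "strict")
        loose = hbond_occupancy(traj, triples, HBondCriteria(r_max=3.4, theta_min=110))
        tight = hbond_occupancy(traj, triples, HBondCriteria(r_max=2.95, theta_min=150))
        occ = lambda recs: {(r.donor, r.hydrogen, r.acceptor): r.occupancy for r in recs}
        lo, ti = occ(loose), occ(tight)
        for key, o in ti.items():
            # nested criteria: every tightly-satisfied frame is loosely satisfied
            assert key in lo and o <= lo[key] + 1e-12

    def test_strict_triples_subset_of_cho(self, me3_traj):
        traj, _ = me3_traj
        s = traj.structure
        strict = set(enumerate_dha_triples(s, "strict"))
        cho = set(enumerate_dha_triples(s, "cho"))
        assert strict <= cho

    def test_rigid_transform_invariance(self):
        traj = make_hbond_fixture(HBondFixtureSpec(fraction=0.4, n_frames=50, seed=3))
        rot = Rotation.from_euler("xyz", [50, 10, -30], degrees=True)
        moved = Trajectory(
            traj.structure,
            [Frame(rot.apply(fr.coordinates) - 4.0, fr.time) for fr in traj.frames],
            traj.dt,
        )
        triples = enumerate_dha_triples(traj.structure, "strict")
        a = hbond_occupancy(traj, triples, HBondCriteria.strict())
        b = hbond_occupancy(moved, triples, HBondCriteria.strict())
        assert [(r.donor, r.acceptor, r.occupancy) for r in a] == [
            (r.donor, r.acceptor, r.occupancy) for r in b
        ]


class TestClassify:
    def test_substrate_mainchain_to_enzyme_sidechain_interface(self):
        s, _ = build(
            [("N", "N", "ALA", 1, "B"), ("H", "H", "ALA", 1, "B"),
             ("OD1", "O", "ASN", 290, "A")],
            np.zeros((3, 3)),
        )
        from methyldyn.hbonds import HBondRecord
        rec = classify_bond(HBondRecord(0, 1, 2), s, "B", "A")
        assert rec.donor_class == "main chain"
        assert rec.acceptor_class == "side chain"
        assert rec.span_class == "interface"

    def test_arg_sidechain_to_lys_mainchain_intra_substrate(self):
        # the intra-substrate bond stabilising the bent peptide conformation
        s, _ = build(
            [("NH1", "N", "ARG", 8, "B"), ("HH11", "H", "ARG", 8, "B"),
             ("O", "O", "M3L", 9, "B")],
            np.zeros((3, 3)),
        )
        from methyldyn.hbonds import HBondRecord
        rec = classify_bond(HBondRecord(0, 1, 2), s, "B", "A")
        assert rec.donor_class == "side chain"
        assert rec.acceptor_class == "main chain"
        assert rec.span_class == "intra-substrate"

    def test_water_is_side_chain(self):
        s, _ = build(
            [("O", "O", "HOH", 401, "A"), ("H1", "H", "HOH", 401, "A"),
             ("O", "O", "GLY", 170, "A")],
            np.zeros((3, 3)),
        )
        from methyldyn.hbonds import HBondRecord
        rec = classify_bond(HBondRecord(0, 1, 2), s, "B", "A")
        assert rec.donor_class == "side chain"
        assert rec.span_class == "intra-enzyme"

    def test_undeclared_chain_rejected(self):
        s, _ = build(
            [("N", "N", "ALA", 1, "X"), ("H", "H", "ALA", 1, "X"),
             ("O", "O", "GLY", 2, "A")],
            np.zeros((3, 3)),
        )
        from methyldyn.hbonds import HBondRecord
        with pytest.raises(StructureError):
            classify_bond(HBondRecord(0, 1, 2), s, "B", "A")
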