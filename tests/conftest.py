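"""Shared fixtures: small synthetic systems generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from methyldyn.geometry import dihedral_series
from methyldyn.synthetic import (
    NoiseModel,
    PocketSpec,
    RotamerKinetics,
    make_pocket_frame,
    simulate_rotamer_trajectory,
)

TINY_PDB = """\
TITLE     three-atom fixture
ATOM      1  N   ALA B   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA B   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA B   1       2.009   1.420   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    path = tmp_path / "tiny.pdb"
    path.write_text(TINY_PDB)
    return path


@pytest.fixture(scope="session")
def me3_pocket():
    return PocketSpec.symmetric(3)


@pytest.fixture(scope="session")
def me3_frame(me3_pocket):
    """Ideal noise-free me3 head parked in trans."""
    return make_pocket_frame(me3_pocket, state="t")


def head_indices(structure, names=("CD", "CE", "NZ", "CZ1")):
    return tuple(structure.index_of("B", 9, n) for n in names)


@pytest.fixture(scope="session")
def me3_traj():
    """Short symmetric-kinetics me3 trajectory with its hidden states."""
    traj, states = simulate_rotamer_trajectory(
        RotamerKinetics.symmetric(1.0),
        PocketSpec.symmetric(3),
        NoiseModel(),
        n_frames=20_000,
        dt=2.0,
        seed=42,
    )
    return traj, states


@pytest.fixture(scope="session")
def me3_quads(me3_traj):
    traj, _ = me3_traj
    s = traj.structure
    cd, ce, nz = (s.index_of("B", 9, n) for n in ("CD", "CE", "NZ"))
    return {
        name: (cd, ce, nz, s.index_of("B", 9, name))
        for name in ("CZ1", "CZ2", "CZ3")
    }
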