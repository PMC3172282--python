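"""Synthetic rotamer-jump trajectories and geometric test fixtures.

The generator emulates the statistical structure the downstream analyses
assume: a methyllysine head whose torsion about the CE-NZ bond hops among
the three rotamer wells (g+ at +60°, g- at -60°, t at 180°) of a
discrete-time Markov chain, embedded in a rigid oxygen-lined pocket with an
Fe(II) site and optional waters.  Per-step transition probabilities follow
an Arrhenius form p(i→j) = κ·exp(-B(i→j)/kT) with a documented attempt
prefactor κ (default 0.1 per frame); forbidden transitions are encoded as
+inf barriers.  The hidden state sequence is returned alongside the
coordinates so that recovery tests have an exact oracle.

Geometry: the head is built at tetrahedral geometry about NZ (N-C bond
1.49 Å, CE-NZ-CZ angle 109.5°, successive methyls 120° apart in torsion).
The default pocket is an idealised symmetric oxygen cage (all NZ-O
distances 4.2 Å); the asymmetric variant pulls Asn290:OD1 and Gly170:O in
to 3.1 Å near the g+ slot, emulating the restricted environment of the
lower methylation states.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import DEFAULT_TEMPERATURE, K_BOLTZMANN_KCAL
from .rotamer import STATE_LABELS
from .structures import AtomRecord, Frame, StructureModel, Trajectory

__all__ = [
    "STATE_CENTERS",
    "RotamerKinetics",
    "PocketSpec",
    "NoiseModel",
    "HBondFixtureSpec",
    "simulate_rotamer_trajectory",
    "make_pocket_frame",
    "make_hbond_fixture",
    "make_peptide_fixture",
    "write_default_parameters",
    "write_sidecar",
]

#: torsion-well centres (degrees) in STATE_LABELS order (g+, g-, t)
STATE_CENTERS = {"g+": 60.0, "g-": -60.0, "t": 180.0}

_TETRAHEDRAL = 109.5   # degrees, CE-NZ-CZ cone angle
_NC_BOND = 1.49        # Å, N-CH3
_NH_BOND = 1.03        # Å, N-H for unsubstituted amine slots
_CE_NZ = 1.49          # Å


class KineticsError(ValueError):
    """Inconsistent or non-normalisable kinetic parameterisation."""


@dataclass(frozen=True)
class RotamerKinetics:
    """Relative state energies and transition barriers (kcal/mol).

    ``barrier_energies[(i, j)]`` is the barrier of the ordered transition
    i→j; +inf declares it forbidden.  Each barrier must be at least the
    uphill energy difference max(0, E_j - E_i).
    """

    state_energies: dict[str, float]
    barrier_energies: dict[tuple[str, str], float]
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        for s in STATE_LABELS:
            if s not in self.state_energies:
                raise KineticsError(f"missing state energy for {s!r}")
        for a in STATE_LABELS:
            for b in STATE_LABELS:
                if a == b:
                    continue
                bar = self.barrier_energies.get((a, b))
                if bar is None:
                    raise KineticsError(f"missing barrier for {(a, b)}")
                uphill = max(0.0, self.state_energies[b] - self.state_energies[a])
                if bar < uphill - 1e-9:
                    raise KineticsError(
                        f"barrier {(a, b)} = {bar} below uphill difference {uphill}"
                    )

    @property
    def kT(self) -> float:
        return K_BOLTZMANN_KCAL * self.temperature

    @classmethod
    def symmetric(
        cls, barrier: float, temperature: float = DEFAULT_TEMPERATURE
    ) -> "RotamerKinetics":
        """Equal state energies, one common barrier for all transitions."""
        return cls(
            state_energies={s: 0.0 for s in STATE_LABELS},
            barrier_energies={
                (a, b): barrier for a in STATE_LABELS for b in STATE_LABELS if a != b
            },
            temperature=temperature,
        )

    @classmethod
    def from_energies(
        cls,
        state_energies: dict[str, float],
        transition_state_energy: float | dict[frozenset, float],
        temperature: float = DEFAULT_TEMPERATURE,
    ) -> "RotamerKinetics":
        """Barriers from a shared (or per-pair) transition-state energy.

        B(i→j) = E_TS(ij) - E_i gives detailed balance with the Boltzmann
        stationary distribution of the state energies.
        """
        barriers = {}
        for a in STATE_LABELS:
            for b in STATE_LABELS:
                if a == b:
                    continue
                ts = (
                    transition_state_energy
                    if isinstance(transition_state_energy, (int, float))
                    else transition_state_energy[frozenset((a, b))]
                )
                barriers[(a, b)] = ts - state_energies[a]
        return cls(state_energies=dict(state_energies), barrier_energies=barriers,
                   temperature=temperature)

    @classmethod
    def pair_barriers(
        cls,
        barriers: dict[frozenset, float],
        temperature: float = DEFAULT_TEMPERATURE,
    ) -> "RotamerKinetics":
        """Symmetric per-pair barriers (equal state energies)."""
        full = {}
        for a in STATE_LABELS:
            for b in STATE_LABELS:
                if a != b:
                    full[(a, b)] = barriers[frozenset((a, b))]
        return cls(
            state_energies={s: 0.0 for s in STATE_LABELS},
            barrier_energies=full,
            temperature=temperature,
        )

    def transition_matrix(self, kappa: float = 0.1) -> np.ndarray:
        """Row-stochastic per-frame jump matrix in STATE_LABELS order."""
        n = len(STATE_LABELS)
        P = np.zeros((n, n))
        for i, a in enumerate(STATE_LABELS):
            for j, b in enumerate(STATE_LABELS):
                if i == j:
                    continue
                bar = self.barrier_energies[(a, b)]
                P[i, j] = 0.0 if math.isinf(bar) else kappa * math.exp(-bar / self.kT)
            leave = P[i].sum()
            if leave > 1.0:
                raise KineticsError(
                    f"total per-step transition probability {leave:.3f} > 1 "
                    f"from state {a!r}; reduce kappa or raise barriers"
                )
            P[i, i] = 1.0 - leave
        return P

    def stationary_distribution(self, kappa: float = 0.1) -> np.ndarray:
        """Stationary distribution of the jump chain by power iteration.

        Starting from the uniform distribution makes the result well
        defined (and deterministic) even when forbidden transitions leave
        the chain reducible.
        """
        P = self.transition_matrix(kappa)
        pi = np.full(len(STATE_LABELS), 1.0 / len(STATE_LABELS))
        for _ in range(200_000):
            nxt = pi @ P
            if np.abs(nxt - pi).sum() < 1e-13:
                pi = nxt
                break
            pi = nxt
        return pi / pi.sum()


@dataclass(frozen=True)
class NoiseModel:
    """Per-frame Gaussian perturbations: Cartesian jitter and torsion wobble."""

    jitter_sigma: float = 0.05    # Å, isotropic per atom per frame
    dihedral_sigma: float = 10.0  # degrees, within-well wobble

    def __post_init__(self) -> None:
        if self.jitter_sigma < 0 or self.dihedral_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class PocketSpec:
    """Rigid-pocket geometry: Fe site, labelled oxygens, waters, head stem."""

    fe_position: tuple[float, float, float]
    pocket_oxygen_positions: dict[str, tuple[float, float, float]]
    water_positions: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    cd_position: tuple[float, float, float] = (1.419, 0.0, 2.035)
    ce_position: tuple[float, float, float] = (0.0, 0.0, 1.49)
    nz_position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    methyl_count: int = 3

    def __post_init__(self) -> None:
        if not 1 <= self.methyl_count <= 3:
            raise ValueError("methyl_count must be 1, 2 or 3")
        d = np.linalg.norm(np.array(self.ce_position) - np.array(self.nz_position))
        if not 1.3 <= d <= 1.7:
            raise ValueError(f"CE-NZ distance {d:.3f} Å outside [1.3, 1.7]")

    # --- head-frame helpers -------------------------------------------------

    def _head_frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(nz, u=NZ→CE unit, r̂ torsion-zero reference, ŝ=â×r̂)."""
        nz = np.array(self.nz_position)
        ce = np.array(self.ce_position)
        cd = np.array(self.cd_position)
        u = _unit(ce - nz)
        axis = _unit(nz - ce)  # torsion rotation axis CE→NZ
        ref = cd - ce
        r_hat = _unit(ref - np.dot(ref, axis) * axis)
        s_hat = np.cross(axis, r_hat)
        return nz, u, r_hat, s_hat

    def slot_position(self, torsion_deg: float, bond: float = _NC_BOND) -> np.ndarray:
        """Substituent position at a given CD-CE-NZ-X torsion (degrees)."""
        nz, u, r_hat, s_hat = self._head_frame()
        theta = math.radians(_TETRAHEDRAL)
        phi = math.radians(torsion_deg)
        direction = (
            math.cos(theta) * u
            + math.sin(theta) * (math.cos(phi) * r_hat + math.sin(phi) * s_hat)
        )
        return nz + bond * direction

    def slot_positions_many(
        self, torsions_deg: np.ndarray, bond: float = _NC_BOND
    ) -> np.ndarray:
        """Vectorised :meth:`slot_position` over an array of torsions."""
        nz, u, r_hat, s_hat = self._head_frame()
        theta = math.radians(_TETRAHEDRAL)
        phi = np.radians(np.asarray(torsions_deg, dtype=float))[..., None]
        direction = (
            math.cos(theta) * u
            + math.sin(theta) * (np.cos(phi) * r_hat + np.sin(phi) * s_hat)
        )
        return nz + bond * direction

    # --- constructors -------------------------------------------------------

    @classmethod
    def symmetric(
        cls, methyl_count: int = 3, include_waters: bool = True
    ) -> "PocketSpec":
        """Idealised symmetric oxygen cage: every NZ-O distance 4.2 Å.

        Oxygens sit on a ring 140° from the NZ→CE direction (safely below
        the methyl cone) at seven evenly spaced azimuths; Fe(II) lies 5.0 Å
        from NZ along the trans-slot direction, so a trans methyl carbon is
        3.51 Å from Fe while gauche carbons stay beyond 5.5 Å.
        """
        base = cls(
            fe_position=(0.0, 0.0, 0.0),
            pocket_oxygen_positions={},
            methyl_count=methyl_count,
        )
        nz, u, r_hat, s_hat = base._head_frame()
        polar = math.radians(140.0)
        labels = [
            "Gly170:O", "Tyr175:OH", "Tyr177:OH", "Ser288:OG",
            "Asn290:OD1", "Glu190:OE1", "Glu190:OE2",
        ]
        oxygens = {}
        for k, label in enumerate(labels):
            az = math.radians(360.0 * k / len(labels))
            direction = (
                math.cos(polar) * u
                + math.sin(polar) * (math.cos(az) * r_hat + math.sin(az) * s_hat)
            )
            oxygens[label] = tuple(nz + 4.2 * direction)
        fe = nz + 5.0 * _unit(base.slot_position(180.0) - nz)
        waters = {}
        if include_waters:
            fe_dir = _unit(fe - nz)
            perp = _unit(np.cross(fe_dir, u))
            wat1_o = fe + 2.15 * perp
            waters = {"Wat1": tuple(wat1_o)}
        return cls(
            fe_position=tuple(fe),
            pocket_oxygen_positions=oxygens,
            water_positions=waters,
            methyl_count=methyl_count,
        )

    @classmethod
    def asymmetric(
        cls, methyl_count: int = 2, include_waters: bool = True
    ) -> "PocketSpec":
        """Restricted pocket: Asn290:OD1 and Gly170:O pulled in to 3.1 Å.

        Both sit near the g+ slot direction, so a head whose methyls occupy
        the g-/t slots is clash-free while a rotation placing a methyl into
        the g+ slot overlaps them — the restricted regime of the lower
        methylation states.
        """
        sym = cls.symmetric(methyl_count=methyl_count, include_waters=include_waters)
        nz = np.array(sym.nz_position)
        oxygens = dict(sym.pocket_oxygen_positions)
        oxygens["Asn290:OD1"] = tuple(nz + 3.1 * _unit(sym.slot_position(60.0) - nz))
        oxygens["Gly170:O"] = tuple(nz + 3.1 * _unit(sym.slot_position(80.0) - nz))
        return cls(
            fe_position=sym.fe_position,
            pocket_oxygen_positions=oxygens,
            water_positions=sym.water_positions,
            methyl_count=methyl_count,
        )


_HEAD_RESNAMES = {1: "M1L", 2: "M2L", 3: "M3L"}

ENZYME_CHAIN = "A"
SUBSTRATE_CHAIN = "B"
HEAD_RESIDUE = 9


def _pocket_structure(
    pocket: PocketSpec, include_hydrogens: bool
) -> tuple[StructureModel, np.ndarray, list[tuple[str, float, float]]]:
    """Static structure + static coordinates + head-slot plan.

    The slot plan lists (atom_name, torsion_offset_deg, bond_length) for the
    torsion-dependent head atoms, in atom order after the static block.
    """
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    serial = 1

    def add(name, element, resname, resnum, chain, xyz, backbone=False):
        nonlocal serial
        atoms.append(
            AtomRecord(
                serial=serial, name=name, element=element, residue_name=resname,
                residue_number=resnum, chain_id=chain, backbone_flag=backbone,
            )
        )
        coords.append(np.asarray(xyz, dtype=float))
        serial += 1

    resname_map = {
        "Gly170": ("GLY", 170), "Tyr175": ("TYR", 175), "Tyr177": ("TYR", 177),
        "Ser288": ("SER", 288), "Asn290": ("ASN", 290), "Glu190": ("GLU", 190),
    }
    for label, xyz in pocket.pocket_oxygen_positions.items():
        res_label, atom_name = label.split(":")
        resname, resnum = resname_map[res_label]
        add(atom_name, "O", resname, resnum, ENZYME_CHAIN, xyz,
            backbone=(atom_name == "O"))
    add("FE", "Fe", "FE", 400, ENZYME_CHAIN, pocket.fe_position)
    for w, (label, oxyz) in enumerate(sorted(pocket.water_positions.items())):
        o = np.asarray(oxyz, dtype=float)
        add("O", "O", "HOH", 401 + w, ENZYME_CHAIN, o)
        # water hydrogens at 0.96 Å, ~104.5° opening, oriented toward the pocket
        toward = _unit(np.array(pocket.nz_position) - o)
        perp = np.cross(toward, [0.0, 0.0, 1.0])
        perp = _unit(perp) if np.linalg.norm(perp) > 1e-8 else np.array([1.0, 0.0, 0.0])
        h1 = o + 0.96 * _unit(math.cos(math.radians(52.25)) * toward
                              + math.sin(math.radians(52.25)) * perp)
        h2 = o + 0.96 * _unit(math.cos(math.radians(52.25)) * toward
                              - math.sin(math.radians(52.25)) * perp)
        add("H1", "H", "HOH", 401 + w, ENZYME_CHAIN, h1)
        add("H2", "H", "HOH", 401 + w, ENZYME_CHAIN, h2)

    resname = _HEAD_RESNAMES[pocket.methyl_count]
    add("CD", "C", resname, HEAD_RESIDUE, SUBSTRATE_CHAIN, pocket.cd_position)
    add("CE", "C", resname, HEAD_RESIDUE, SUBSTRATE_CHAIN, pocket.ce_position)
    add("NZ", "N", resname, HEAD_RESIDUE, SUBSTRATE_CHAIN, pocket.nz_position)

    slot_plan: list[tuple[str, float, float]] = []
    for k in range(pocket.methyl_count):
        slot_plan.append((f"CZ{k + 1}", 120.0 * k, _NC_BOND))
    if include_hydrogens:
        for k in range(pocket.methyl_count, 3):
            slot_plan.append((f"HZ{k + 1}", 120.0 * k, _NH_BOND))
    for name, offset, bond in slot_plan:
        elem = "C" if name.startswith("C") else "H"
        add(name, elem, resname, HEAD_RESIDUE, SUBSTRATE_CHAIN,
            pocket.slot_position(offset, bond))

    return StructureModel(atoms), np.array(coords), slot_plan


def make_pocket_frame(
    pocket: PocketSpec,
    state: str = "t",
    torsion_deg: float | None = None,
    include_hydrogens: bool = False,
) -> tuple[StructureModel, Frame]:
    """Noise-free single frame with the head parked at a torsion.

    ``state`` picks a well centre; an explicit ``torsion_deg`` overrides it.
    Hydrogens on the amine slots are omitted by default (heavy-atom contact
    analysis).
    """
    tau = STATE_CENTERS[state] if torsion_deg is None else torsion_deg
    structure, coords, slot_plan = _pocket_structure(pocket, include_hydrogens)
    n_slots = len(slot_plan)
    for k, (name, offset, bond) in enumerate(slot_plan):
        coords[len(coords) - n_slots + k] = pocket.slot_position(tau + offset, bond)
    return structure, Frame(coords, time=0.0)


def simulate_rotamer_trajectory(
    kinetics: RotamerKinetics,
    pocket: PocketSpec,
    noise: NoiseModel,
    n_frames: int,
    dt: float,
    seed: int,
    kappa: float = 0.1,
    include_hydrogens: bool = True,
    initial_state: str | None = None,
) -> tuple[Trajectory, np.ndarray]:
    """Markov rotamer-jump trajectory plus the hidden true state sequence.

    A single seeded stream drives, in this order: the initial state (drawn
    from the stationary distribution unless ``initial_state`` pins it), the
    per-step jumps, the torsional wobble and finally the Cartesian jitter.
    All pocket atoms are static up to jitter; the head substituents follow
    the per-frame torsion state centre + wobble.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    P = kinetics.transition_matrix(kappa)
    pi = kinetics.stationary_distribution(kappa)

    cum = np.cumsum(P, axis=1)
    states_idx = np.empty(n_frames, dtype=int)
    if initial_state is not None:
        states_idx[0] = STATE_LABELS.index(initial_state)
    else:
        states_idx[0] = rng.choice(len(STATE_LABELS), p=pi)
    draws = rng.random(n_frames - 1)
    for f in range(1, n_frames):
        states_idx[f] = int(np.searchsorted(cum[states_idx[f - 1]], draws[f - 1],
                                            side="right"))
    labels = np.array(STATE_LABELS, dtype=object)[states_idx]

    centers = np.array([STATE_CENTERS[s] for s in STATE_LABELS])
    torsions = centers[states_idx]
    if noise.dihedral_sigma > 0:
        torsions = torsions + rng.normal(0.0, noise.dihedral_sigma, n_frames)

    structure, static_coords, slot_plan = _pocket_structure(pocket, include_hydrogens)
    n_atoms = structure.n_atoms
    n_slots = len(slot_plan)
    xyz = np.broadcast_to(static_coords, (n_frames, n_atoms, 3)).copy()
    for k, (name, offset, bond) in enumerate(slot_plan):
        xyz[:, n_atoms - n_slots + k] = pocket.slot_positions_many(
            torsions + offset, bond
        )
    if noise.jitter_sigma > 0:
        xyz += rng.normal(0.0, noise.jitter_sigma, xyz.shape)

    structure.title = (
        f"synthetic {_HEAD_RESNAMES[pocket.methyl_count]} rotamer trajectory seed={seed}"
    )
    frames = [Frame(xyz[f], time=f * dt) for f in range(n_frames)]
    return Trajectory(structure, frames, dt), labels


# ---------------------------------------------------------------------------
# constructed fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBondFixtureSpec:
    """A single donor/H/acceptor bond with a prescribed satisfied fraction."""

    fraction: float
    n_frames: int
    seed: int = 0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def make_hbond_fixture(spec: HBondFixtureSpec) -> Trajectory:
    """Trajectory whose one N-H···O bond holds in exactly round(f·n) frames.

    Satisfied frames use R = 2.9 Å, θ = 180°; violating frames alternate a
    distance violation (R = 3.3 Å) with an angle violation (θ = 105°), each
    clear of the strict criteria by at least 0.2 Å / 10°.
    """
    atoms = [
        AtomRecord(1, "N", "N", "ALA", 1, SUBSTRATE_CHAIN, backbone_flag=True),
        AtomRecord(2, "H", "H", "ALA", 1, SUBSTRATE_CHAIN, backbone_flag=True),
        AtomRecord(3, "O", "O", "GLY", 2, ENZYME_CHAIN, backbone_flag=True),
    ]
    structure = StructureModel(atoms, title=f"hbond fixture seed={spec.seed}")
    n = spec.n_frames
    k = round(spec.fraction * n)
    rng = np.random.default_rng(spec.seed)
    satisfied = np.zeros(n, dtype=bool)
    satisfied[rng.permutation(n)[:k]] = True

    d = np.array([0.0, 0.0, 0.0])
    h = np.array([1.0, 0.0, 0.0])
    a_ok = np.array([2.9, 0.0, 0.0])
    a_far = np.array([3.3, 0.0, 0.0])
    # θ = 105° at R_HA = 1.8 Å: rejected on angle, not distance
    ang = math.radians(105.0)
    a_bent = h + 1.8 * np.array([-math.cos(ang), math.sin(ang), 0.0])

    frames = []
    bad_parity = 0
    for f in range(n):
        if satisfied[f]:
            acc = a_ok
        else:
            acc = a_far if bad_parity % 2 == 0 else a_bent
            bad_parity += 1
        frames.append(Frame(np.array([d, h, acc]), time=f * spec.dt))
    return Trajectory(structure, frames, spec.dt)


def make_peptide_fixture(
    n_residues: int, w_shape: bool = False
) -> tuple[StructureModel, Frame]:
    """Backbone-only peptide trace (N/CA/C/O per residue) for RMSD tests.

    With ``w_shape`` the CA z-profile follows cos(4π·i/(n-1)), giving the
    two-arc (W-shaped) trace with exactly two interior local minima.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    atoms = []
    coords = []
    serial = 1
    for i in range(n_residues):
        z = 2.0 * math.cos(4.0 * math.pi * i / (n_residues - 1)) if w_shape else 0.0
        ca = np.array([3.8 * i, 0.0, z])
        offsets = {
            "N": np.array([-1.2, 0.6, 0.0]),
            "CA": np.array([0.0, 0.0, 0.0]),
            "C": np.array([1.2, 0.6, 0.0]),
            "O": np.array([1.4, 1.8, 0.0]),
        }
        for name, off in offsets.items():
            atoms.append(
                AtomRecord(
                    serial=serial, name=name, element=name[0], residue_name="GLY",
                    residue_number=i + 1, chain_id=SUBSTRATE_CHAIN, backbone_flag=True,
                )
            )
            coords.append(ca + off)
            serial += 1
    return StructureModel(atoms, title="peptide fixture"), Frame(np.array(coords))


# ---------------------------------------------------------------------------
# parameters and sidecars
# ---------------------------------------------------------------------------

# toy nonbonded parameters for the synthetic vocabulary: the methylammonium
# head carries ~+1 e in total, oxygens are partial-negative
_PARAM_ROWS: list[tuple[str, str, float, float, float, float]] = []
for _res in ("M1L", "M2L", "M3L"):
    _PARAM_ROWS += [
        (_res, "CD", 0.00, 3.40, 0.10, 1.70),
        (_res, "CE", 0.25, 3.40, 0.10, 1.70),
        (_res, "NZ", -0.30, 3.25, 0.17, 1.55),
        (_res, "CZ1", 0.35, 3.40, 0.10, 1.70),
        (_res, "CZ2", 0.35, 3.40, 0.10, 1.70),
        (_res, "CZ3", 0.35, 3.40, 0.10, 1.70),
        (_res, "HZ1", 0.35, 1.07, 0.016, 1.20),
        (_res, "HZ2", 0.35, 1.07, 0.016, 1.20),
        (_res, "HZ3", 0.35, 1.07, 0.016, 1.20),
    ]
_PARAM_ROWS += [
    ("GLY", "O", -0.50, 2.96, 0.21, 1.52),
    ("TYR", "OH", -0.55, 3.07, 0.21, 1.52),
    ("SER", "OG", -0.55, 3.07, 0.21, 1.52),
    ("ASN", "OD1", -0.50, 2.96, 0.21, 1.52),
    ("GLU", "OE1", -0.60, 2.96, 0.21, 1.52),
    ("GLU", "OE2", -0.60, 2.96, 0.21, 1.52),
    ("FE", "FE", 2.00, 2.00, 0.05, 1.30),
    ("HOH", "O", -0.834, 3.15, 0.152, 1.52),
    ("HOH", "H1", 0.417, 1.00, 0.01, 1.20),
    ("HOH", "H2", 0.417, 1.00, 0.01, 1.20),
    ("ALA", "N", -0.40, 3.25, 0.17, 1.55),
    ("ALA", "H", 0.25, 1.07, 0.016, 1.20),
]


def write_default_parameters(path: str | Path) -> None:
    """Write the packaged toy parameter sidecar for synthetic structures."""
    lines = ["residue_name,atom_name,charge,lj_sigma,lj_epsilon,vdw_radius"]
    for res, name, q, s, e, r in _PARAM_ROWS:
        lines.append(f"{res},{name},{q},{s},{e},{r}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_sidecar(
    path: str | Path,
    seed: int,
    states: np.ndarray,
    parameters: dict,
) -> None:
    """JSON sidecar with the hidden state sequence and generation parameters."""
    payload = {
        "seed": seed,
        "parameters": parameters,
        "states": list(map(str, states)),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
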