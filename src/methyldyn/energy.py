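"""Per-residue nonbonded interface energy decomposition.

Gas-phase molecular-mechanics terms only: Lennard-Jones
4ε[(σ/r)¹² − (σ/r)⁶] with Lorentz-Berthelot combining (arithmetic σ,
geometric ε) and screened Coulomb k·q_i·q_j/(ε_int·r) with an internal
dielectric of 4 by default, consistent with force-field practice for
buried interfaces.  Only enzyme↔substrate cross pairs are summed, so
intramolecular exclusions never arise.  Continuum-solvation and entropy
terms are deliberately not part of this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .constants import COULOMB_CONSTANT_KCAL
from .structures import AtomRecord, Selection, StructureError, Trajectory

__all__ = [
    "NonbondedParams",
    "ResidueEnergyRow",
    "pair_energy",
    "interface_decomposition",
    "interface_totals",
    "write_energy_csv",
]


@dataclass(frozen=True)
class NonbondedParams:
    dielectric: float = 4.0
    coulomb_constant: float = COULOMB_CONSTANT_KCAL  # kcal Å / (mol e²)
    cutoff: float | None = None                      # Å; None = all pairs

    def __post_init__(self) -> None:
        if self.dielectric <= 0:
            raise ValueError("dielectric must be positive")


@dataclass
class ResidueEnergyRow:
    chain: str
    residue_number: int
    residue_name: str
    vdw: float      # kcal/mol, trajectory averaged
    coulomb: float
    frames_averaged: int

    @property
    def total(self) -> float:
        return self.vdw + self.coulomb


def _require_params(atom: AtomRecord) -> tuple[float, float, float]:
    if atom.charge is None or atom.lj_sigma is None or atom.lj_epsilon is None:
        raise StructureError(
            f"atom {atom.chain_id}:{atom.residue_number}:{atom.name} is missing "
            "charge/LJ parameters"
        )
    return atom.charge, atom.lj_sigma, atom.lj_epsilon


def pair_energy(
    atom_i: AtomRecord,
    atom_j: AtomRecord,
    r: float,
    params: NonbondedParams | None = None,
) -> tuple[float, float]:
    """(vdw, coulomb) in kcal/mol for one atom pair at distance r (Å)."""
    params = params or NonbondedParams()
    if r <= 0:
        raise ValueError("pair distance must be positive")
    qi, si, ei = _require_params(atom_i)
    qj, sj, ej = _require_params(atom_j)
    sigma = 0.5 * (si + sj)
    eps = math.sqrt(ei * ej)
    sr6 = (sigma / r) ** 6
    vdw = 4.0 * eps * (sr6 * sr6 - sr6)
    coulomb = params.coulomb_constant * qi * qj / (params.dielectric * r)
    return vdw, coulomb


def interface_decomposition(
    traj: Trajectory,
    enzyme: Selection | Sequence[int],
    substrate: Selection | Sequence[int],
    params: NonbondedParams | None = None,
    window: tuple[int | None, int | None] | None = None,
) -> list[ResidueEnergyRow]:
    """Per-residue trajectory-averaged cross-interface energies, both sides.

    Each residue's row sums the pairwise energies between its atoms and every
    atom of the opposite selection, averaged over the window frames; rows are
    sorted most favourable (lowest total) first.
    """
    params = params or NonbondedParams()
    e_idx = enzyme.index_array if isinstance(enzyme, Selection) else np.asarray(enzyme, int)
    s_idx = substrate.index_array if isinstance(substrate, Selection) else np.asarray(substrate, int)
    if e_idx.size == 0 or s_idx.size == 0:
        raise StructureError("interface_decomposition: empty selection")
    if set(e_idx.tolist()) & set(s_idx.tolist()):
        raise StructureError("enzyme and substrate selections overlap")

    atoms = traj.structure.atoms
    def arrays(idx):
        q, s, e = [], [], []
        for i in idx:
            qi, si, ei = _require_params(atoms[i])
            q.append(qi); s.append(si); e.append(ei)
        return np.array(q), np.array(s), np.array(e)

    q_e, s_e, eps_e = arrays(e_idx)
    q_s, s_s, eps_s = arrays(s_idx)
    sigma = 0.5 * (s_e[:, None] + s_s[None, :])
    eps = np.sqrt(eps_e[:, None] * eps_s[None, :])
    qq = q_e[:, None] * q_s[None, :]

    xyz = traj.xyz
    if window is not None:
        xyz = xyz[slice(*window)]
    n_frames = xyz.shape[0]
    if n_frames == 0:
        raise StructureError("interface_decomposition: empty analysis window")

    vdw_acc = np.zeros(sigma.shape)
    cou_acc = np.zeros(sigma.shape)
    for f in range(n_frames):
        d = np.linalg.norm(
            xyz[f][e_idx][:, None, :] - xyz[f][s_idx][None, :, :], axis=2
        )
        sr6 = (sigma / d) ** 6
        vdw = 4.0 * eps * (sr6 * sr6 - sr6)
        cou = params.coulomb_constant * qq / (params.dielectric * d)
        if params.cutoff is not None:
            mask = d < params.cutoff
            vdw *= mask
            cou *= mask
        vdw_acc += vdw
        cou_acc += cou
    vdw_mean = vdw_acc / n_frames
    cou_mean = cou_acc / n_frames

    rows: list[ResidueEnergyRow] = []
    for side_idx, axis in ((e_idx, 1), (s_idx, 0)):
        per_res: dict[tuple[str, int, str], tuple[float, float]] = {}
        side_vdw = vdw_mean.sum(axis=axis)
        side_cou = cou_mean.sum(axis=axis)
        for pos, i in enumerate(side_idx):
            a = atoms[i]
            key = (a.chain_id, a.residue_number, a.residue_name)
            v, c = per_res.get(key, (0.0, 0.0))
            per_res[key] = (v + side_vdw[pos], c + side_cou[pos])
        for (chain, resnum, resname), (v, c) in per_res.items():
            rows.append(
                ResidueEnergyRow(
                    chain=chain,
                    residue_number=resnum,
                    residue_name=resname,
                    vdw=float(v),
                    coulomb=float(c),
                    frames_averaged=n_frames,
                )
            )
    rows.sort(key=lambda r: (r.total, r.chain, r.residue_number))
    return rows


def interface_totals(rows: Sequence[ResidueEnergyRow]) -> dict[str, tuple[float, float, float]]:
    """Per-chain (vdw, coulomb, total) sums; the two sides must agree."""
    totals: dict[str, list[float]] = {}
    for r in rows:
        acc = totals.setdefault(r.chain, [0.0, 0.0])
        acc[0] += r.vdw
        acc[1] += r.coulomb
    return {
        chain: (v, c, v + c) for chain, (v, c) in sorted(totals.items())
    }


def write_energy_csv(path: str | Path, rows: Sequence[ResidueEnergyRow]) -> None:
    lines = ["chain,residue_number,residue_name,vdw_kcal,coulomb_kcal,total_kcal,frames_averaged"]
    for r in rows:
        lines.append(
            f"{r.chain},{r.residue_number},{r.residue_name},"
            f"{r.vdw:.8g},{r.coulomb:.8g},{r.total:.8g},{r.frames_averaged}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
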