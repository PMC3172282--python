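"""Rigid rotation of the methylammonium head and steric-clash detection.

The head group is rotated rigidly about the CE→NZ axis (the rotation sign
follows the torsion convention of :mod:`methyldyn.geometry`: a rotation by δ
changes the CD-CE-NZ-CZx dihedral by exactly δ) and overlaps with the
surrounding pocket are scored by the van der Waals criterion
d(i, j) < r_i + r_j - tolerance.  Side chains are held fixed: this is a
single-pose contact test with no relaxation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import GeometryError, rodrigues_rotate
from .structures import Frame, Selection, StructureError, StructureModel

__all__ = [
    "VDW_RADII",
    "DEFAULT_TOLERANCE",
    "DEFAULT_SCAN_ANGLES",
    "ClashReport",
    "rotate_group",
    "detect_clashes",
    "rotation_scan",
]

#: element van der Waals radii (Å) used when atoms carry no override
VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "Fe": 1.30}

#: overlap tolerance (Å) subtracted from the radius sum
DEFAULT_TOLERANCE = 0.4

#: the canonical -120° scan visiting all three methyl slots
DEFAULT_SCAN_ANGLES = (0.0, -120.0, -240.0)


@dataclass
class ClashPair:
    head_atom: int
    environment_atom: int
    distance: float
    overlap: float  # (r_i + r_j - tolerance) - d, > 0 for listed pairs


@dataclass
class ClashReport:
    rotation_angle: float
    clashing_pairs: list[ClashPair]

    @property
    def clash_count(self) -> int:
        return len(self.clashing_pairs)


def _indices(sel: Selection | Sequence[int]) -> np.ndarray:
    return sel.index_array if isinstance(sel, Selection) else np.asarray(sel, dtype=int)


def rotate_group(
    frame: Frame,
    head: Selection | Sequence[int],
    axis_from: int,
    axis_to: int,
    angle: float,
) -> np.ndarray:
    """Rotate head atoms rigidly about the axis_from→axis_to line.

    Returns a full coordinate copy with only the head atoms moved.
    """
    coords = frame.coordinates.copy()
    idx = _indices(head)
    a0 = coords[axis_from]
    a1 = coords[axis_to]
    if np.linalg.norm(a1 - a0) < 1e-10:
        raise GeometryError("rotation axis atoms coincide")
    coords[idx] = rodrigues_rotate(coords[idx], a1, a1 - a0, angle)
    return coords


def _radius_for(structure: StructureModel, index: int) -> float:
    atom = structure.atoms[index]
    if atom.vdw_radius is not None:
        return atom.vdw_radius
    r = VDW_RADII.get(atom.element)
    if r is None:
        raise StructureError(
            f"no van der Waals radius for atom "
            f"{atom.chain_id}:{atom.residue_number}:{atom.name} (element {atom.element})"
        )
    return r


def detect_clashes(
    coords: np.ndarray,
    structure: StructureModel,
    head: Selection | Sequence[int],
    environment: Selection | Sequence[int],
    tolerance: float = DEFAULT_TOLERANCE,
    rotation_angle: float = 0.0,
) -> ClashReport:
    """Pairwise head-environment overlap census.

    Environment atoms belonging to the head's own residue (the covalent
    stem CD/CE/NZ and its neighbours) are excluded so that bonded contacts
    are not counted as clashes.
    """
    head_idx = _indices(head)
    env_idx = _indices(environment)
    if head_idx.size == 0 or env_idx.size == 0:
        raise StructureError("detect_clashes: empty head or environment selection")
    head_residues = {
        (structure.atoms[i].chain_id, structure.atoms[i].residue_number)
        for i in head_idx
    }
    env_idx = np.array(
        [
            j
            for j in env_idx
            if (structure.atoms[j].chain_id, structure.atoms[j].residue_number)
            not in head_residues
        ],
        dtype=int,
    )
    pairs: list[ClashPair] = []
    if env_idx.size:
        r_head = np.array([_radius_for(structure, i) for i in head_idx])
        r_env = np.array([_radius_for(structure, j) for j in env_idx])
        d = np.linalg.norm(
            coords[head_idx][:, None, :] - coords[env_idx][None, :, :], axis=2
        )
        threshold = r_head[:, None] + r_env[None, :] - tolerance
        for i, j in zip(*np.nonzero(d < threshold)):
            pairs.append(
                ClashPair(
                    head_atom=int(head_idx[i]),
                    environment_atom=int(env_idx[j]),
                    distance=float(d[i, j]),
                    overlap=float(threshold[i, j] - d[i, j]),
                )
            )
    return ClashReport(rotation_angle=rotation_angle, clashing_pairs=pairs)


def rotation_scan(
    frame: Frame,
    structure: StructureModel,
    head: Selection | Sequence[int],
    axis_from: int,
    axis_to: int,
    environment: Selection | Sequence[int],
    angles: Sequence[float] = DEFAULT_SCAN_ANGLES,
    tolerance: float = DEFAULT_TOLERANCE,
) -> list[ClashReport]:
    """Clash report at each rigid head rotation of ``angles``."""
    reports = []
    for angle in angles:
        coords = rotate_group(frame, head, axis_from, axis_to, angle)
        reports.append(
            detect_clashes(
                coords, structure, head, environment,
                tolerance=tolerance, rotation_angle=float(angle),
            )
        )
    return reports


def write_clash_csv(
    path: str | Path, structure: StructureModel, reports: Sequence[ClashReport]
) -> None:
    def tag(i: int) -> str:
        a = structure.atoms[i]
        return f"{a.chain_id}:{a.residue_name}{a.residue_number}:{a.name}"

    lines = ["angle_deg,head_atom,environment_atom,distance_A,overlap_A"]
    for rep in reports:
        if not rep.clashing_pairs:
            lines.append(f"{rep.rotation_angle:.6g},,,,")
        for p in rep.clashing_pairs:
            lines.append(
                f"{rep.rotation_angle:.6g},{tag(p.head_atom)},"
                f"{tag(p.environment_atom)},{p.distance:.6g},{p.overlap:.6g}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
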