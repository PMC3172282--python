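"""Geometric hydrogen-bond detection, occupancy and classification.

Two criteria sets are packaged.  The strict criteria (R < 3.00 Å,
120° < θ ≤ 180°) select conventional N/O-donor hydrogen bonds; the loose
criteria (R < 3.4 Å, same angle window) extend the donor set to carbon so
that weak C-H···O interactions can be screened.  R is the donor-acceptor
heavy-atom distance by default; θ is the donor-hydrogen-acceptor angle.

Donor-hydrogen pairing is purely name based (no bond graph is read): an
explicit residue/hydrogen-name map covers the common vocabulary and a
prefix heuristic (strip trailing digits, match the stem against N/O/C atom
names in the residue) covers the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .structures import Frame, StructureError, StructureModel, Trajectory

__all__ = [
    "HBondCriteria",
    "HBondRecord",
    "enumerate_dha_triples",
    "detect_frame",
    "hbond_occupancy",
    "classify_bond",
    "write_hbond_csv",
]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria.

    ``distance_definition`` selects which R the ``r_max`` cutoff applies to:
    the conventional donor-acceptor heavy-atom distance (default) or the
    hydrogen-acceptor distance.
    """

    r_max: float = 3.00          # Å
    theta_min: float = 120.0     # degrees
    theta_max: float = 180.0
    distance_definition: str = "donor-acceptor"

    def __post_init__(self) -> None:
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        if not (0.0 <= self.theta_min < self.theta_max <= 180.0):
            raise ValueError("need 0 <= theta_min < theta_max <= 180")
        if self.distance_definition not in ("donor-acceptor", "hydrogen-acceptor"):
            raise ValueError(f"unknown distance definition {self.distance_definition!r}")

    @classmethod
    def strict(cls) -> "HBondCriteria":
        return cls(r_max=3.00)

    @classmethod
    def cho(cls) -> "HBondCriteria":
        """Loosened criteria used when screening weak C-H···O bonds."""
        return cls(r_max=3.4)


@dataclass
class HBondRecord:
    donor: int
    hydrogen: int
    acceptor: int
    occupancy: float = 0.0
    mean_distance: float = float("nan")            # Å, over satisfied frames
    mean_linearity_deviation: float = float("nan")  # 180 - θ, over satisfied frames
    donor_class: str = ""    # "main chain" / "side chain"
    acceptor_class: str = ""
    span_class: str = ""     # "interface" / "intra-substrate" / "intra-enzyme"


# explicit donor-hydrogen name map; "*" matches any residue
_H_NAME_MAP: dict[tuple[str, str], str] = {
    ("HOH", "H1"): "O",
    ("HOH", "H2"): "O",
    ("WAT", "H1"): "O",
    ("WAT", "H2"): "O",
    ("*", "H"): "N",
    ("*", "H1"): "N",
    ("*", "H2"): "N",
    ("*", "H3"): "N",
    ("*", "HA"): "CA",
}


def _heavy_for_hydrogen(
    residue_atoms: dict[str, int], residue_name: str, h_name: str
) -> str | None:
    """Attached heavy-atom name for a hydrogen, by map then prefix heuristic."""
    for key in ((residue_name, h_name), ("*", h_name)):
        heavy = _H_NAME_MAP.get(key)
        if heavy is not None:
            return heavy if heavy in residue_atoms else None
    stem = h_name[1:]
    while True:
        if stem:
            for elem in ("N", "O", "C", "S"):
                cand = elem + stem
                if cand in residue_atoms:
                    return cand
        if stem and stem[-1].isdigit():
            stem = stem[:-1]
        else:
            return None


def enumerate_dha_triples(
    structure: StructureModel, mode: str = "strict"
) -> list[tuple[int, int, int]]:
    """All candidate donor/hydrogen/acceptor triples.

    strict mode: donors are N/O heavy atoms paired with a hydrogen by name;
    cho mode additionally admits C-H donor pairs.  Acceptors are all N/O
    atoms outside the donor's residue.
    """
    if mode not in ("strict", "cho"):
        raise ValueError(f"unknown mode {mode!r}")
    atoms = structure.atoms
    if not any(a.element == "H" for a in atoms):
        raise StructureError(
            "structure contains no hydrogens; geometric donor-H-acceptor "
            "criteria cannot apply"
        )
    donor_elements = {"N", "O"} if mode == "strict" else {"N", "O", "C"}

    residues: dict[tuple[str, int, str], dict[str, int]] = {}
    for i, a in enumerate(atoms):
        residues.setdefault((a.chain_id, a.residue_number, a.residue_name), {})[a.name] = i

    donor_pairs: list[tuple[int, int]] = []
    for (chain, resnum, resname), names in residues.items():
        for name, h_idx in names.items():
            if atoms[h_idx].element != "H":
                continue
            heavy_name = _heavy_for_hydrogen(names, resname, name)
            if heavy_name is None:
                continue
            d_idx = names[heavy_name]
            if atoms[d_idx].element in donor_elements:
                donor_pairs.append((d_idx, h_idx))

    acceptors = [i for i, a in enumerate(atoms) if a.element in ("N", "O")]
    triples = []
    for d, h in donor_pairs:
        d_res = (atoms[d].chain_id, atoms[d].residue_number)
        for acc in acceptors:
            if acc == d:
                continue
            if (atoms[acc].chain_id, atoms[acc].residue_number) == d_res:
                continue
            triples.append((d, h, acc))
    return triples


def _geometry(
    coords: np.ndarray, triples: Sequence[tuple[int, int, int]]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-triple (R_DA, R_HA, theta) for one frame."""
    idx = np.asarray(triples, dtype=int)
    d, h, a = coords[idx[:, 0]], coords[idx[:, 1]], coords[idx[:, 2]]
    r_da = np.linalg.norm(a - d, axis=1)
    r_ha = np.linalg.norm(a - h, axis=1)
    v1 = d - h
    v2 = a - h
    cos = np.einsum("ij,ij->i", v1, v2) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
    )
    theta = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    return r_da, r_ha, theta


def _satisfied(
    coords: np.ndarray,
    triples: Sequence[tuple[int, int, int]],
    criteria: HBondCriteria,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    r_da, r_ha, theta = _geometry(coords, triples)
    r = r_da if criteria.distance_definition == "donor-acceptor" else r_ha
    ok = (r < criteria.r_max) & (theta > criteria.theta_min) & (theta <= criteria.theta_max)
    return ok, r, theta


def detect_frame(
    frame: Frame,
    triples: Sequence[tuple[int, int, int]],
    criteria: HBondCriteria | None = None,
) -> list[tuple[int, int, int]]:
    """Triples satisfying the criteria in a single frame."""
    if not triples:
        return []
    criteria = criteria or HBondCriteria.strict()
    ok, _, _ = _satisfied(frame.coordinates, triples, criteria)
    return [t for t, flag in zip(triples, ok) if flag]


def hbond_occupancy(
    traj: Trajectory,
    triples: Sequence[tuple[int, int, int]],
    criteria: HBondCriteria | None = None,
    window: tuple[int | None, int | None] | None = None,
) -> list[HBondRecord]:
    """Per-triple occupancy over a frame window.

    One record is returned per triple satisfied in at least one frame;
    occupancy is satisfied frames / window frames, while the mean distance
    and mean deviation from linearity average over satisfied frames only.
    """
    criteria = criteria or HBondCriteria.strict()
    xyz = traj.xyz
    if window is not None:
        xyz = xyz[slice(*window)]
    n_frames = xyz.shape[0]
    if n_frames == 0:
        raise StructureError("hbond_occupancy: empty analysis window")
    if not triples:
        return []
    m = len(triples)
    sat_count = np.zeros(m, dtype=int)
    dist_sum = np.zeros(m)
    dev_sum = np.zeros(m)
    for f in range(n_frames):
        ok, r, theta = _satisfied(xyz[f], triples, criteria)
        sat_count += ok
        dist_sum[ok] += r[ok]
        dev_sum[ok] += 180.0 - theta[ok]
    records = []
    for k, triple in enumerate(triples):
        if sat_count[k] == 0:
            continue
        records.append(
            HBondRecord(
                donor=triple[0],
                hydrogen=triple[1],
                acceptor=triple[2],
                occupancy=sat_count[k] / n_frames,
                mean_distance=dist_sum[k] / sat_count[k],
                mean_linearity_deviation=dev_sum[k] / sat_count[k],
            )
        )
    return records


def classify_bond(
    record: HBondRecord,
    structure: StructureModel,
    substrate_chain: str,
    enzyme_chain: str,
) -> HBondRecord:
    """Assign main-chain/side-chain and interface/intra-chain classes.

    Waters carry no backbone flag, so they classify as side chain; the span
    class follows the chain identities (interface when donor and acceptor
    chains differ).
    """
    donor = structure.atoms[record.donor]
    acceptor = structure.atoms[record.acceptor]
    for atom in (donor, acceptor):
        if atom.chain_id not in (substrate_chain, enzyme_chain):
            raise StructureError(
                f"atom {atom.chain_id}:{atom.residue_number}:{atom.name} is on "
                f"neither declared chain ({substrate_chain!r}/{enzyme_chain!r})"
            )
    def cls(atom) -> str:
        return "main chain" if atom.backbone_flag else "side chain"

    if donor.chain_id != acceptor.chain_id:
        span = "interface"
    elif donor.chain_id == substrate_chain:
        span = "intra-substrate"
    else:
        span = "intra-enzyme"
    return replace(
        record,
        donor_class=cls(donor),
        acceptor_class=cls(acceptor),
        span_class=span,
    )


def write_hbond_csv(
    path: str | Path, structure: StructureModel, records: Sequence[HBondRecord]
) -> None:
    def tag(i: int) -> str:
        a = structure.atoms[i]
        return f"{a.chain_id}:{a.residue_name}{a.residue_number}:{a.name}"

    lines = [
        "donor,hydrogen,acceptor,occupancy,mean_distance_A,"
        "mean_linearity_deviation_deg,donor_class,acceptor_class,span_class"
    ]
    for r in records:
        lines.append(
            f"{tag(r.donor)},{tag(r.hydrogen)},{tag(r.acceptor)},"
            f"{r.occupancy:.6g},{r.mean_distance:.6g},"
            f"{r.mean_linearity_deviation:.6g},"
            f"{r.donor_class},{r.acceptor_class},{r.span_class}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
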