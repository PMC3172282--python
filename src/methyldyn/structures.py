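"""Structure/trajectory data model and readers/writers for PDB, XYZ and CSV.

Conventions used throughout the package: coordinates in Å, times in ps,
energies in kcal/mol, angles in degrees on (-180, +180].

The main-chain atom set is ``{N, CA, C, O, OXT, H, HA, H1, H2, H3}``; every
other atom is side chain.  Water residues (HOH/WAT) are treated as
side-chain-only regardless of atom name, so that waters are classified as
distinct entities rather than protein backbone.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "StructureModel",
    "Frame",
    "Trajectory",
    "Selection",
    "SelectionClause",
    "StructureError",
    "SelectionError",
    "ParameterError",
    "MAIN_CHAIN_ATOMS",
    "WATER_RESIDUES",
    "read_structure",
    "read_trajectory",
    "read_parameters",
    "resolve_selection",
    "parse_selection",
    "write_structure",
    "write_trajectory",
]

MAIN_CHAIN_ATOMS = frozenset({"N", "CA", "C", "O", "OXT", "H", "HA", "H1", "H2", "H3"})
WATER_RESIDUES = frozenset({"HOH", "WAT"})

# two-letter element symbols recognised during name-based inference;
# "CA" is deliberately absent (alpha carbon, not calcium)
_TWO_LETTER = frozenset({"FE", "ZN", "MG", "MN", "NA", "CL", "BR", "SE", "CU", "NI"})


class StructureError(ValueError):
    """Malformed or inconsistent structure/trajectory input."""


class SelectionError(StructureError):
    """A selection resolved to no atoms or referenced unknown atoms."""


class ParameterError(StructureError):
    """Invalid nonbonded-parameter sidecar table."""


def infer_element(name: str, residue_name: str = "") -> str:
    """Infer an element symbol from a PDB atom name.

    Digits and spaces are stripped; a leading two-letter metal/halogen symbol
    wins, otherwise the first alphabetic character is the element.
    """
    stripped = re.sub(r"[\d\s']", "", name).upper()
    if not stripped:
        raise StructureError(f"cannot infer element from atom name {name!r}")
    if stripped in _TWO_LETTER:
        return stripped.capitalize()
    return stripped[0]


def is_main_chain(name: str, residue_name: str) -> bool:
    return name in MAIN_CHAIN_ATOMS and residue_name not in WATER_RESIDUES


@dataclass
class AtomRecord:
    """One atom: identity, classification and optional nonbonded parameters."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    backbone_flag: bool = False
    charge: float | None = None     # elementary charges
    lj_sigma: float | None = None   # Å
    lj_epsilon: float | None = None  # kcal/mol
    vdw_radius: float | None = None  # Å

    def __post_init__(self) -> None:
        if self.serial <= 0:
            raise StructureError(f"atom serial must be positive, got {self.serial}")

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_RESIDUES

    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.name)


@dataclass
class StructureModel:
    """An ordered list of atoms; the frame of reference for all selections."""

    atoms: list[AtomRecord]
    title: str = ""

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            dup = sorted({s for s in serials if serials.count(s) > 1})
            raise StructureError(f"duplicate atom serials: {dup[:5]}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def index_of(self, chain_id: str, residue_number: int, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.chain_id == chain_id and a.residue_number == residue_number and a.name == name:
                return i
        raise SelectionError(f"no atom {chain_id}:{residue_number}:{name}")

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id)
        return list(seen)


@dataclass
class Frame:
    """Coordinates (n_atoms, 3) in Å at a single time point (ps)."""

    coordinates: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise StructureError(
                f"frame coordinates must be (n, 3), got {self.coordinates.shape}"
            )


@dataclass
class Trajectory:
    structure: StructureModel
    frames: list[Frame]
    dt: float  # ps

    def __post_init__(self) -> None:
        n = self.structure.n_atoms
        for i, fr in enumerate(self.frames):
            if fr.coordinates.shape[0] != n:
                raise StructureError(
                    f"frame {i}: {fr.coordinates.shape[0]} atoms, structure has {n}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    @property
    def xyz(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) coordinate stack."""
        return np.stack([fr.coordinates for fr in self.frames])

    def window(self, start: int | None = None, stop: int | None = None) -> "Trajectory":
        """Frame-window view [start, stop) as a new Trajectory."""
        sub = self.frames[slice(start, stop)]
        if not sub:
            raise StructureError(f"window [{start}:{stop}] selects no frames")
        return Trajectory(self.structure, list(sub), self.dt)


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionClause:
    """(chain, residue range, atom-name set) triple; None means "any"."""

    chain: str | None = None
    residues: tuple[int, int] | None = None  # inclusive range
    names: frozenset[str] | None = None
    backbone_only: bool = False

    def matches(self, atom: AtomRecord) -> bool:
        if self.chain is not None and atom.chain_id != self.chain:
            return False
        if self.residues is not None and not (
            self.residues[0] <= atom.residue_number <= self.residues[1]
        ):
            return False
        if self.backbone_only and not atom.backbone_flag:
            return False
        if self.names is not None and atom.name not in self.names:
            return False
        return True


@dataclass(frozen=True)
class Selection:
    clauses: tuple[SelectionClause, ...]
    indices: tuple[int, ...]  # unique, sorted

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def index_array(self) -> np.ndarray:
        return np.array(self.indices, dtype=int)


def parse_selection(spec: str) -> list[SelectionClause]:
    """Parse ``"CHAIN:RESRANGE:NAMES"`` clauses separated by ``;``.

    RESRANGE is ``*``, a single number or ``lo-hi``; NAMES is ``*``,
    ``backbone`` or a comma-separated atom-name list.  ``*`` for CHAIN matches
    any chain.  Example: ``"B:9:CZ1,CZ2,CZ3"``; ``"B:*:backbone"``.
    """
    clauses = []
    for raw in spec.split(";"):
        parts = raw.strip().split(":")
        if len(parts) != 3:
            raise SelectionError(f"bad selection clause {raw!r}: want CHAIN:RES:NAMES")
        chain_s, res_s, names_s = (p.strip() for p in parts)
        chain = None if chain_s in ("*", "") else chain_s
        if res_s in ("*", ""):
            residues = None
        elif "-" in res_s[1:]:
            cut = res_s.index("-", 1)
            residues = (int(res_s[:cut]), int(res_s[cut + 1 :]))
        else:
            residues = (int(res_s), int(res_s))
        backbone = False
        names: frozenset[str] | None
        if names_s in ("*", ""):
            names = None
        elif names_s.lower() == "backbone":
            names = None
            backbone = True
        else:
            names = frozenset(n.strip() for n in names_s.split(","))
        clauses.append(SelectionClause(chain, residues, names, backbone))
    return clauses


def resolve_selection(
    structure: StructureModel, spec: str | Sequence[SelectionClause]
) -> Selection:
    """Resolve a selection expression to a sorted, unique atom-index list.

    Raises :class:`SelectionError` on an empty result — never silently.
    """
    clauses = tuple(parse_selection(spec) if isinstance(spec, str) else spec)
    hits = {
        i
        for i, atom in enumerate(structure.atoms)
        if any(c.matches(atom) for c in clauses)
    }
    if not hits:
        raise SelectionError(f"selection {spec!r} matched no atoms")
    return Selection(clauses, tuple(sorted(hits)))


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _parse_pdb_atom_line(line: str, lineno: int) -> tuple[AtomRecord, np.ndarray, str]:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16]
        resname = line[17:21].strip()
        chain = line[21].strip() or " "
        resnum = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise StructureError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc
    element = line[76:78].strip() if len(line) >= 77 else ""
    if not element:
        element = infer_element(name, resname)
    else:
        element = element.capitalize() if len(element) > 1 else element.upper()
    atom = AtomRecord(
        serial=serial,
        name=name,
        element=element,
        residue_name=resname,
        residue_number=resnum,
        chain_id=chain,
        backbone_flag=is_main_chain(name, resname),
    )
    return atom, np.array([x, y, z]), altloc


def read_structure(path: str | Path, dialect: str = "pdb") -> StructureModel:
    """Read a PDB file's first model into a StructureModel.

    altLoc indicators other than blank/'A' are dropped; backbone flags are
    assigned from the main-chain atom-name set.
    """
    if dialect != "pdb":
        raise StructureError(f"unsupported structure dialect {dialect!r}")
    path = Path(path)
    atoms: list[AtomRecord] = []
    title = ""
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6]
        if rec.startswith("TITLE"):
            title = (title + " " + line[10:].strip()).strip()
        elif rec in ("ATOM  ", "HETATM"):
            atom, _, altloc = _parse_pdb_atom_line(line, lineno)
            if altloc not in (" ", "A", ""):
                continue
            atoms.append(atom)
        elif rec.startswith("ENDMDL"):
            break
    if not atoms:
        raise StructureError(f"{path}: no ATOM/HETATM records found")
    return StructureModel(atoms, title=title)


def _read_pdb_frames(path: Path, n_atoms: int) -> list[np.ndarray]:
    frames: list[np.ndarray] = []
    current: list[np.ndarray] = []
    in_model = False
    saw_model_card = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            saw_model_card = True
            in_model = True
            current = []
        elif rec in ("ATOM  ", "HETATM"):
            _, coords, altloc = _parse_pdb_atom_line(line, lineno)
            if altloc not in (" ", "A", ""):
                continue
            current.append(coords)
        elif rec.startswith("ENDMDL"):
            frames.append(np.array(current))
            in_model = False
            current = []
    if current and (in_model or not saw_model_card):
        frames.append(np.array(current))
    return frames


def read_trajectory(
    path: str | Path,
    structure: StructureModel,
    dt: float,
    dialect: str | None = None,
) -> Trajectory:
    """Read a multi-model PDB or XYZ trajectory against a known structure.

    Frame times are assigned as 0, dt, 2·dt, …; any frame whose atom count
    differs from the structure raises an error naming that frame index.
    """
    path = Path(path)
    if dialect is None:
        dialect = "xyz" if path.suffix.lower() == ".xyz" else "pdb"
    if dialect == "pdb":
        raw = _read_pdb_frames(path, structure.n_atoms)
    elif dialect == "xyz":
        raw = _read_xyz_frames(path)
    else:
        raise StructureError(f"unsupported trajectory dialect {dialect!r}")
    if not raw:
        raise StructureError(f"{path}: no frames found")
    frames = []
    for i, coords in enumerate(raw):
        if coords.shape[0] != structure.n_atoms:
            raise StructureError(
                f"frame {i}: atom count {coords.shape[0]} does not match "
                f"structure ({structure.n_atoms})"
            )
        frames.append(Frame(coords, time=i * dt))
    return Trajectory(structure, frames, dt)


def _read_xyz_frames(path: Path) -> list[np.ndarray]:
    lines = path.read_text().splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].strip())
        except ValueError as exc:
            raise StructureError(f"{path}: bad XYZ count line at line {i + 1}") from exc
        block = lines[i + 2 : i + 2 + count]
        if len(block) < count:
            raise StructureError(f"{path}: truncated XYZ frame at line {i + 1}")
        coords = []
        for j, row in enumerate(block):
            parts = row.split()
            if len(parts) < 4:
                raise StructureError(f"{path}: bad XYZ atom line at line {i + 3 + j}")
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        frames.append(np.array(coords))
        i += 2 + count
    return frames


def _format_pdb_atom(atom: AtomRecord, xyz: np.ndarray) -> str:
    rec = "HETATM" if (atom.is_water or atom.residue_name in ("FE", "FE2", "NOG")) else "ATOM  "
    name = atom.name
    if len(name) < 4 and len(atom.element) == 1:
        name = " " + name
    elem = atom.element.upper()
    return (
        f"{rec}{atom.serial:>5d} {name:<4s} {atom.residue_name:<4s}"
        f"{atom.chain_id:1s}{atom.residue_number:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {elem:>2s}"
    )


def write_structure(
    structure: StructureModel, frame: Frame, path: str | Path
) -> None:
    """Write one model as fixed-column PDB (3-decimal coordinates)."""
    path = Path(path)
    lines = []
    if structure.title:
        lines.append(f"TITLE     {structure.title}")
    for atom, xyz in zip(structure.atoms, frame.coordinates):
        lines.append(_format_pdb_atom(atom, xyz))
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def write_trajectory(traj: Trajectory, path: str | Path, dialect: str | None = None) -> None:
    """Write a trajectory as multi-model PDB or XYZ (chosen by suffix)."""
    path = Path(path)
    if dialect is None:
        dialect = "xyz" if path.suffix.lower() == ".xyz" else "pdb"
    lines = []
    if dialect == "pdb":
        if traj.structure.title:
            lines.append(f"TITLE     {traj.structure.title}")
        for m, fr in enumerate(traj.frames, start=1):
            lines.append(f"MODEL     {m:>4d}")
            for atom, xyz in zip(traj.structure.atoms, fr.coordinates):
                lines.append(_format_pdb_atom(atom, xyz))
            lines.append("ENDMDL")
        lines.append("END")
    elif dialect == "xyz":
        for fr in traj.frames:
            lines.append(str(traj.structure.n_atoms))
            lines.append(f"t= {fr.time:.3f} ps {traj.structure.title}")
            for atom, xyz in zip(traj.structure.atoms, fr.coordinates):
                lines.append(
                    f"{atom.element:<2s} {xyz[0]:12.6f} {xyz[1]:12.6f} {xyz[2]:12.6f}"
                )
    else:
        raise StructureError(f"unsupported trajectory dialect {dialect!r}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# parameter sidecar
# ---------------------------------------------------------------------------

def read_parameters(
    structure: StructureModel, path: str | Path
) -> tuple[StructureModel, list[str]]:
    """Annotate atoms with charges/LJ parameters from a sidecar CSV.

    The table is keyed by (residue_name, atom_name) with columns
    ``residue_name,atom_name,charge,lj_sigma,lj_epsilon,vdw_radius``.
    Returns the annotated structure plus a report of unmatched table keys and
    unannotated atoms.  A duplicate key in the table is a validation error.
    """
    df = pd.read_csv(path)
    required = {"residue_name", "atom_name"}
    if not required.issubset(df.columns):
        raise ParameterError(f"parameter table must have columns {sorted(required)}")
    keys = list(zip(df["residue_name"], df["atom_name"]))
    if len(set(keys)) != len(keys):
        dup = sorted({k for k in keys if keys.count(k) > 1})
        raise ParameterError(f"duplicate parameter keys: {dup[:5]}")
    table = {
        (str(r.residue_name), str(r.atom_name)): r for r in df.itertuples(index=False)
    }
    matched_keys: set[tuple[str, str]] = set()
    warnings: list[str] = []
    new_atoms = []
    for atom in structure.atoms:
        key = (atom.residue_name, atom.name)
        row = table.get(key)
        if row is None:
            warnings.append(f"atom {atom.chain_id}:{atom.residue_number}:{atom.name} unmatched")
            new_atoms.append(atom)
            continue
        matched_keys.add(key)
        kwargs = {}
        for col, attr in (
            ("charge", "charge"),
            ("lj_sigma", "lj_sigma"),
            ("lj_epsilon", "lj_epsilon"),
            ("vdw_radius", "vdw_radius"),
        ):
            val = getattr(row, col, None)
            if val is not None and not pd.isna(val):
                kwargs[attr] = float(val)
        new_atoms.append(replace(atom, **kwargs))
    for key in table:
        if key not in matched_keys:
            warnings.append(f"table key {key} matched no atom")
    return StructureModel(new_atoms, title=structure.title), warnings
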