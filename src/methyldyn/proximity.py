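"""Sphere-occupancy and distance statistics around reference atoms.

The central statistic is the fraction of trajectory frames in which target
atoms (methyl carbons) lie strictly within a sphere of given radius around a
reference atom (the catalytic Fe(II)).  Three variants are reported side by
side: the per-atom fractions, their arithmetic sum, and the union fraction
(≥ 1 target inside).  Sum and union coincide exactly in the single-occupancy
regime where at most one target is ever inside at once.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .structures import Selection, StructureError, Trajectory

__all__ = [
    "OccupancyResult",
    "DistanceStats",
    "occupancy_frequency",
    "radius_sweep",
    "distance_stats",
    "DEFAULT_SPHERE_RADIUS",
    "DEFAULT_RADIUS_SWEEP",
]

#: default Fe(II) proximity sphere radius, Å
DEFAULT_SPHERE_RADIUS = 4.7
#: default sensitivity sweep, Å
DEFAULT_RADIUS_SWEEP = (4.6, 4.7, 4.8)


@dataclass
class OccupancyResult:
    radius: float
    per_atom_fraction: dict[str, float]  # atom label -> fraction of frames inside
    union_fraction: float                # ≥1 target inside
    sum_fraction: float                  # arithmetic sum of per-atom fractions
    n_frames: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.union_fraction <= min(1.0, self.sum_fraction) + 1e-12):
            raise ValueError("union fraction outside [0, min(1, sum)]")


@dataclass
class DistanceStats:
    mean: float
    std: float   # population standard deviation
    series: np.ndarray


def _atom_label(traj: Trajectory, index: int) -> str:
    a = traj.structure.atoms[index]
    return f"{a.chain_id}:{a.residue_number}:{a.name}"


def _window_coords(traj: Trajectory, window) -> np.ndarray:
    xyz = traj.xyz
    if window is not None:
        xyz = xyz[slice(*window)]
        if xyz.shape[0] == 0:
            raise StructureError(f"window {window} selects no frames")
    return xyz


def occupancy_frequency(
    traj: Trajectory,
    reference: int,
    targets: Selection | Sequence[int],
    radius: float = DEFAULT_SPHERE_RADIUS,
    window: tuple[int | None, int | None] | None = None,
) -> OccupancyResult:
    """Frequency of target atoms strictly within ``radius`` of a reference atom."""
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    idx = targets.index_array if isinstance(targets, Selection) else np.asarray(targets, int)
    if idx.size == 0:
        raise StructureError("occupancy_frequency: empty target selection")
    xyz = _window_coords(traj, window)
    ref = xyz[:, reference]                       # (F, 3)
    tgt = xyz[:, idx]                             # (F, T, 3)
    dist = np.linalg.norm(tgt - ref[:, None, :], axis=2)
    inside = dist < radius                        # strict inequality
    per_atom = inside.mean(axis=0)
    labels = [_atom_label(traj, i) for i in idx]
    return OccupancyResult(
        radius=float(radius),
        per_atom_fraction=dict(zip(labels, per_atom.tolist())),
        union_fraction=float(inside.any(axis=1).mean()),
        sum_fraction=float(per_atom.sum()),
        n_frames=int(inside.shape[0]),
    )


def radius_sweep(
    traj: Trajectory,
    reference: int,
    targets: Selection | Sequence[int],
    radii: Sequence[float] = DEFAULT_RADIUS_SWEEP,
    window: tuple[int | None, int | None] | None = None,
) -> list[OccupancyResult]:
    """Occupancy at each radius of a sorted positive radius list."""
    radii = list(radii)
    if any(r <= 0 for r in radii):
        raise ValueError("radii must all be positive")
    if sorted(radii) != radii:
        raise ValueError("radii must be sorted ascending")
    return [
        occupancy_frequency(traj, reference, targets, r, window=window) for r in radii
    ]


def distance_stats(
    traj: Trajectory,
    a: int,
    b: int,
    window: tuple[int | None, int | None] | None = None,
) -> DistanceStats:
    """Per-frame distance series between two atoms with mean and population std."""
    if a == b:
        raise ValueError("distance_stats needs two distinct atoms")
    xyz = _window_coords(traj, window)
    series = np.linalg.norm(xyz[:, a] - xyz[:, b], axis=1)
    return DistanceStats(
        mean=float(series.mean()), std=float(series.std(ddof=0)), series=series
    )


def write_occupancy_csv(path: str | Path, results: Sequence[OccupancyResult]) -> None:
    lines = ["radius,atom,per_atom_fraction,union_fraction,sum_fraction,n_frames"]
    for res in results:
        for label, frac in res.per_atom_fraction.items():
            lines.append(
                f"{res.radius:.6g},{label},{frac:.8g},"
                f"{res.union_fraction:.8g},{res.sum_fraction:.8g},{res.n_frames}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
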