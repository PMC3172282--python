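"""Three-state rotamer discretisation and Boltzmann-inverted statistics.

The torsion circle (-180, +180] is partitioned into three 120°-wide arcs
centred on the classic side-chain rotamers: gauche+ near +60°, gauche- near
-60° and trans near 180°.  From a labelled frame series the module derives
state populations, ordered transition counts, relative state free energies
ΔG_i = -kT ln(p_i / p_max) and per-transition barrier estimates
ΔE‡(i→j) = -kT ln(n(i→j) / n_i).

Absolute barrier values carry an unknown attempt-frequency offset common to
all transitions; differences between barriers are the supported output.
A transition never observed from a visited state is reported as +inf;
statistics from an unvisited state are reported as NaN (missing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import DEFAULT_TEMPERATURE, K_BOLTZMANN_KCAL
from .geometry import DihedralSeries

__all__ = [
    "STATE_LABELS",
    "StateBinning",
    "StateSeries",
    "StateStats",
    "assign_states",
    "state_statistics",
    "combine_equivalent_methyls",
]

#: canonical state order: gauche+, gauche-, trans
STATE_LABELS = ("g+", "g-", "t")


@dataclass(frozen=True)
class StateBinning:
    """Partition of the torsion circle into three labelled arcs.

    Defaults: (0, 120] → g+, (-120, 0] → g-, remainder → t.  Each arc is
    half-open at its upper edge, so a value exactly on an edge belongs to
    the arc it closes (120° → g+, 0° → g-, -120° → t, 180° → t).
    """

    edges: tuple[float, float, float] = (-120.0, 0.0, 120.0)
    labels: tuple[str, str, str] = STATE_LABELS

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Vectorised label assignment; returns an array of label strings."""
        v = np.asarray(values, dtype=float)
        lo, mid, hi = self.edges
        gp, gm, t = self.labels
        out = np.full(v.shape, t, dtype=object)
        out[(v > mid) & (v <= hi)] = gp
        out[(v > lo) & (v <= mid)] = gm
        return out


@dataclass
class StateSeries:
    """Per-frame rotamer-state labels for one torsion series."""

    labels: np.ndarray
    source: DihedralSeries | None = None
    binning: StateBinning = field(default_factory=StateBinning)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.source is not None and len(self.labels) != len(self.source):
            raise ValueError("label count differs from source series length")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class StateStats:
    """Populations, transition counts and Boltzmann-inverted energies."""

    populations: dict[str, float]
    residence_counts: dict[str, int]
    transition_counts: dict[tuple[str, str], int]
    temperature: float
    relative_energies: dict[str, float]      # kcal/mol, min is 0
    barrier_estimates: dict[tuple[str, str], float]  # kcal/mol; +inf/NaN allowed
    n_frames: int

    def barrier_difference(
        self, a: tuple[str, str], b: tuple[str, str]
    ) -> float:
        return self.barrier_estimates[a] - self.barrier_estimates[b]


def assign_states(
    series: DihedralSeries, binning: StateBinning | None = None
) -> StateSeries:
    """Label every frame of a torsion series with its rotamer state."""
    binning = binning or StateBinning()
    return StateSeries(binning.assign(series.values), source=series, binning=binning)


def state_statistics(
    series: StateSeries,
    temperature: float = DEFAULT_TEMPERATURE,
    window: tuple[int | None, int | None] | None = None,
) -> StateStats:
    """Populations, transitions, relative energies and barrier estimates.

    ``window`` restricts the analysis to frames [start, stop), mirroring the
    common practice of discarding an equilibration prefix.
    """
    labels = series.labels
    if window is not None:
        labels = labels[slice(*window)]
    n = len(labels)
    if n < 2:
        raise ValueError("state_statistics needs at least 2 frames")
    kT = K_BOLTZMANN_KCAL * temperature
    names = series.binning.labels
    residence = {s: int(np.sum(labels == s)) for s in names}
    populations = {s: residence[s] / n for s in names}
    transitions = {
        (a, b): 0 for a in names for b in names if a != b
    }
    prev = labels[:-1]
    nxt = labels[1:]
    changed = prev != nxt
    for a, b in zip(prev[changed], nxt[changed]):
        transitions[(a, b)] += 1

    p_max = max(populations.values())
    energies = {}
    for s in names:
        p = populations[s]
        energies[s] = float("inf") if p == 0 else -kT * math.log(p / p_max)

    barriers = {}
    for (a, b), count in transitions.items():
        n_a = residence[a]
        if n_a == 0:
            barriers[(a, b)] = float("nan")
        elif count == 0:
            barriers[(a, b)] = float("inf")
        else:
            barriers[(a, b)] = -kT * math.log(count / n_a)

    return StateStats(
        populations=populations,
        residence_counts=residence,
        transition_counts=transitions,
        temperature=temperature,
        relative_energies=energies,
        barrier_estimates=barriers,
        n_frames=n,
    )


@dataclass
class MethylCombination:
    """Occupancy of "any methyl in trans" across equivalent methyl torsions."""

    any_trans: np.ndarray           # per-frame boolean
    any_trans_fraction: float
    per_methyl_populations: list[dict[str, float]]
    all_distinct: bool              # every frame's labels pairwise distinct


def combine_equivalent_methyls(
    series_list: Sequence[StateSeries], trans_label: str = "t"
) -> MethylCombination:
    """Combine 1-3 equivalent methyl state series over identical frames.

    For a methylammonium head the chemically equivalent methyls sit 120°
    apart, so for an ideal trimethyl head every frame has exactly one methyl
    per state; the effectual (Fe-aligned) orientation is reported as the
    fraction of frames where at least one methyl is trans.
    """
    if not 1 <= len(series_list) <= 3:
        raise ValueError("expected 1-3 methyl series")
    lengths = {len(s) for s in series_list}
    if len(lengths) != 1:
        raise ValueError(f"series lengths differ: {sorted(lengths)}")
    stack = np.stack([s.labels for s in series_list])
    any_trans = np.any(stack == trans_label, axis=0)
    per_methyl = []
    for s in series_list:
        n = len(s)
        per_methyl.append(
            {lab: float(np.sum(s.labels == lab)) / n for lab in s.binning.labels}
        )
    if len(series_list) > 1:
        all_distinct = bool(
            np.all(
                [
                    len(set(stack[:, f])) == stack.shape[0]
                    for f in range(stack.shape[1])
                ]
            )
        )
    else:
        all_distinct = True
    return MethylCombination(
        any_trans=any_trans,
        any_trans_fraction=float(any_trans.mean()),
        per_methyl_populations=per_methyl,
        all_distinct=all_distinct,
    )
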