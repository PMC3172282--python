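# Methods

## The system being emulated

A methylated lysine side chain bound in the methylammonium pocket of a
JmjC-domain demethylase presents its head group to the catalytic Fe(II)
through an oxygen-lined cage (backbone O of a glycine plus tyrosine,
serine, asparagine and glutamate side-chain oxygens).  Catalysis requires
a methyl carbon close to Fe(II); geometrically this corresponds to the
torsion about the CE–NZ bond sitting in the *trans* well.  The analyses in
this package quantify how methylation state changes the statistics of that
torsion, the resulting Fe-proximity of methyl carbons, the hydrogen-bond
network, the sterics of forced rotation, and the nonbonded interface
energetics.

## Torsion states and Boltzmann inversion

The torsion χ = ∠(CD, CE, NZ, CZx) is reported in degrees on (−180, +180]
(+180 canonical for trans) with the standard sign convention: rotating the
fourth atom right-handedly by δ about the CE→NZ axis increases χ by
exactly δ.  The circle is partitioned into three 120° arcs, each half-open
at its upper edge: (0, 120] → g⁺, (−120, 0] → g⁻, remainder → t, so
χ = 120° is g⁺, χ = 0° is g⁻ and χ = −120° is t.

From a labelled series over an analysis window of N frames:

- populations p_i = n_i / N and relative free energies
  ΔG_i = −kT·ln(p_i/p_max), zero at the most populated state;
- ordered transition counts n(i→j) from consecutive-frame label changes,
  at native frame resolution (display decimation is presentation, never
  analysis);
- barrier estimates ΔE‡(i→j) = −kT·ln(n(i→j)/n_i), the Boltzmann-inverted
  per-opportunity transition probability.

k = 1.987×10⁻³ kcal/(mol·K); the default temperature is 310 K, so
kT = 0.61597 kcal/mol and a population ratio of e corresponds to
0.616 kcal/mol.  The estimator carries an unknown attempt-frequency offset
(−kT·ln κ under the generator's kinetics) that is *common to all
transitions*: differences between barriers are the supported output, and
absolute values are not interpreted.  A transition never observed from a
visited state reports +∞; statistics from an unvisited state report NaN.
Analysis windows are first-class arguments throughout because production
statistics conventionally discard an equilibration prefix.

For a tetrahedral trimethyl head the three CZ torsions are rigidly 120°
apart, so the per-frame labels are always pairwise distinct and exactly
one methyl occupies each well; `combine_equivalent_methyls` reports the
fraction of frames with *any* methyl in trans — the "effectual value" for
catalysis — alongside per-methyl populations and the distinctness check.

## The synthetic generator

The generator produces trajectories with the statistical structure the
analyses assume, plus the hidden truth needed to validate them.  It is a
model of the *analysis inputs*, not of force-field dynamics.

**Kinetics.**  A discrete-time Markov chain over (g⁺, g⁻, t) with per-step
transition probability p(i→j) = κ·exp(−B(i→j)/kT).  κ (default 0.1 per
frame) is a documented attempt prefactor; a +∞ barrier encodes a forbidden
transition (the dimethyl g⁻↔g⁺ block); a parameterisation whose per-step
leave probability exceeds 1 is rejected.  Barriers must be at least the
uphill energy difference; `from_energies` builds detailed-balance barriers
from state energies and a transition-state energy, making the stationary
law exactly Boltzmann.  The stationary distribution is computed by power
iteration from the uniform distribution, which stays well defined (and
deterministic) when forbidden transitions make the chain reducible.  A
discrete-time chain was chosen over continuous-time kinetic Monte Carlo
because the analyses consume evenly spaced frames.

**Geometry.**  NZ at the origin, CE 1.49 Å along +z, CD placed at a
111° bond angle.  Head substituents sit on the tetrahedral cone about NZ
(N–C 1.49 Å, N–H 1.03 Å, CE–NZ–CZ 109.5°), at torsion slots 120° apart;
per frame the head is placed at the state's well centre (+60/−60/180°)
plus Gaussian torsional wobble, then isotropic Cartesian jitter is added
to every atom.  Defaults: wobble σ = 10° (well inside a 120° bin),
jitter σ = 0.05 Å.  Note that 0.05 Å jitter on all four torsion-defining
atoms with ~1.4 Å lever arms propagates to ≈5° RMS of torsion noise —
harmless for state assignment but visible in raw torsion traces.

**Pocket.**  The symmetric default is an idealised oxygen cage: seven
labelled oxygens (Gly170:O, Tyr175:OH, Tyr177:OH, Ser288:OG, Asn290:OD1,
Glu190:OE1/OE2) all 4.2 Å from NZ on a ring 140° from the NZ→CE axis —
below the methyl cone, so no pose of the head clashes with them.  Fe(II)
sits 5.0 Å from NZ along the trans-slot direction: a trans methyl carbon
is 3.51 Å from Fe (inside the 4.7 Å sphere) and gauche carbons are 5.67 Å
(outside), giving clean single-occupancy statistics.  One water oxygen is
placed 2.15 Å from Fe, off the Fe–NZ axis, with its hydrogens pointing
into the pocket.  The asymmetric variant pulls Asn290:OD1 and Gly170:O in
to 3.1 Å from NZ near the g⁺ slot, emulating the restricted environment
of the lower methylation states: a head whose methyls occupy g⁻/t is
clash-free, and any rotation forcing a methyl into the blocked slot
overlaps those oxygens.

Ideal single-pose frames (`make_pocket_frame`) are heavy-atom only by
default: clash analysis here is a heavy-atom contact criterion, and an
amine hydrogen parked in the blocked slot of the asymmetric pocket would
otherwise register a contact in the resting pose that the heavy-atom
picture does not support.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: force-field dynamics, solvent diffusion and
exchange, pocket flexibility and induced fit, correlated noise between
atoms, periodic-boundary imaging, and the enzyme fold beyond the pocket
fragment.  Conclusions about real systems require real trajectories; the
generator establishes only that the *statistics are computed correctly*.

**Determinism.**  One integer seed drives a single pseudo-random stream in
a documented order (initial state, jumps, wobble, jitter); identical seeds
give bitwise-identical coordinates, and every generated structure embeds
its seed in the title.

## Proximity statistics

Sphere occupancy counts a target strictly inside (d < r) a sphere around
the reference atom.  Three variants are reported side by side — per-atom
fractions, their arithmetic sum, and the union (≥ 1 target inside) —
because summed per-methyl percentages equal the union only in the
single-occupancy regime; emitting both makes that assumption checkable
instead of implicit.  Default radius 4.7 Å with a 4.6/4.7/4.8 Å
sensitivity sweep.  Distance statistics report the per-frame series, its
mean, and the population (ddof = 0) standard deviation.  Positional
fluctuation is the RMS deviation of one atom from its trajectory-mean
position, with no superposition.

## Hydrogen bonds

Strict criteria: donor–acceptor distance R < 3.00 Å and donor–H–acceptor
angle 120° < θ ≤ 180°, N/O donors.  Loose (C–H···O) criteria: R < 3.4 Å,
same angle window, carbon donors admitted.  R is the donor–acceptor
heavy-atom distance — consistent with the 3.0/3.4 Å magnitudes and common
convention; the hydrogen–acceptor alternative is exposed as an option
(`distance_definition`).  Donor–hydrogen pairing is name based (an
explicit map for waters/backbone plus a stem-matching heuristic against
N/O/C names in the residue) because no bond graph is read; acceptors are
N/O atoms outside the donor's residue.  Occupancy divides satisfied frames
by the *window* frame count; mean distance and mean deviation from
linearity (180° − θ) average over satisfied frames only.  Classification:
main chain iff the atom name is in {N, CA, C, O, OXT, H, HA, H1–H3} and
the residue is not water (waters are side-chain-only entities); span class
is interface when donor and acceptor chains differ, otherwise
intra-substrate or intra-enzyme.

## Clash scanning

The head is rotated rigidly about the CE→NZ axis (sign convention shared
with the torsion kernel, so a −120° rotation shifts χ by exactly −120°);
all other atoms, including pocket side chains, stay fixed — this is a
single-pose contact test, with no relaxation, so clash counts are an upper
bound on the strain a relaxing pocket would feel.  A head/environment pair
clashes when d < r_i + r_j − tolerance with tolerance 0.4 Å and element
radii H 1.20, C 1.70, N 1.55, O 1.52, S 1.80, Fe 1.30 Å (per-atom override
via the parameter sidecar).  Environment atoms of the head's own residue
are excluded (covalent stem).  The default scan (0, −120, −240°) visits
all three slot assignments.

## Interface energy decomposition

Gas-phase molecular-mechanics cross terms only, between disjoint enzyme
and substrate selections: Lennard-Jones 4ε[(σ/r)¹² − (σ/r)⁶] under
Lorentz–Berthelot combining (arithmetic σ, geometric ε) and Coulomb
k_e·q_iq_j/(ε_int·r) with k_e = 332.0636 kcal·Å/(mol·e²) and internal
dielectric ε_int = 4 by default.  No cutoff by default (desk-scale
systems; an optional hard cutoff exists for speed).  Intra-selection
exclusions never arise because only cross pairs are summed.  Each
residue's row is its summed interaction with the entire opposite
selection, averaged over the window; both sides are reported and their
totals agree to numerical precision.  Continuum solvation (PB/GB) and
entropy terms are out of scope, so rankings for charged residues may
differ from a solvation-screened decomposition — the output is labelled
gas-phase for that reason.

## Numerical choices

- Angles always mapped to (−180, +180], with −180 folded to +180.
- Degenerate torsion geometry (coincident/collinear points below 1e-10 of
  norm) raises a domain error rather than returning 0.
- Superposition uses the Kabsch rotation (no reflection); the residual is
  recomputed from the fitted pose because the solver's internal residual
  loses ~√ε to cancellation near zero.
- Sphere membership and hydrogen-bond thresholds are strict inequalities
  on the lower side (d < r), half-open on angle (θ_min < θ ≤ θ_max).
- Barrier estimates use residence counts over the full window as the
  opportunity denominator; the last frame contributes residence but no
  transition opportunity (an O(1/N) effect).
- CSV output is fully formatted text (no locale, no timestamps), making
  byte-identical reproduction a testable contract.

## Problem sizes used in validation

Statistical checks run on 10⁵-frame synthetic trajectories (three seeds
for the barrier-ladder recovery, pooling transition counts across seeds
and both directions of each symmetric barrier); census-style checks use
50-atom/200-frame and 30-residue systems compared against exhaustive
loops; the packaged end-to-end demonstration uses 10⁴ frames.  These sizes
keep every statistic's sampling error an order of magnitude below the
thresholds asserted in the tests.

## Known limitations

- Absolute barrier heights are not identifiable from transition counts
  alone (unknown attempt frequency); only differences are reported.
- Name-based donor–hydrogen pairing can misassign hydrogens in residues
  with ambiguous stems not covered by the packaged map.
- The PDB reader keeps the first model's atom set as the topology and
  drops altLoc ≠ blank/'A'; no mmCIF, no bond perception, no
  periodic-boundary unwrapping.
- The packaged nonbonded parameter set for synthetic systems is a toy
  (head ≈ +1 e, partial-negative oxygens) meant to exercise the machinery,
  not to approximate any force field.
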