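# methyldyn

Trajectory analyses of how an Fe(II)/α-ketoglutarate histone demethylase
(a JmjC-domain enzyme such as JMJD2A) discriminates mono-, di- and
trimethylated lysine on a histone tail.  The package is aimed at
computational structural biologists who have (or want to emulate) MD
trajectories of a methyllysine head bound in the oxygen-lined
methylammonium pocket, and who want the discrimination-relevant statistics
rather than raw coordinates:

- **Rotamer states and barriers.**  The torsion χ = ∠(CD–CE–NZ–CZx) about
  the CE–NZ bond is measured per frame, discretised into the three
  120°-wide rotamer arcs (g⁺ ≈ +60°, g⁻ ≈ −60°, t ≈ 180°), and Boltzmann
  inversion converts occupancies and transition frequencies into relative
  free energies and barrier estimates:

  ΔG_i = −kT ln(p_i / p_max),  ΔE‡(i→j) = −kT ln(n(i→j) / n_i)

  with k = 1.987×10⁻³ kcal/(mol·K).  Transitions that never occur from a
  visited state report +∞ — the signature of a blocked g⁻↔g⁺
  interconversion in the dimethyl case.
- **Fe(II) sphere occupancy.**  The fraction of frames in which each
  methyl carbon sits strictly within a sphere (default radius 4.7 Å, sweep
  4.6–4.8 Å) of the catalytic Fe(II), reported per atom, as a sum, and as
  a union — the statistic that separates the productive trimethyl substrate
  from the lower methylation states.
- **Distances and fluctuations.**  NZ–pocket-oxygen and Fe–water distance
  statistics, plus the raw positional fluctuation of the Fe(II) cation.
- **Hydrogen-bond census.**  Geometric donor–H–acceptor detection under
  strict (R < 3.0 Å, 120° < θ ≤ 180°) and loose C–H···O (R < 3.4 Å)
  criteria, with per-bond occupancy, mean distance, mean deviation from
  linearity, and main-chain/side-chain and interface/intra-chain classes.
- **Steric clash scan.**  Rigid −120° rotations of the methylammonium head
  about the CE–NZ axis with a van der Waals overlap census against the
  pocket — the 3-fold-symmetric trimethyl head finds nothing new, while a
  restricted pocket clashes as soon as a methyl is forced into the walled
  slot.
- **Interface energy decomposition.**  Per-residue trajectory-averaged
  Lennard-Jones + screened Coulomb (internal dielectric 4) cross terms
  between enzyme and substrate — the gas-phase molecular-mechanics core of
  an end-point binding-energy decomposition (no continuum solvation or
  entropy terms).

Because real demethylase trajectories are rarely shareable, the package
ships a first-class synthetic generator: a methyllysine head hopping among
the three rotamer wells of a discrete-time Markov chain
(p(i→j) = κ·e^(−B(i→j)/kT), κ = 0.1 per frame) inside a rigid idealised
pocket, returning the hidden state sequence so every analysis stage can be
validated against ground truth.

## Worked example

The packaged configuration runs every stage on a 10⁴-frame synthetic
trimethyllysine trajectory (symmetric kinetics, barrier 1.0 kcal/mol,
310 K, 2 ps/frame):

```sh
methyldyn run --config examples/me3.toml --out out/
```

```
{"out_dir": "out/", "stages": {"clashes": "ok", "distances": "ok", "energy": "ok",
 "hbonds": "ok", "occupancy": "ok", "rmsd": "ok", "rotamer": "ok"}}
```

Reading the bundle (`out/rotamer_stats.json`, `out/occupancy.csv`,
`out/distances.csv`, `out/clash_counts.json`, `out/energy_totals.json`)
for this run:

- CZ1 state populations (g⁺, g⁻, t) = (0.320, 0.389, 0.292) — all three
  wells visited roughly equally, as the symmetric kinetics dictate; the
  relative energies are correspondingly small (≤ 0.18 kcal/mol) and the
  six barrier estimates cluster at 2.3–2.5 kcal/mol (the generator's
  1.0 kcal/mol barrier plus the common −kT·ln κ ≈ 1.42 kcal/mol attempt
  offset — only barrier *differences* are physically meaningful here).
- `any_methyl_trans_fraction` = 1.0: the tetrahedral trimethyl head always
  has exactly one methyl in the Fe-aligned trans slot.
- Fe-sphere occupancy at 4.7 Å: per-methyl fractions ≈ 0.29–0.39 summing
  to 1.00, union 1.00 — single-occupancy regime, one methyl carbon inside
  the sphere in every frame.
- Fe–water mean distance 2.151 ± 0.071 Å; Fe positional fluctuation
  0.087 Å (a rigid, well-anchored metal site).
- Clash counts at rotations 0/−120/−240° are 0/0/0: rotating the symmetric
  trimethyl head creates no new overlaps.
- Interface energy totals agree between the enzyme side and the substrate
  side (−43.6 kcal/mol with the packaged toy parameter set), dominated by
  the Coulomb attraction between the cationic head and the oxygen cage.

Individual stages are also available as subcommands (`simulate`,
`dihedrals`, `states`, `occupancy`, `distances`, `hbonds`, `clashes`,
`energy`, `report`) and as plain library calls; see the module docstrings
under `src/methyldyn/`.

### Output schemas

| table | columns |
|---|---|
| `rmsd.csv` | frame, time_ps, value (Å) |
| `rotamer_states.csv` | frame, time_ps, per-methyl torsion (deg) and state |
| `occupancy.csv` | radius, atom, per_atom_fraction, union_fraction, sum_fraction, n_frames |
| `distances.csv` | kind, a, b, mean_A, std_A |
| `hbonds.csv` | donor, hydrogen, acceptor, occupancy, mean_distance_A, mean_linearity_deviation_deg, classes |
| `clashes.csv` | angle_deg, head_atom, environment_atom, distance_A, overlap_A |
| `energy.csv` | chain, residue_number, residue_name, vdw_kcal, coulomb_kcal, total_kcal, frames_averaged |

`manifest.json` records the package version, seed, full config and its
SHA-256 hash; identical configs reproduce byte-identical tables.

## Scope notes

File formats are deliberately desk-scale and text-based: fixed-column PDB
(multi-model for trajectories), XYZ, and CSV sidecars for partial charges
and Lennard-Jones parameters.  The package analyses trajectories; it does
not run MD, parameterise force fields, or compute continuum-solvation /
entropy terms.  See `docs/methods.md` for the model details, defaults and
limitations.
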