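"""Configuration-driven pipeline: all analysis stages into one report bundle.

A run is described by a :class:`RunConfig` (TOML file or constructed in
code): either on-disk inputs (structure + trajectory + parameter sidecar)
or a synthetic-generation block.  ``run_pipeline`` executes the stages in
method order — RMSD, rotamer states/barriers, Fe-sphere occupancy, pocket
distances, hydrogen bonds, clash scan, interface energy decomposition —
writing one CSV table per stage plus a JSON manifest recording the config
hash, seed and package version.  A stage failure is recorded and the
remaining stages still run.  Outputs are deterministic given config + seed
(no wall-clock data is written; timings go to the stderr log).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .clash import DEFAULT_SCAN_ANGLES, DEFAULT_TOLERANCE, rotation_scan, write_clash_csv
from .constants import DEFAULT_TEMPERATURE
from .energy import NonbondedParams, interface_decomposition, interface_totals, write_energy_csv
from .geometry import dihedral_series, mean_fluctuation, rmsd_series, write_series_csv
from .hbonds import HBondCriteria, classify_bond, enumerate_dha_triples, hbond_occupancy, write_hbond_csv
from .proximity import DEFAULT_RADIUS_SWEEP, distance_stats, radius_sweep, write_occupancy_csv
from .rotamer import assign_states, combine_equivalent_methyls, state_statistics
from .structures import (
    SelectionClause,
    SelectionError,
    StructureError,
    Trajectory,
    read_parameters,
    read_structure,
    read_trajectory,
    resolve_selection,
    write_structure,
    write_trajectory,
)
from .synthetic import (
    ENZYME_CHAIN,
    HEAD_RESIDUE,
    SUBSTRATE_CHAIN,
    NoiseModel,
    PocketSpec,
    RotamerKinetics,
    simulate_rotamer_trajectory,
    write_default_parameters,
    write_sidecar,
)

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "build_synthetic_input", "ALL_STAGES"]

log = logging.getLogger("methyldyn")

ALL_STAGES = (
    "rmsd", "rotamer", "occupancy", "distances", "hbonds", "clashes", "energy",
)

PRESETS = ("me1", "me2", "me3", "me2-asymmetric")


class ConfigError(ValueError):
    """Invalid run configuration; message lists all problems at once."""


@dataclass
class RunConfig:
    # file inputs (ignored when a synthetic block is present)
    structure_path: str | None = None
    trajectory_path: str | None = None
    parameters_path: str | None = None
    dt: float = 1.0  # ps, frame interval of a file trajectory
    # synthetic generation block
    synthetic: dict | None = None
    # selections
    enzyme_chain: str = ENZYME_CHAIN
    substrate_chain: str = SUBSTRATE_CHAIN
    head_residue: int = HEAD_RESIDUE
    fe_atom: str = f"{ENZYME_CHAIN}:400:FE"
    # analysis window [start, stop) in frames; None = all
    window_start: int | None = None
    window_stop: int | None = None
    # thresholds
    hbond_mode: str = "strict"
    sphere_radii: list[float] = field(default_factory=lambda: list(DEFAULT_RADIUS_SWEEP))
    clash_tolerance: float = DEFAULT_TOLERANCE
    dielectric: float = 4.0
    temperature: float = DEFAULT_TEMPERATURE
    # execution
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    out_dir: str = "methyldyn_out"
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()

    def validate(self) -> None:
        problems = []
        if self.synthetic is None:
            if not self.structure_path:
                problems.append("no structure_path and no synthetic block")
            elif not Path(self.structure_path).exists():
                problems.append(f"structure_path missing: {self.structure_path}")
            if not self.trajectory_path:
                problems.append("no trajectory_path and no synthetic block")
            elif not Path(self.trajectory_path).exists():
                problems.append(f"trajectory_path missing: {self.trajectory_path}")
            if self.parameters_path and not Path(self.parameters_path).exists():
                problems.append(f"parameters_path missing: {self.parameters_path}")
        else:
            preset = self.synthetic.get("preset", "me3")
            if preset not in PRESETS:
                problems.append(f"unknown synthetic preset {preset!r}; choose {PRESETS}")
            if int(self.synthetic.get("n_frames", 1)) < 1:
                problems.append("synthetic n_frames must be >= 1")
        if self.hbond_mode not in ("strict", "cho"):
            problems.append(f"hbond_mode must be strict or cho, got {self.hbond_mode!r}")
        if any(r <= 0 for r in self.sphere_radii):
            problems.append("sphere_radii must be positive")
        if sorted(self.sphere_radii) != list(self.sphere_radii):
            problems.append("sphere_radii must be sorted ascending")
        if self.dielectric <= 0:
            problems.append("dielectric must be positive")
        if (
            self.window_start is not None
            and self.window_stop is not None
            and self.window_stop <= self.window_start
        ):
            problems.append("window_stop must exceed window_start")
        for s in self.stages:
            if s not in ALL_STAGES:
                problems.append(f"unknown stage {s!r}")
        if problems:
            raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(problems))

    @property
    def window(self) -> tuple[int | None, int | None] | None:
        if self.window_start is None and self.window_stop is None:
            return None
        return (self.window_start, self.window_stop)


def build_synthetic_input(config: RunConfig) -> tuple[Trajectory, np.ndarray, dict]:
    """Generate the trajectory described by the config's synthetic block."""
    blk = dict(config.synthetic or {})
    preset = blk.get("preset", "me3")
    n_frames = int(blk.get("n_frames", 10_000))
    dt = float(blk.get("dt", 2.0))
    kappa = float(blk.get("kappa", 0.1))
    seed = int(blk.get("seed", config.seed))
    jitter = float(blk.get("jitter_sigma", 0.05))
    wobble = float(blk.get("dihedral_sigma", 10.0))
    barrier = float(blk.get("barrier", 1.0))

    if preset == "me3":
        pocket = PocketSpec.symmetric(3)
        kinetics = RotamerKinetics.symmetric(barrier, temperature=config.temperature)
    elif preset == "me2":
        pocket = PocketSpec.symmetric(2)
        kinetics = RotamerKinetics.symmetric(barrier, temperature=config.temperature)
    elif preset == "me2-asymmetric":
        pocket = PocketSpec.asymmetric(2)
        # direct g- <-> g+ interconversion forbidden (no circular motion);
        # the g+ <-> t barrier raised relative to the others
        barriers = {}
        for a in ("g+", "g-", "t"):
            for b in ("g+", "g-", "t"):
                if a == b:
                    continue
                pair = frozenset((a, b))
                if pair == frozenset(("g-", "g+")):
                    barriers[(a, b)] = float("inf")
                elif pair == frozenset(("g+", "t")):
                    barriers[(a, b)] = barrier + 1.0
                else:
                    barriers[(a, b)] = barrier
        kinetics = RotamerKinetics(
            state_energies={"g+": 0.0, "g-": 0.0, "t": 0.0},
            barrier_energies=barriers,
            temperature=config.temperature,
        )
    else:  # me1
        pocket = PocketSpec.symmetric(1)
        kinetics = RotamerKinetics.symmetric(barrier, temperature=config.temperature)
    traj, states = simulate_rotamer_trajectory(
        kinetics,
        pocket,
        NoiseModel(jitter_sigma=jitter, dihedral_sigma=wobble),
        n_frames=n_frames,
        dt=dt,
        seed=seed,
        kappa=kappa,
    )
    meta = {
        "preset": preset, "n_frames": n_frames, "dt": dt, "kappa": kappa,
        "seed": seed, "jitter_sigma": jitter, "dihedral_sigma": wobble,
        "barrier": barrier,
    }
    return traj, states, meta


def _load_input(config: RunConfig) -> tuple[Trajectory, dict]:
    if config.synthetic is not None:
        traj, states, meta = build_synthetic_input(config)
        return traj, {"synthetic": meta}
    structure = read_structure(config.structure_path)
    if config.parameters_path:
        structure, warnings = read_parameters(structure, config.parameters_path)
        for w in warnings[:20]:
            log.debug("parameters: %s", w)
    traj = read_trajectory(config.trajectory_path, structure, dt=config.dt)
    return traj, {"structure": config.structure_path, "trajectory": config.trajectory_path}


def _apply_synthetic_parameters(traj: Trajectory, out_dir: Path) -> Trajectory:
    params_csv = out_dir / "parameters.csv"
    write_default_parameters(params_csv)
    structure, _ = read_parameters(traj.structure, params_csv)
    return Trajectory(structure, traj.frames, traj.dt)


def _methyl_quads(traj: Trajectory, config: RunConfig) -> list[tuple[str, tuple[int, int, int, int]]]:
    s = traj.structure
    cd = s.index_of(config.substrate_chain, config.head_residue, "CD")
    ce = s.index_of(config.substrate_chain, config.head_residue, "CE")
    nz = s.index_of(config.substrate_chain, config.head_residue, "NZ")
    quads = []
    for name in ("CZ1", "CZ2", "CZ3"):
        try:
            cz = s.index_of(config.substrate_chain, config.head_residue, name)
        except SelectionError:
            continue
        quads.append((name, (cd, ce, nz, cz)))
    if not quads:
        raise SelectionError("no methyl carbons (CZ1..CZ3) found on the head residue")
    return quads


def run_pipeline(config: RunConfig) -> dict:
    """Run all enabled stages; return the manifest (also written as JSON)."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    traj, input_meta = _load_input(config)
    window = config.window
    wtraj = traj.window(*window) if window else traj

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "input": input_meta,
        "n_frames": traj.n_frames,
        "stages": {},
        "tables": [],
    }

    def record(stage: str, table: str | None, status: str) -> None:
        manifest["stages"][stage] = status
        if table is not None:
            manifest["tables"].append(table)

    def run_stage(stage, fn):
        if stage not in config.stages:
            record(stage, None, "skipped")
            log.info("stage %-10s skipped", stage)
            return
        t0 = time.perf_counter()
        try:
            table = fn()
            record(stage, table, "ok")
            log.info("stage %-10s ok      (%.2f s)", stage, time.perf_counter() - t0)
        except Exception as exc:  # recorded, remaining stages still run
            record(stage, None, f"failed: {exc}")
            log.warning("stage %-10s FAILED: %s", stage, exc)

    # --- stages, in method order ------------------------------------------

    def stage_rmsd() -> str:
        try:
            subset = resolve_selection(
                traj.structure,
                [SelectionClause(chain=config.substrate_chain, backbone_only=True)],
            )
        except SelectionError:
            subset = resolve_selection(
                traj.structure, [SelectionClause(chain=config.substrate_chain)]
            )
        series = rmsd_series(wtraj, traj.frames[0], subset)
        write_series_csv(out_dir / "rmsd.csv", series, traj.dt)
        return "rmsd.csv"

    def stage_rotamer() -> str:
        quads = _methyl_quads(traj, config)
        all_series = {}
        state_series = {}
        for name, quad in quads:
            ds = dihedral_series(wtraj, quad, label=name)
            all_series[name] = ds
            state_series[name] = assign_states(ds)
        lines = ["frame,time_ps," + ",".join(
            f"{n}_deg,{n}_state" for n in all_series
        )]
        n = len(next(iter(all_series.values())))
        for f in range(n):
            cells = [str(f), f"{f * traj.dt:.6g}"]
            for name in all_series:
                cells.append(f"{all_series[name].values[f]:.4f}")
                cells.append(str(state_series[name].labels[f]))
            lines.append(",".join(cells))
        (out_dir / "rotamer_states.csv").write_text("\n".join(lines) + "\n")

        stats = {
            name: state_statistics(ss, temperature=config.temperature)
            for name, ss in state_series.items()
        }
        combo = combine_equivalent_methyls(list(state_series.values()))
        report = {
            name: {
                "populations": st.populations,
                "relative_energies_kcal": st.relative_energies,
                "transition_counts": {f"{a}->{b}": c for (a, b), c in st.transition_counts.items()},
                "barrier_estimates_kcal": {f"{a}->{b}": v for (a, b), v in st.barrier_estimates.items()},
            }
            for name, st in stats.items()
        }
        report["any_methyl_trans_fraction"] = combo.any_trans_fraction
        (out_dir / "rotamer_stats.json").write_text(
            json.dumps(report, indent=1, sort_keys=True, default=str) + "\n"
        )
        return "rotamer_states.csv"

    def stage_occupancy() -> str:
        chain, resnum, name = config.fe_atom.split(":")
        fe = traj.structure.index_of(chain, int(resnum), name)
        targets = resolve_selection(
            traj.structure,
            [SelectionClause(
                chain=config.substrate_chain,
                residues=(config.head_residue, config.head_residue),
                names=frozenset({"CZ1", "CZ2", "CZ3"}),
            )],
        )
        results = radius_sweep(traj, fe, targets, config.sphere_radii, window=window)
        write_occupancy_csv(out_dir / "occupancy.csv", results)
        return "occupancy.csv"

    def stage_distances() -> str:
        s = traj.structure
        chain, resnum, name = config.fe_atom.split(":")
        fe = s.index_of(chain, int(resnum), name)
        nz = s.index_of(config.substrate_chain, config.head_residue, "NZ")
        rows = ["kind,a,b,mean_A,std_A"]
        for i, atom in enumerate(s.atoms):
            if atom.is_water and atom.name == "O":
                st = distance_stats(traj, fe, i, window=window)
                rows.append(
                    f"distance,{config.fe_atom},"
                    f"{atom.chain_id}:{atom.residue_number}:O,{st.mean:.6g},{st.std:.6g}"
                )
            if atom.element == "O" and atom.chain_id == config.enzyme_chain and not atom.is_water:
                st = distance_stats(traj, nz, i, window=window)
                rows.append(
                    f"distance,{config.substrate_chain}:{config.head_residue}:NZ,"
                    f"{atom.chain_id}:{atom.residue_number}:{atom.name},"
                    f"{st.mean:.6g},{st.std:.6g}"
                )
        fluct = mean_fluctuation(wtraj, fe)
        rows.append(f"fluctuation,{config.fe_atom},,{fluct:.6g},")
        (out_dir / "distances.csv").write_text("\n".join(rows) + "\n")
        return "distances.csv"

    def stage_hbonds() -> str:
        criteria = HBondCriteria.strict() if config.hbond_mode == "strict" else HBondCriteria.cho()
        triples = enumerate_dha_triples(traj.structure, mode=config.hbond_mode)
        records = hbond_occupancy(traj, triples, criteria, window=window)
        records = [
            classify_bond(r, traj.structure, config.substrate_chain, config.enzyme_chain)
            for r in records
        ]
        records.sort(key=lambda r: (-r.occupancy, r.donor, r.acceptor))
        write_hbond_csv(out_dir / "hbonds.csv", traj.structure, records)
        return "hbonds.csv"

    def stage_clashes() -> str:
        s = traj.structure
        ce = s.index_of(config.substrate_chain, config.head_residue, "CE")
        nz = s.index_of(config.substrate_chain, config.head_residue, "NZ")
        head = resolve_selection(
            s,
            [SelectionClause(
                chain=config.substrate_chain,
                residues=(config.head_residue, config.head_residue),
                names=frozenset({"CZ1", "CZ2", "CZ3", "HZ1", "HZ2", "HZ3"}),
            )],
        )
        env = resolve_selection(s, [SelectionClause(chain=config.enzyme_chain)])
        frame = wtraj.frames[0]
        reports = rotation_scan(
            frame, s, head, ce, nz, env,
            angles=DEFAULT_SCAN_ANGLES, tolerance=config.clash_tolerance,
        )
        write_clash_csv(out_dir / "clashes.csv", s, reports)
        (out_dir / "clash_counts.json").write_text(
            json.dumps(
                {f"{r.rotation_angle:g}": r.clash_count for r in reports}, indent=1
            ) + "\n"
        )
        return "clashes.csv"

    def stage_energy() -> str:
        etraj = traj
        if config.synthetic is not None and config.parameters_path is None:
            etraj = _apply_synthetic_parameters(traj, out_dir)
        enzyme = resolve_selection(
            etraj.structure, [SelectionClause(chain=config.enzyme_chain)]
        )
        substrate = resolve_selection(
            etraj.structure, [SelectionClause(chain=config.substrate_chain)]
        )
        params = NonbondedParams(dielectric=config.dielectric)
        rows = interface_decomposition(etraj, enzyme, substrate, params, window=window)
        write_energy_csv(out_dir / "energy.csv", rows)
        totals = interface_totals(rows)
        (out_dir / "energy_totals.json").write_text(
            json.dumps({c: {"vdw": v, "coulomb": q, "total": t}
                        for c, (v, q, t) in totals.items()}, indent=1) + "\n"
        )
        return "energy.csv"

    run_stage("rmsd", stage_rmsd)
    run_stage("rotamer", stage_rotamer)
    run_stage("occupancy", stage_occupancy)
    run_stage("distances", stage_distances)
    run_stage("hbonds", stage_hbonds)
    run_stage("clashes", stage_clashes)
    run_stage("energy", stage_energy)

    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return manifest


def write_synthetic_bundle(config: RunConfig, out_dir: str | Path) -> dict:
    """Generate and write a synthetic trajectory + sidecar (CLI `simulate`)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    traj, states, meta = build_synthetic_input(config)
    write_structure(traj.structure, traj.frames[0], out_dir / "structure.pdb")
    write_trajectory(traj, out_dir / "trajectory.xyz")
    write_default_parameters(out_dir / "parameters.csv")
    write_sidecar(out_dir / "sidecar.json", meta["seed"], states, meta)
    return meta
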