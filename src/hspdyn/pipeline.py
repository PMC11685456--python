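"""Configuration-driven orchestration, CLI, logging and report emission.

A JSON config names input structures/trajectories, domain and vector
definitions, and an ordered task list; :func:`run` executes the tasks and
writes CSV/JSON reports.  Every output carries provenance (config hash,
seed, package version) and identical config + seed gives identical outputs.

Exit codes of the ``hspdyn`` CLI: 0 success, 2 configuration/validation
error, 1 runtime error.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import click
import numpy as np

from . import __version__
from .anm import (anm_from_calpha, calpha_nodes, cross_correlations,
                  mean_square_fluctuations, write_nmd)
from .geometry import (ContactCutoffs, SASAParams, centroid_displacement,
                       contact_map, stalk_bend_angle, subdomain_rotation)
from .structure_io import (BACKBONE_ATOMS, DomainDefinition, Structure,
                           Trajectory, read_structure, read_trajectory,
                           select_atoms, write_structure, write_trajectory_xyz)
from .superpose import domain_rmsd_series, per_atom_deviation_series
from .synthetic_data import SubstateGenSpec, make_angle_trajectory, make_ideal_helix
from .traj_analysis import (AngleSeries, AtomRef, SubstateSpec,
                            VectorDefinition, angle_kde, angle_series,
                            kde_mode, region_boundaries_from_printed,
                            substate_occupancy)

logger = logging.getLogger("hspdyn")

KNOWN_TASKS = ("simulate", "angles", "occupancy", "kde", "domain-rmsd",
               "anchor-rmsd", "anm", "rotation", "bend", "interface",
               "displacement")


class ConfigError(ValueError):
    """A configuration problem; the message names the offending field."""


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Validated analysis configuration."""

    output_dir: Path
    seed: int = 0
    structures: dict[str, Path] = field(default_factory=dict)
    trajectories: dict[str, dict] = field(default_factory=dict)
    domains: dict[str, DomainDefinition] = field(default_factory=dict)
    vectors: dict[str, VectorDefinition] = field(default_factory=dict)
    substates: dict[str, SubstateSpec] = field(default_factory=dict)
    tasks: list[dict] = field(default_factory=list)
    raw: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        # output_dir is excluded: where results land must not change what
        # they contain
        hashed = {k: v for k, v in self.raw.items() if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(hashed, sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path, seed: int | None = None,
                  output_dir: str | Path | None = None) -> "AnalysisConfig":
        try:
            raw = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ConfigError(f"config {path}: invalid JSON ({exc})") from exc
        return cls.from_dict(raw, seed=seed, output_dir=output_dir,
                             base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, seed: int | None = None,
                  output_dir: str | Path | None = None,
                  base_dir: Path | None = None) -> "AnalysisConfig":
        base = base_dir or Path(".")
        if output_dir is None:
            output_dir = raw.get("output_dir")
            if output_dir is None:
                raise ConfigError("config field 'output_dir' is required")
        if seed is None:
            seed = int(raw.get("seed", 0))

        structures = {name: (base / p) for name, p in raw.get("structures", {}).items()}
        trajectories = {}
        for name, entry in raw.get("trajectories", {}).items():
            if "path" not in entry or "topology" not in entry:
                raise ConfigError(
                    f"trajectory {name!r}: needs 'path' and 'topology' fields")
            trajectories[name] = {
                "path": base / entry["path"],
                "topology": entry["topology"],
                "frame_interval": float(entry.get("frame_interval", 2.0)),
                "format": entry.get("format", "auto"),
            }

        domains = {}
        for label, entry in raw.get("domains", {}).items():
            try:
                domains[label] = DomainDefinition(
                    label, entry["chain"],
                    tuple((int(a), int(b)) for a, b in entry["ranges"]),
                    frozenset(entry["atoms"]) if "atoms" in entry else BACKBONE_ATOMS)
            except (KeyError, ValueError, TypeError) as exc:
                raise ConfigError(f"domain {label!r}: {exc}") from exc

        vectors = {}
        for label, entry in raw.get("vectors", {}).items():
            try:
                vectors[label] = VectorDefinition(
                    label, AtomRef.parse(entry["from"]), AtomRef.parse(entry["to"]))
            except (KeyError, ValueError) as exc:
                raise ConfigError(f"vector {label!r}: {exc}") from exc

        substates = {}
        for label, entry in raw.get("substates", {}).items():
            try:
                if "printed_ranges" in entry:
                    substates[label] = region_boundaries_from_printed(
                        [tuple(map(float, r)) for r in entry["printed_ranges"]],
                        tuple(entry.get("labels", ())))
                else:
                    substates[label] = SubstateSpec(
                        tuple(map(float, entry["edges"])),
                        tuple(entry.get("labels", ())))
            except (KeyError, ValueError) as exc:
                raise ConfigError(f"substates {label!r}: {exc}") from exc

        tasks = raw.get("tasks", [])
        if not tasks:
            raise ConfigError("config field 'tasks' must be a non-empty list")
        cfg = cls(Path(output_dir), int(seed), structures, trajectories,
                  domains, vectors, substates, list(tasks), raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for i, task in enumerate(self.tasks):
            name = task.get("task")
            if name not in KNOWN_TASKS:
                raise ConfigError(
                    f"tasks[{i}]: unknown task {name!r}; expected one of "
                    f"{', '.join(KNOWN_TASKS)}")
            for key in ("vectors",):
                for label in task.get(key, []):
                    if label not in self.vectors:
                        raise ConfigError(
                            f"tasks[{i}] ({name}): undefined vector label {label!r}")
            for key in ("domain", "align", "probe", "stalk", "selection_a",
                        "selection_b", "alignment", "atoms"):
                label = task.get(key)
                if isinstance(label, str) and label not in self.domains:
                    raise ConfigError(
                        f"tasks[{i}] ({name}): undefined domain label {label!r} "
                        f"in field {key!r}")
            label = task.get("substates")
            if isinstance(label, str) and label not in self.substates:
                raise ConfigError(
                    f"tasks[{i}] ({name}): undefined substate label {label!r}")


# ---------------------------------------------------------------------------
# run
# ---------------------------------------------------------------------------

class _Runner:
    def __init__(self, config: AnalysisConfig):
        self.config = config
        self.structures: dict[str, Structure] = {}
        self.trajectories: dict[str, Trajectory] = {}
        self.angle_cache: dict[str, AngleSeries] = {}
        self.outputs: list[Path] = []

    # -- provenance-carrying writers ------------------------------------
    @property
    def provenance(self) -> dict:
        return {"config_hash": self.config.config_hash,
                "seed": self.config.seed,
                "hspdyn_version": __version__}

    def _outpath(self, name: str) -> Path:
        path = self.config.output_dir / name
        path.parent.mkdir(parents=True, exist_ok=True)
        self.outputs.append(path)
        return path

    def write_csv(self, name: str, header: list[str],
                  rows: np.ndarray) -> Path:
        path = self._outpath(name)
        with open(path, "w") as fh:
            for k, v in self.provenance.items():
                fh.write(f"# {k}={v}\n")
            fh.write(",".join(header) + "\n")
            for row in np.atleast_2d(rows):
                fh.write(",".join(f"{v:.6g}" for v in row) + "\n")
        return path

    def write_json(self, name: str, payload: dict) -> Path:
        path = self._outpath(name)
        payload = {"provenance": self.provenance, **payload}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path

    # -- input resolution -------------------------------------------------
    def structure(self, name: str) -> Structure:
        if name not in self.structures:
            if name not in self.config.structures:
                raise ConfigError(f"undefined structure {name!r}")
            self.structures[name] = read_structure(self.config.structures[name])
        return self.structures[name]

    def trajectory(self, name: str) -> Trajectory:
        if name not in self.trajectories:
            if name not in self.config.trajectories:
                raise ConfigError(f"undefined trajectory {name!r}")
            entry = self.config.trajectories[name]
            topo = self.structure(entry["topology"])
            self.trajectories[name] = read_trajectory(
                entry["path"], topo, format=entry["format"],
                frame_interval=entry["frame_interval"])
        return self.trajectories[name]

    def domain(self, label: str) -> DomainDefinition:
        if label not in self.config.domains:
            raise ConfigError(f"undefined domain {label!r}")
        return self.config.domains[label]

    def angles_for(self, task: dict) -> AngleSeries:
        va, vb = task["vectors"]
        key = f"{task['trajectory']}:{va}:{vb}"
        if key not in self.angle_cache:
            traj = self.trajectory(task["trajectory"])
            self.angle_cache[key] = angle_series(
                traj, self.config.vectors[va], self.config.vectors[vb])
        return self.angle_cache[key]

    # -- tasks -------------------------------------------------------------
    def run_task(self, task: dict) -> None:
        getattr(self, "task_" + task["task"].replace("-", "_"))(task)

    def task_simulate(self, task: dict) -> None:
        gen = task.get("generator", {})
        topo = self.structures.get(task.get("topology", ""))
        if topo is None:
            topo = make_ideal_helix(int(gen.get("n_res", 30)))
        spec = SubstateGenSpec(
            centers=tuple(gen.get("centers", (90.0,))),
            widths=tuple(gen.get("widths", (5.0,))),
            occupancies=tuple(gen["occupancies"]) if "occupancies" in gen else None,
            transition_matrix=gen.get("transition_matrix"),
            noise_sigma=float(gen.get("noise_sigma", 0.0)),
            n_frames=int(gen.get("n_frames", 1000)),
            seed=self.config.seed)
        va, vb = task["vectors"]
        traj = make_angle_trajectory(
            topo, (self.config.vectors[va], self.config.vectors[vb]), spec)
        name = task.get("name", "synthetic")
        topo_path = self._outpath(f"{name}_topology.pdb")
        write_structure(topo, topo_path)
        traj_path = self._outpath(f"{name}_traj.xyz")
        write_trajectory_xyz(traj, traj_path)
        self.structures[name] = topo
        self.trajectories[name] = traj
        logger.info("simulate: wrote %s (%d frames)", traj_path, traj.n_frames)

    def task_angles(self, task: dict) -> None:
        series = self.angles_for(task)
        rows = np.column_stack([np.arange(series.n_frames), series.times,
                                series.angles])
        self.write_csv(task.get("output", "angles.csv"),
                       ["frame", "time_ps", "angle_deg"], rows)

    def task_occupancy(self, task: dict) -> None:
        series = self.angles_for(task)
        spec = self.config.substates[task["substates"]]
        report = substate_occupancy(series, spec)
        self.write_json(task.get("output", "occupancy.json"), report.to_dict())

    def task_kde(self, task: dict) -> None:
        series = self.angles_for(task)
        curve = angle_kde(series, bandwidth=task.get("bandwidth", "silverman"),
                          grid_step=float(task.get("grid_step", 0.1)))
        rows = np.column_stack([curve.grid, curve.density])
        self.write_csv(task.get("output", "kde.csv"),
                       ["angle_deg", "density"], rows)

    def task_domain_rmsd(self, task: dict) -> None:
        traj = self.trajectory(task["trajectory"])
        sel = select_atoms(traj.topology, self.domain(task["domain"]))
        series = domain_rmsd_series(traj, sel,
                                    reference_frame=int(task.get("reference_frame", 0)))
        rows = np.column_stack([np.arange(series.values.size), series.times,
                                series.values])
        base = task.get("output", f"rmsd_{task['domain']}")
        self.write_csv(base + ".csv", ["frame", "time_ps", "rmsd_A"], rows)
        self.write_json(base + ".json", {
            "domain": task["domain"], "mean": series.mean, "sd": series.sd,
            "n_frames": int(series.values.size)})

    def task_anchor_rmsd(self, task: dict) -> None:
        traj = self.trajectory(task["trajectory"])
        atoms = select_atoms(traj.topology, self.domain(task["atoms"]))
        align = select_atoms(traj.topology, self.domain(task["alignment"]))
        series = per_atom_deviation_series(
            traj, atoms, align, reference_frame=int(task.get("reference_frame", 0)))
        names = [f"{a.chain_id}:{a.residue_number}:{a.atom_name}"
                 for a in atoms.atoms]
        rows = np.column_stack([np.arange(series.values.shape[0]),
                                series.times, series.values])
        self.write_csv(task.get("output", "anchor_rmsd.csv"),
                       ["frame", "time_ps"] + names, rows)

    def task_anm(self, task: dict) -> None:
        struct = self.structure(task["structure"])
        model = anm_from_calpha(struct,
                                cutoff=float(task.get("cutoff", 10.0)),
                                gamma=float(task.get("gamma", 1.0)),
                                n_modes=int(task.get("n_modes", 10)))
        base = task.get("output", "anm")
        write_nmd(model, self._outpath(base + ".nmd"),
                  title=f"hspdyn ANM {task['structure']}")
        msf = mean_square_fluctuations(model)
        self.write_csv(base + "_msf.csv", ["node", "msf"],
                       np.column_stack([np.arange(msf.size), msf]))
        cc = cross_correlations(model)
        self.write_csv(base + "_crosscorr.csv",
                       [f"n{j}" for j in range(cc.shape[1])], cc)
        self.write_json(base + ".json", {
            "structure": task["structure"], "n_nodes": model.n_nodes,
            "cutoff": model.cutoff, "gamma": model.gamma,
            "n_rigid_skipped": model.n_rigid_skipped,
            "eigenvalues": model.eigenvalues.tolist()})

    def _paired(self, sa: Structure, sb: Structure, label: str):
        d = self.domain(label)
        return select_atoms(sa, d), select_atoms(sb, d)

    def task_rotation(self, task: dict) -> None:
        sa = self.structure(task["structure_a"])
        sb = self.structure(task["structure_b"])
        align = self._paired(sa, sb, task["align"])
        probe = self._paired(sa, sb, task["probe"])
        angle = subdomain_rotation(sa, sb, align, probe,
                                   method=task.get("method", "axis-angle"))
        self.write_json(task.get("output", "rotation.json"), {
            "structure_a": task["structure_a"], "structure_b": task["structure_b"],
            "align": task["align"], "probe": task["probe"],
            "method": task.get("method", "axis-angle"),
            "rotation_deg": angle})

    def task_bend(self, task: dict) -> None:
        struct = self.structure(task["structure"])
        reference: Structure | str = "self"
        if "reference" in task and task["reference"] != "self":
            reference = self.structure(task["reference"])
        angle = stalk_bend_angle(struct, self.domain(task["stalk"]),
                                 int(task["split"]), reference=reference)
        self.write_json(task.get("output", "bend.json"), {
            "structure": task["structure"], "stalk": task["stalk"],
            "split": int(task["split"]),
            "reference": task.get("reference", "self"),
            "bend_deg": angle})

    def task_interface(self, task: dict) -> None:
        struct = self.structure(task["structure"])
        sel_a = select_atoms(struct, self.domain(task["selection_a"]))
        sel_b = select_atoms(struct, self.domain(task["selection_b"]))
        report = contact_map(struct, sel_a, sel_b,
                             sasa_params=SASAParams(),
                             bsa_convention=task.get("bsa_convention",
                                                     "per-interface"))
        base = task.get("output", "interface")
        self.write_json(base + ".json", report.to_dict())
        rows = [[c.residue_a[1], c.residue_b[1], c.min_distance,
                 float(_CLASS_CODE[c.contact_class])] for c in report.contacts]
        self.write_csv(base + "_contacts.csv",
                       ["residue_a", "residue_b", "min_distance_A",
                        "class_code"],
                       np.array(rows) if rows else np.empty((0, 4)))

    def task_displacement(self, task: dict) -> None:
        sa = self.structure(task["structure_a"])
        sb = self.structure(task["structure_b"])
        align = self._paired(sa, sb, task["align"])
        probe = self._paired(sa, sb, task["probe"])
        d = centroid_displacement(sa, sb, align, probe)
        self.write_json(task.get("output", "displacement.json"), {
            "structure_a": task["structure_a"], "structure_b": task["structure_b"],
            "align": task["align"], "probe": task["probe"],
            "displacement_A": d})


_CLASS_CODE = {"vdw": 0, "hbond-capable": 1, "salt-bridge": 2}


def run(config: AnalysisConfig) -> list[Path]:
    """Execute every task in order; returns the list of written outputs.

    Defaults actually used (reference frame, cutoffs, conventions) are echoed
    to the run log so published numbers are auditable.
    """
    config.output_dir.mkdir(parents=True, exist_ok=True)
    runner = _Runner(config)
    log_path = config.output_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    prev_level = logger.level
    if logger.getEffectiveLevel() > logging.INFO:
        logger.setLevel(logging.INFO)  # the run log always records tasks
    try:
        logger.info("config hash %s, seed %d, hspdyn %s",
                    config.config_hash, config.seed, __version__)
        for i, task in enumerate(config.tasks):
            logger.info("task %d: %s %s", i, task["task"],
                        {k: v for k, v in task.items() if k != "task"})
            runner.run_task(task)
    finally:
        logger.setLevel(prev_level)
        logger.removeHandler(handler)
        handler.close()
    return runner.outputs


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def _setup_logging(level: str) -> None:
    logging.basicConfig(level=getattr(logging, level.upper()),
                        format="%(levelname)s %(name)s: %(message)s")


@click.group()
@click.option("--log-level", default="warning",
              type=click.Choice(["debug", "info", "warning", "error"]))
def cli(log_level: str) -> None:
    """Structural-dynamics analyses for chaperone/exchange-factor complexes."""
    _setup_logging(log_level)


@cli.command()
@click.argument("config_path", type=click.Path(exists=True))
@click.option("--out", type=click.Path(), default=None,
              help="Output directory (overrides config).")
@click.option("--seed", type=int, default=None, help="Overrides config seed.")
def analyze(config_path: str, out: str | None, seed: int | None) -> None:
    """Run every task of a JSON analysis config."""
    config = AnalysisConfig.from_file(config_path, seed=seed, output_dir=out)
    outputs = run(config)
    for p in outputs:
        click.echo(p)


@cli.command()
@click.option("--spec", "spec_path", type=click.Path(exists=True), required=True,
              help="JSON generator spec (centers, widths, occupancies, ...).")
@click.option("--out", type=click.Path(), required=True, help="Output directory.")
@click.option("--seed", type=int, default=0)
def simulate(spec_path: str, out: str, seed: int) -> None:
    """Generate a synthetic angular-substate trajectory."""
    gen = json.loads(Path(spec_path).read_text())
    vectors = gen.pop("vectors", {
        "va": {"from": "A:5:CA", "to": "A:12:CA"},
        "vb": {"from": "A:5:CA", "to": "A:25:CA"}})
    raw = {
        "output_dir": out, "seed": seed, "vectors": vectors,
        "tasks": [{"task": "simulate", "generator": gen,
                   "vectors": list(vectors)[:2]}],
    }
    config = AnalysisConfig.from_dict(raw)
    for p in run(config):
        click.echo(p)


@cli.command()
@click.option("--traj", "traj_path", type=click.Path(exists=True), required=True)
@click.option("--topology", "topo_path", type=click.Path(exists=True), required=True)
@click.option("--vec-a", required=True,
              help="chain:res:atom,chain:res:atom (from,to)")
@click.option("--vec-b", required=True)
@click.option("--out", type=click.Path(), default="angles.csv")
@click.option("--frame-interval", type=float, default=2.0)
def angles(traj_path: str, topo_path: str, vec_a: str, vec_b: str,
           out: str, frame_interval: float) -> None:
    """Per-frame inter-vector angle of a trajectory."""
    topo = read_structure(topo_path)
    traj = read_trajectory(traj_path, topo, frame_interval=frame_interval)
    defs = []
    for label, text in (("a", vec_a), ("b", vec_b)):
        f, t = text.split(",")
        defs.append(VectorDefinition(label, AtomRef.parse(f), AtomRef.parse(t)))
    series = angle_series(traj, defs[0], defs[1])
    with open(out, "w") as fh:
        fh.write("frame,time_ps,angle_deg\n")
        for i, (t, a) in enumerate(zip(series.times, series.angles)):
            fh.write(f"{i},{t:.6g},{a:.6g}\n")
    click.echo(out)


@cli.command()
@click.option("--traj", "traj_path", type=click.Path(exists=True), required=True)
@click.option("--topology", "topo_path", type=click.Path(exists=True), required=True)
@click.option("--chain", required=True)
@click.option("--ranges", required=True, help="e.g. 160-217 or 440-555,600-639")
@click.option("--out", type=click.Path(), default="rmsd.csv")
def rmsd(traj_path: str, topo_path: str, chain: str, ranges: str, out: str) -> None:
    """Domain RMSD series (self-aligned per frame)."""
    topo = read_structure(topo_path)
    traj = read_trajectory(traj_path, topo)
    rr = tuple(tuple(int(x) for x in part.split("-")) for part in ranges.split(","))
    sel = select_atoms(topo, DomainDefinition("cli", chain, rr))
    series = domain_rmsd_series(traj, sel)
    with open(out, "w") as fh:
        fh.write("frame,time_ps,rmsd_A\n")
        for i, (t, v) in enumerate(zip(series.times, series.values)):
            fh.write(f"{i},{t:.6g},{v:.6g}\n")
    click.echo(f"{out} mean={series.mean:.4f} sd={series.sd:.4f}")


@cli.command()
@click.option("--structure", "struct_path", type=click.Path(exists=True), required=True)
@click.option("--cutoff", type=float, default=10.0)
@click.option("--gamma", type=float, default=1.0)
@click.option("--n-modes", type=int, default=10)
@click.option("--out", type=click.Path(), default="anm.nmd")
def anm(struct_path: str, cutoff: float, gamma: float, n_modes: int, out: str) -> None:
    """Anisotropic network model of a structure's CA atoms."""
    struct = read_structure(struct_path)
    model = anm_from_calpha(struct, cutoff=cutoff, gamma=gamma, n_modes=n_modes)
    write_nmd(model, out)
    click.echo(f"{out} nodes={model.n_nodes} eigenvalues="
               + ",".join(f"{v:.4g}" for v in model.eigenvalues))


@cli.command()
@click.option("--structure-a", type=click.Path(exists=True), required=True)
@click.option("--structure-b", type=click.Path(exists=True), required=True)
@click.option("--align", required=True, help="chain:lo-hi[,lo-hi...]")
@click.option("--probe", required=True)
@click.option("--method", type=click.Choice(["axis-angle", "helix-axis"]),
              default="axis-angle")
def rotation(structure_a: str, structure_b: str, align: str, probe: str,
             method: str) -> None:
    """Rotation (degrees) of a probe region between two conformations."""
    sa = read_structure(structure_a)
    sb = read_structure(structure_b)

    def sel_pair(spec: str, label: str):
        chain, rest = spec.split(":")
        rr = tuple(tuple(int(x) for x in part.split("-"))
                   for part in rest.split(","))
        d = DomainDefinition(label, chain, rr)
        return select_atoms(sa, d), select_atoms(sb, d)

    angle = subdomain_rotation(sa, sb, sel_pair(align, "align"),
                               sel_pair(probe, "probe"), method=method)
    click.echo(f"rotation_deg={angle:.3f}")


@cli.command()
@click.option("--structure", "struct_path", type=click.Path(exists=True), required=True)
@click.option("--sel-a", required=True, help="chain:lo-hi[,lo-hi...]")
@click.option("--sel-b", required=True)
@click.option("--out", type=click.Path(), default="interface.json")
def interface(struct_path: str, sel_a: str, sel_b: str, out: str) -> None:
    """Contacts and buried surface area between two regions."""
    struct = read_structure(struct_path)

    def sel(spec: str, label: str):
        chain, rest = spec.split(":")
        rr = tuple(tuple(int(x) for x in part.split("-"))
                   for part in rest.split(","))
        return select_atoms(struct, DomainDefinition(label, chain, rr,
                                                     atom_names=None))

    report = contact_map(struct, sel(sel_a, "A"), sel(sel_b, "B"),
                         sasa_params=SASAParams())
    Path(out).write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    click.echo(f"{out} contacts={len(report.contacts)} "
               f"bsa={report.buried_area:.1f}")


def main() -> None:
    """Console entry point with the documented exit-code contract."""
    try:
        cli.main(standalone_mode=False)
    except click.exceptions.Abort:
        sys.exit(1)
    except click.UsageError as exc:
        exc.show()
        sys.exit(2)
    except ConfigError as exc:
        click.echo(f"configuration error: {exc}", err=True)
        sys.exit(2)
    except Exception as exc:  # noqa: BLE001 - CLI boundary
        click.echo(f"error: {exc}", err=True)
        sys.exit(1)


if __name__ == "__main__":
    main()
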