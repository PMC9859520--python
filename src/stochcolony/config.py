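"""Run configuration, workflow orchestration, and fixture generation.

A run configuration is a single YAML document with sections mirroring the
computational modules (``crn``, ``ssa``, ``growth``, ``coupling``,
``bench``) plus a global ``seed`` and ``outdir``.  Every field is validated
against its module's preconditions before any work starts and unknown keys
are rejected, so a bad configuration fails fast with every violation listed.

``run_workflow`` executes the stages whose sections are present (model
generation, SSA runs, colony growth, coupled growth, saturation benchmark)
and writes a manifest of every artifact with its SHA-256 content hash, the
anchor of end-to-end byte-reproducibility checks.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import colony, coupling, crn, sbml_io, ssa

__all__ = ["RunConfig", "ConfigError", "run_workflow", "make_fixtures", "DEFAULTS"]

log = logging.getLogger("stochcolony")

DEFAULTS: dict = {
    "seed": 0,
    "outdir": "out",
    "crn": {
        "sizes": list(crn.MODEL_SIZE_SUITE),
        "topology": "multi_enz",
        "substrate_init": 1000,
        "enzyme_init": 10,
        "k": 0.001,
    },
    "ssa": {
        "method": "tau_leaping",
        "interval": 0.1,
        "max_time": 3.0,
        "n_runs": 1,
        "average": True,
        "tau_epsilon": 0.03,
        "exact_fallback_multiplier": 10.0,
    },
    "growth": {
        "mode": "pseudo_off_lattice",
        "n_workers": 1,
        "cells_per_worker": 100,
        "monolayer": False,
        "obstacle": None,  # path to an OBJ file
        "proliferation_prob": 1.0,
        "death_prob": 0.0,
        "mutation_prob": 0.0,
    },
    "coupling": {
        "probe": "in_process",
        "target": 64,
        "sleep_ms": 10,
    },
    "bench": {
        "activations": 20,
        "workers": 4,
    },
}

_SECTION_KEYS = {name: set(sec) for name, sec in DEFAULTS.items() if isinstance(sec, dict)}


class ConfigError(ValueError):
    """Invalid run configuration; ``.violations`` lists every problem."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid configuration:\n  " + "\n  ".join(violations))


@dataclass
class RunConfig:
    seed: int = 0
    outdir: Path = Path("out")
    crn: dict | None = None
    ssa: dict | None = None
    growth: dict | None = None
    coupling: dict | None = None
    bench: dict | None = None

    @classmethod
    def parse(cls, raw: dict) -> "RunConfig":
        violations: list[str] = []
        known_top = {"seed", "outdir", *_SECTION_KEYS}
        for key in raw:
            if key not in known_top:
                violations.append(f"unknown top-level key {key!r}")
        sections: dict[str, dict | None] = {}
        for name in _SECTION_KEYS:
            sec = raw.get(name)
            if sec is None:
                sections[name] = None
                continue
            if not isinstance(sec, dict):
                violations.append(f"section {name!r} must be a mapping")
                sections[name] = None
                continue
            merged = {**DEFAULTS[name]}
            for key, value in sec.items():
                if key not in _SECTION_KEYS[name]:
                    violations.append(f"unknown key {name}.{key}")
                else:
                    merged[key] = value
            sections[name] = merged
        cfg = cls(
            seed=raw.get("seed", DEFAULTS["seed"]),
            outdir=Path(raw.get("outdir", DEFAULTS["outdir"])),
            **sections,
        )
        violations.extend(cfg._validate())
        if violations:
            raise ConfigError(violations)
        return cfg

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError([f"{path}: top level must be a mapping"])
        return cls.parse(raw)

    def _validate(self) -> list[str]:
        v: list[str] = []
        if not isinstance(self.seed, int):
            v.append("seed must be an integer")
        if self.crn is not None:
            if self.crn["topology"] not in ("multi_enz", "single_enz"):
                v.append("crn.topology must be multi_enz or single_enz")
            sizes = self.crn["sizes"]
            if not sizes or any(int(n) < 1 for n in sizes):
                v.append("crn.sizes must be a non-empty list of counts >= 1")
            if self.crn["k"] < 0:
                v.append("crn.k must be >= 0")
            if self.crn["substrate_init"] < 0 or self.crn["enzyme_init"] < 0:
                v.append("crn initial counts must be >= 0")
        if self.ssa is not None:
            try:
                self._ssa_config()
            except ValueError as exc:
                v.append(f"ssa.{exc}" if "interval" in str(exc) or "max_time" in str(exc) else f"ssa: {exc}")
        if self.growth is not None:
            g = self.growth
            if g["mode"] not in ("pseudo_off_lattice", "on_lattice"):
                v.append("growth.mode must be pseudo_off_lattice or on_lattice")
            if int(g["n_workers"]) < 1 or int(g["cells_per_worker"]) < 1:
                v.append("growth.n_workers and growth.cells_per_worker must be >= 1")
            for p in ("proliferation_prob", "death_prob", "mutation_prob"):
                if not 0.0 <= float(g[p]) <= 1.0:
                    v.append(f"growth.{p} must be in [0, 1]")
            if g["obstacle"] is not None and not Path(g["obstacle"]).exists():
                v.append(f"growth.obstacle file not found: {g['obstacle']}")
        if self.coupling is not None:
            if self.coupling["probe"] not in ("file", "in_process"):
                v.append("coupling.probe must be file or in_process")
            if int(self.coupling["target"]) < 1:
                v.append("coupling.target must be >= 1")
            if float(self.coupling["sleep_ms"]) <= 0:
                v.append("coupling.sleep_ms must be > 0")
        if self.bench is not None:
            if int(self.bench["activations"]) < 1 or int(self.bench["workers"]) < 1:
                v.append("bench.activations and bench.workers must be >= 1")
        return v

    # -- section -> module objects ----------------------------------------
    def _ssa_config(self) -> ssa.SSAConfig:
        s = self.ssa or DEFAULTS["ssa"]
        return ssa.SSAConfig(seed=self.seed, **s)

    def _growth_config(self) -> colony.GrowthConfig:
        g = self.growth or DEFAULTS["growth"]
        obstacle = (
            colony.load_obstacle(g["obstacle"]) if g.get("obstacle") else frozenset()
        )
        return colony.GrowthConfig(
            mode=g["mode"],
            frozen_axes=(2,) if g["monolayer"] else (),
            obstacle=obstacle,
            phenotype=colony.Phenotype(
                proliferation_prob=float(g["proliferation_prob"]),
                death_prob=float(g["death_prob"]),
                mutation_prob=float(g["mutation_prob"]),
            ),
        )

    def normalized(self) -> dict:
        out: dict = {"seed": self.seed, "outdir": str(self.outdir)}
        for name in _SECTION_KEYS:
            sec = getattr(self, name)
            if sec is not None:
                out[name] = dict(sec)
        return out

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.normalized(), sort_keys=True)


# ---------------------------------------------------------------------------
# workflow


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_workflow(config: RunConfig) -> dict:
    """Execute the configured stages; returns the artifact manifest.

    The manifest maps each artifact path (relative to ``outdir``) to its
    SHA-256 hash and is itself written to ``outdir/manifest.json``.
    """
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    models: dict[int, crn.CRNModel] = {}

    if config.crn is not None:
        for n in config.crn["sizes"]:
            model = crn.build_serial_pathway(
                int(n),
                config.crn["topology"],
                int(config.crn["substrate_init"]),
                int(config.crn["enzyme_init"]),
                float(config.crn["k"]),
            )
            models[int(n)] = model
            path = outdir / f"{model.name}.xml"
            sbml_io.write_sbml(model, path)
            artifacts.append(path)
            log.info("generated %s (seed=%d)", path.name, config.seed)

    def primary_model() -> crn.CRNModel:
        if models:
            return models[sorted(models)[0]]
        return crn.build_serial_pathway(4)

    if config.ssa is not None:
        model = primary_model()
        cfg = config._ssa_config()
        traj = ssa.simulate(model, cfg)
        if isinstance(traj, list):
            traj = traj[0]
        path = outdir / f"{model.name}_{cfg.method}.csv"
        ssa.write_trajectory_csv(traj, path)
        artifacts.append(path)
        log.info("simulated %s with %s (seed=%d)", model.name, cfg.method, config.seed)

    if config.growth is not None:
        g = config.growth
        plan = colony.WorkerPlan(int(g["n_workers"]), int(g["cells_per_worker"]))
        mesh = colony.grow_colony(plan, config._growth_config(), seed=config.seed)
        path = outdir / "colony.obj"
        colony.write_obj(mesh, path)
        artifacts.append(path)
        log.info("grew %d vertices (seed=%d)", len(mesh.vertices), config.seed)

    if config.coupling is not None:
        target = int(config.coupling["target"])
        mesh, records, _ = coupling.run_coupled_growth(
            primary_model(),
            config._growth_config(),
            config._ssa_config(),
            target=target,
            growth_seed=config.seed,
            probe_mode=config.coupling["probe"],
            workdir=outdir if config.coupling["probe"] == "file" else None,
            poll_sleep=float(config.coupling["sleep_ms"]) / 1000.0,
        )
        path = outdir / "colony_coupled.obj"
        colony.write_obj(mesh, path)
        artifacts.append(path)
        path = outdir / "coupled_activations.csv"
        coupling.write_bench_csv(records, path)
        artifacts.append(path)
        log.info("coupled growth to %d cells, %d activations", target, len(records))

    if config.bench is not None:
        records, failures = coupling.saturate(
            int(config.bench["activations"]),
            primary_model(),
            config._ssa_config(),
            int(config.bench["workers"]),
        )
        path = outdir / "bench.csv"
        coupling.write_bench_csv(records, path)
        artifacts.append(path)
        log.info("saturation bench: %d completed, %d failed", len(records), failures)

    manifest = {
        str(p.relative_to(outdir)): _sha256(p) for p in artifacts
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# fixtures


def make_fixtures(seed: int, outdir: str | os.PathLike) -> dict[str, Path]:
    """Deterministic small fixture battery.

    2- and 4-reaction models of each topology (SBML), a 27-cell monolayer
    mesh (OBJ), a 1-voxel wall obstacle (OBJ), and a 31-row trajectory CSV.
    Byte-stable for a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fixtures: dict[str, Path] = {}

    for n in (2, 4):
        for topology in ("multi_enz", "single_enz"):
            model = crn.build_serial_pathway(n, topology)
            path = outdir / f"{model.name}.xml"
            sbml_io.write_sbml(model, path)
            fixtures[model.name] = path

    plan = colony.WorkerPlan(1, 27)
    mesh = colony.grow_colony(plan, colony.GrowthConfig(frozen_axes=(2,)), seed=seed)
    path = outdir / "monolayer27.obj"
    colony.write_obj(mesh, path)
    fixtures["monolayer27"] = path

    wall = [(5, y, z) for y in range(-8, 9) for z in range(-8, 9)]
    path = outdir / "wall.obj"
    path.write_text("\n".join(f"v {x} {y} {z}" for x, y, z in wall) + "\n")
    fixtures["wall"] = path

    traj = ssa.simulate(crn.build_serial_pathway(1), ssa.SSAConfig(seed=seed))
    assert not isinstance(traj, list)
    path = outdir / "trajectory.csv"
    ssa.write_trajectory_csv(traj, path)
    fixtures["trajectory"] = path
    return fixtures
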