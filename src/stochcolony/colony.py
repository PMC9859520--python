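"""Batch-processed, worker-partitioned 3D colony growth.

Two growth modes are provided:

* **Pseudo off-lattice stochastic chain extension** — no fixed world bounds,
  but daughters are placed at unit (lattice) spacing from the parent, so a
  plain coordinate hash-set answers the occupancy question.  Each logical
  worker extends a chain: the most recently generated *live* cell replicates
  in a random direction; if the target coordinate is taken the displacement
  is "tunnelled" (multiplied by increasing integer increments) until a free
  coordinate is found.  Obstacle coordinate sets and frozen axes (monolayer
  or line constraints) restrict placement.

* **On-lattice Monte-Carlo seeding** — a fixed cubic boolean occupancy array;
  per sweep, coordinates are visited in a fresh uniform random permutation
  and every cell occupied at the start of the sweep seeds, with probability
  ``p_seed``, one uniformly chosen free cell of its 26-neighbourhood.

Vertices are written to Wavefront OBJ in global slot order
``local_index + cells_per_worker * worker_id``, with parent-daughter edges as
``l`` elements, so the file is deterministic for a fixed mesh regardless of
how workers were scheduled, and Blender-style particle playback over the
ordered vertex sequence animates the growth.

Agents are bacilli or cocci; a bacillus is born at 1.5 um and divides on
doubling to 3 um.  Phenotype records carry the full editor parameter set
(proliferation, contact inhibition, death, neoplastic mutation, adhesion,
differentiation, shape, motility, colour inheritance); contact inhibition,
adhesion and motility are inert data in this batch engine.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Displacement",
    "Phenotype",
    "CellVertex",
    "WorkerPlan",
    "LatticeWorld",
    "ColonyMesh",
    "GrowthConfig",
    "GrowthError",
    "random_unit_displacement",
    "tunnel",
    "grow_chain",
    "grow_colony",
    "inherit_phenotype",
    "grow_on_lattice",
    "load_obstacle",
    "write_obj",
    "read_obj",
    "morphology_search",
    "synchronous_doubling",
]

Coord = tuple[int, int, int]


class GrowthError(RuntimeError):
    """Raised when a chain head cannot place a daughter in any direction."""


@dataclass(frozen=True)
class Displacement:
    dx: int
    dy: int
    dz: int

    def __post_init__(self) -> None:
        for c in (self.dx, self.dy, self.dz):
            if c not in (-1, 0, 1):
                raise ValueError("displacement components must be in {-1, 0, 1}")
        if self.dx == self.dy == self.dz == 0:
            raise ValueError("zero displacement (should have been re-rolled)")

    def scaled(self, increment: int) -> Coord:
        return (self.dx * increment, self.dy * increment, self.dz * increment)


@dataclass(frozen=True)
class Phenotype:
    """Editable per-cell parameter record.

    ``division_length`` is tied to the doubling rule: a bacillus born at
    1.5 um splits at 3 um.  ``contact_inhibition``, ``adhesion`` and
    ``motility_force`` are carried and inherited but do not alter the batch
    growth rules (their physical effects belong to a real-time physics
    engine, not this mesh builder).
    """

    proliferation_prob: float = 1.0
    death_prob: float = 0.0
    mutation_prob: float = 0.0
    color: tuple[float, float, float] = (0.2, 0.8, 0.2)
    shape: str = "bacillus"  # "bacillus" | "coccus"
    birth_length: float = 1.5
    contact_inhibition: float = 0.0
    adhesion: float = 0.0
    motility_force: float = 0.0
    differentiation_prob: float = 0.0

    def __post_init__(self) -> None:
        for name in ("proliferation_prob", "death_prob", "mutation_prob",
                     "differentiation_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.shape not in ("bacillus", "coccus"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.birth_length <= 0:
            raise ValueError("birth_length must be > 0")

    @property
    def division_length(self) -> float:
        """Length at which the cell splits: double the birth length."""
        return 2.0 * self.birth_length

    _MUTABLE_FIELDS = (
        "proliferation_prob", "death_prob", "mutation_prob", "birth_length",
        "contact_inhibition", "adhesion", "motility_force", "differentiation_prob",
    )


@dataclass(frozen=True)
class CellVertex:
    coord: Coord
    parent_slot: int | None  # global slot of the parent; None for founders
    worker_id: int
    local_index: int
    phenotype: Phenotype
    alive: bool = True


@dataclass(frozen=True)
class WorkerPlan:
    """Partition of a target population across logical workers.

    A vertex's global output slot is ``local_index + cells_per_worker *
    worker_id``, which pre-assigns every worker a disjoint block of the
    output array and makes the mesh independent of scheduling.
    """

    n_workers: int
    cells_per_worker: int
    founder_coords: tuple[Coord, ...] = ()

    def __post_init__(self) -> None:
        if self.n_workers < 1 or self.cells_per_worker < 1:
            raise ValueError("n_workers and cells_per_worker must be >= 1")
        if self.founder_coords and len(self.founder_coords) != self.n_workers:
            raise ValueError("need exactly one founder coordinate per worker")
        if not self.founder_coords:
            # default spacing keeps chains from contending: no chain of
            # cells_per_worker unit steps can reach the next founder
            spacing = 2 * self.cells_per_worker
            object.__setattr__(
                self,
                "founder_coords",
                tuple((0, w * spacing, 0) for w in range(self.n_workers)),
            )

    @property
    def total(self) -> int:
        return self.n_workers * self.cells_per_worker

    def slot(self, worker_id: int, local_index: int) -> int:
        return local_index + self.cells_per_worker * worker_id

    @classmethod
    def for_total(cls, total: int, n_workers: int) -> "WorkerPlan":
        if total % n_workers != 0:
            raise ValueError(f"{total} cells do not divide evenly over {n_workers} workers")
        return cls(n_workers=n_workers, cells_per_worker=total // n_workers)


@dataclass
class ColonyMesh:
    """Ordered vertex list plus parent-daughter edge list."""

    vertices: list[CellVertex]
    edges: list[tuple[int, int]]  # (parent slot, child slot), 0-based
    obstacle: frozenset[Coord] = frozenset()

    @property
    def n_founders(self) -> int:
        return sum(1 for v in self.vertices if v.parent_slot is None)

    def coordinates(self) -> list[Coord]:
        return [v.coord for v in self.vertices]

    def bounding_box(self) -> tuple[Coord, Coord]:
        xs, ys, zs = zip(*(v.coord for v in self.vertices))
        return (min(xs), min(ys), min(zs)), (max(xs), max(ys), max(zs))

    def validate(self) -> None:
        coords = self.coordinates()
        if len(set(coords)) != len(coords):
            raise ValueError("single-occupancy violated: duplicate coordinates")
        n = len(self.vertices)
        for p, c in self.edges:
            if not (0 <= p < n and 0 <= c < n):
                raise ValueError(f"dangling edge ({p}, {c})")
        if len(self.edges) != n - self.n_founders:
            raise ValueError("edge count != vertices - founders")
        if self.obstacle and set(coords) & self.obstacle:
            raise ValueError("vertices placed on obstacle coordinates")


@dataclass(frozen=True)
class GrowthConfig:
    mode: str = "pseudo_off_lattice"  # or "on_lattice"
    frozen_axes: tuple[int, ...] = ()  # e.g. (2,) freezes z -> monolayer
    obstacle: frozenset[Coord] = frozenset()
    phenotype: Phenotype = field(default_factory=Phenotype)
    max_increment: int = 10_000
    max_redraws: int = 100
    mutation_jitter: float = 0.1  # relative amplitude of mutated numeric fields
    max_updates_factor: int = 1000  # updates budget = factor * target cells

    def __post_init__(self) -> None:
        if self.mode not in ("pseudo_off_lattice", "on_lattice"):
            raise ValueError(f"unknown growth mode {self.mode!r}")
        if not set(self.frozen_axes) <= {0, 1, 2} or len(self.frozen_axes) > 2:
            raise ValueError("frozen_axes must name at most two of axes 0, 1, 2")
        if self.max_increment < 1 or self.max_redraws < 1:
            raise ValueError("max_increment and max_redraws must be >= 1")


# ---------------------------------------------------------------------------
# primitive moves


def random_unit_displacement(rng: random.Random, frozen_axes: Sequence[int] = ()) -> Displacement:
    """Each component is ``randint(0, 2) - 1``; the all-zero draw is re-rolled.

    Frozen axes are pinned to 0 (their raw draw is skipped entirely so a
    monolayer run consumes the same stream per accepted move).
    """
    frozen = set(frozen_axes)
    while True:
        comps = [0 if axis in frozen else rng.randrange(3) - 1 for axis in range(3)]
        if any(comps):
            return Displacement(*comps)


def tunnel(
    origin: Coord,
    disp: Displacement,
    occupied: set[Coord] | frozenset[Coord],
    max_increment: int,
    obstacle: frozenset[Coord] = frozenset(),
) -> Coord | None:
    """Smallest-increment free coordinate along ``disp``, or None if blocked.

    Checks ``origin + increment * disp`` for increment = 1, 2, ... up to
    ``max_increment`` against both the colony occupancy and the obstacle set.
    """
    ox, oy, oz = origin
    for inc in range(1, max_increment + 1):
        target = (ox + disp.dx * inc, oy + disp.dy * inc, oz + disp.dz * inc)
        if target not in occupied and target not in obstacle:
            return target
    return None


def inherit_phenotype(parent: Phenotype, rng: random.Random, jitter: float = 0.1) -> Phenotype:
    """Daughter phenotype: exact copy, or a neoplastic-mutation variant.

    With probability ``mutation_prob`` every numeric field is perturbed by a
    uniform relative jitter (clamped to its domain) and the colour is redrawn
    uniformly; otherwise the parent record is inherited unchanged (colour
    inheritance is exact).
    """
    if parent.mutation_prob <= 0.0 or rng.random() >= parent.mutation_prob:
        return parent
    changes: dict[str, object] = {}
    for name in Phenotype._MUTABLE_FIELDS:
        v = getattr(parent, name)
        v = v * (1.0 + jitter * (2.0 * rng.random() - 1.0))
        if name.endswith("_prob"):
            v = min(max(v, 0.0), 1.0)
        changes[name] = v
    changes["color"] = (rng.random(), rng.random(), rng.random())
    return replace(parent, **changes)


# ---------------------------------------------------------------------------
# pseudo off-lattice stochastic chain extension


def grow_chain(
    plan: WorkerPlan,
    worker_id: int,
    shared_occupancy: set[Coord],
    config: GrowthConfig,
    rng: random.Random,
) -> list[CellVertex]:
    """Grow one worker's chain to exactly ``cells_per_worker`` vertices.

    The parent of each new vertex is the worker's most recently generated
    *live* vertex.  Dead daughters (``death_prob``) stay in the mesh but are
    never chain heads.  Raises :class:`GrowthError` if ``max_redraws``
    consecutive directions from the head are blocked, or the update budget
    is exhausted (possible when ``proliferation_prob`` is very small).
    """
    founder_coord = plan.founder_coords[worker_id]
    if founder_coord in shared_occupancy or founder_coord in config.obstacle:
        raise GrowthError(f"worker {worker_id}: founder coordinate {founder_coord} occupied")
    shared_occupancy.add(founder_coord)
    founder = CellVertex(founder_coord, None, worker_id, 0, config.phenotype)
    cells = [founder]
    head = founder

    budget = config.max_updates_factor * plan.cells_per_worker
    while len(cells) < plan.cells_per_worker:
        if budget <= 0:
            raise GrowthError(
                f"worker {worker_id}: update budget exhausted at {len(cells)} cells"
            )
        budget -= 1
        if head.phenotype.proliferation_prob < 1.0 and rng.random() >= head.phenotype.proliferation_prob:
            continue
        target = None
        for _ in range(config.max_redraws):
            disp = random_unit_displacement(rng, config.frozen_axes)
            target = tunnel(head.coord, disp, shared_occupancy, config.max_increment, config.obstacle)
            if target is not None:
                break
        if target is None:
            raise GrowthError(
                f"worker {worker_id}: no free coordinate in {config.max_redraws} directions "
                f"from {head.coord}"
            )
        shared_occupancy.add(target)
        pheno = inherit_phenotype(head.phenotype, rng, config.mutation_jitter)
        alive = not (pheno.death_prob > 0.0 and rng.random() < pheno.death_prob)
        child = CellVertex(
            coord=target,
            parent_slot=plan.slot(worker_id, head.local_index),
            worker_id=worker_id,
            local_index=len(cells),
            phenotype=pheno,
            alive=alive,
        )
        cells.append(child)
        if alive:
            head = child
    return cells


def grow_colony(
    plan: WorkerPlan,
    config: GrowthConfig,
    seed: int = 0,
    division_hook=None,
) -> ColonyMesh:
    """Run every worker's chain against one shared occupancy set.

    Workers execute in worker-id order with independent RNG substreams, so
    the result depends only on ``(plan, config, seed)``.  ``division_hook``,
    if given, is called as ``hook(parent_slot, child_slot)`` immediately
    before each division is committed — the coupling layer uses it to gate
    divisions on subcellular-run completion without touching the growth RNG.
    """
    occupancy: set[Coord] = set()
    vertices: list[CellVertex] = []
    edges: list[tuple[int, int]] = []
    for worker_id in range(plan.n_workers):
        rng = random.Random(f"{seed}:{worker_id}")
        cells = grow_chain(plan, worker_id, occupancy, config, rng)
        for cell in cells:
            slot = plan.slot(worker_id, cell.local_index)
            if cell.parent_slot is not None:
                if division_hook is not None:
                    division_hook(cell.parent_slot, slot)
                edges.append((cell.parent_slot, slot))
        vertices.extend(cells)
    # vertices arrive in worker blocks == global slot order by construction
    mesh = ColonyMesh(vertices=vertices, edges=edges, obstacle=config.obstacle)
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# on-lattice Monte-Carlo variant


_NEIGHBORHOOD = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)


@dataclass
class LatticeWorld:
    """Fixed cubic occupancy array seeded with a single founder cell."""

    world_diameter: int
    founder: Coord = (0, 0, 0)
    occupancy: set[Coord] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.world_diameter < 1:
            raise ValueError("world_diameter must be >= 1")
        if not self._in_bounds(self.founder):
            raise ValueError("founder outside world")
        if not self.occupancy:
            self.occupancy.add(self.founder)

    def _in_bounds(self, c: Coord) -> bool:
        return all(0 <= v < self.world_diameter for v in c)

    @property
    def occupied_count(self) -> int:
        return len(self.occupancy)

    def all_coords(self) -> list[Coord]:
        d = self.world_diameter
        return [(x, y, z) for x in range(d) for y in range(d) for z in range(d)]


def _sweep_order(world: LatticeWorld, rng: random.Random) -> list[Coord]:
    """A fresh uniform random permutation of every lattice coordinate."""
    coords = world.all_coords()
    rng.shuffle(coords)
    return coords


def grow_on_lattice(
    world: LatticeWorld, p_seed: float, n_sweeps: int, rng: random.Random
) -> LatticeWorld:
    """Monte-Carlo lattice seeding.

    Per sweep the coordinates are visited in a fresh random permutation;
    each cell occupied *at the start of the sweep* seeds, with probability
    ``p_seed``, one uniformly chosen free coordinate of its 26-neighbourhood
    (if any free neighbour exists).  Occupancy is boolean and never cleared.
    """
    if not 0.0 <= p_seed <= 1.0:
        raise ValueError("p_seed must be in [0, 1]")
    for _ in range(n_sweeps):
        active = frozenset(world.occupancy)
        for coord in _sweep_order(world, rng):
            if coord not in active:
                continue
            if p_seed < 1.0 and rng.random() >= p_seed:
                continue
            x, y, z = coord
            free = [
                (x + dx, y + dy, z + dz)
                for dx, dy, dz in _NEIGHBORHOOD
                if world._in_bounds((x + dx, y + dy, z + dz))
                and (x + dx, y + dy, z + dz) not in world.occupancy
            ]
            if free:
                world.occupancy.add(free[rng.randrange(len(free))])
    return world


# ---------------------------------------------------------------------------
# OBJ input/output


def load_obstacle(obj_path: str | os.PathLike, voxel_size: float = 1.0) -> frozenset[Coord]:
    """Snap an OBJ mesh's vertices to the colony lattice.

    Every ``v x y z`` line contributes the lattice coordinate nearest to
    ``(x, y, z) / voxel_size``; other OBJ record types are ignored.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be > 0")
    coords = set()
    with open(obj_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0] != "v":
                continue
            if len(parts) < 4:
                raise ValueError(f"{obj_path}:{lineno}: malformed vertex line {line.rstrip()!r}")
            try:
                x, y, z = (float(p) for p in parts[1:4])
            except ValueError as exc:
                raise ValueError(
                    f"{obj_path}:{lineno}: malformed vertex line {line.rstrip()!r}"
                ) from exc
            coords.add(tuple(int(round(v / voxel_size)) for v in (x, y, z)))
    return frozenset(coords)


def write_obj(mesh: ColonyMesh, path: str | os.PathLike) -> Path:
    """Write vertices (slot order) and parent-daughter ``l`` edges, 1-based."""
    mesh.validate()
    path = Path(path)
    lines = []
    for v in mesh.vertices:
        x, y, z = v.coord
        lines.append(f"v {x} {y} {z}")
    for p, c in mesh.edges:
        lines.append(f"l {p + 1} {c + 1}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_obj(path: str | os.PathLike) -> tuple[list[Coord], list[tuple[int, int]]]:
    """Recover the ordered vertex list and 0-based edge list from an OBJ file."""
    vertices: list[Coord] = []
    edges: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                if len(parts) < 4:
                    raise ValueError(f"{path}:{lineno}: malformed vertex line")
                vertices.append(tuple(int(round(float(p))) for p in parts[1:4]))
            elif parts[0] == "l":
                i, j = int(parts[1]), int(parts[2])
                edges.append((i - 1, j - 1))
    return vertices, edges


# ---------------------------------------------------------------------------
# randomized morphology search & synchronous doubling


def morphology_search(
    ranges: dict[str, tuple[float, float]],
    cell_limit: int,
    stagnation_timeout: int,
    n_cycles: int,
    rng: random.Random,
    frozen_axes: tuple[int, ...] = (),
) -> list[tuple[Phenotype, dict]]:
    """Randomized parameter-sweep cycles with stagnation reset.

    Each cycle samples a phenotype uniformly from ``ranges`` (keys are
    Phenotype field names, values (lo, hi) bounds), grows a single-worker
    colony until ``cell_limit`` cells or until no new cell appears for
    ``stagnation_timeout`` consecutive updates, and records the sampled
    phenotype with summary statistics before resetting.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    records: list[tuple[Phenotype, dict]] = []
    for _ in range(n_cycles):
        sampled = Phenotype(
            **{name: rng.uniform(lo, hi) for name, (lo, hi) in ranges.items()}
        )
        occupancy: set[Coord] = {(0, 0, 0)}
        vertices: list[Coord] = [(0, 0, 0)]
        head: Coord = (0, 0, 0)
        stagnant = 0
        stagnated = False
        while len(vertices) < cell_limit:
            grew = False
            if rng.random() < sampled.proliferation_prob:
                disp = random_unit_displacement(rng, frozen_axes)
                target = tunnel(head, disp, occupancy, 10_000)
                if target is not None:
                    occupancy.add(target)
                    vertices.append(target)
                    head = target
                    grew = True
            if grew:
                stagnant = 0
            else:
                stagnant += 1
                if stagnant >= stagnation_timeout:
                    stagnated = True
                    break
        xs, ys, zs = zip(*vertices)
        summary = {
            "final_count": len(vertices),
            "bounding_box": ((min(xs), min(ys), min(zs)), (max(xs), max(ys), max(zs))),
            "stagnated": stagnated,
        }
        records.append((sampled, summary))
    return records


def synchronous_doubling(
    n_generations: int, phenotype: Phenotype | None = None
) -> list[float]:
    """Synchronised growth-and-division from one founder.

    Each generation every cell elongates from its birth length to the
    doubling threshold (2x) and splits into two daughters at birth length.
    Returns the population's cell lengths after ``n_generations`` divisions
    (so the population size is ``2 ** n_generations``).
    """
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    pheno = phenotype or Phenotype()
    lengths = [pheno.birth_length]
    for _ in range(n_generations):
        next_gen = []
        for length in lengths:
            grown = 2.0 * length  # elongation to the doubling threshold
            next_gen.extend([grown / 2.0, grown / 2.0])
        lengths = next_gen
    return lengths
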