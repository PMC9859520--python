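"""Colony growth: displacements, tunnelling, chains, lattice, OBJ, phenotypes."""

import math
import random
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stochcolony import (
    Displacement,
    GrowthConfig,
    GrowthError,
    LatticeWorld,
    Phenotype,
    WorkerPlan,
    grow_chain,
    grow_colony,
    grow_on_lattice,
    inherit_phenotype,
    load_obstacle,
    morphology_search,
    random_unit_displacement,
    read_obj,
    synchronous_doubling,
    tunnel,
    write_obj,
)
from stochcolony.colony import _sweep_order


class ScriptedRng(random.Random):
    """Replays a fixed script of randrange(3) draws, then delegates."""

    def __init__(self, script):
        super().__init__(0)
        self.script = list(script)

    def randrange(self, *args):
        if self.script:
            return self.script.pop(0)
        return super().randrange(*args)


# ---------------------------------------------------------------------------
# displacements


def test_displacement_formula_maps_raw_draws():
    """Raw draws (0, 1, 2) map to components (-1, 0, 1)."""
    d = random_unit_displacement(ScriptedRng([0, 1, 2]))
    assert (d.dx, d.dy, d.dz) == (-1, 0, 1)


def test_zero_vector_rejected_and_redrawn():
    d = random_unit_displacement(ScriptedRng([1, 1, 1, 2, 1, 1]))
    assert (d.dx, d.dy, d.dz) == (1, 0, 0)


def test_displacement_type_rejects_zero_and_out_of_range():
    with pytest.raises(ValueError):
        Displacement(0, 0, 0)
    with pytest.raises(ValueError):
        Displacement(2, 0, 0)


def test_frozen_axis_pinned_to_zero(rng):
    for _ in range(200):
        d = random_unit_displacement(rng, frozen_axes=(2,))
        assert d.dz == 0 and (d.dx, d.dy) != (0, 0)


def test_displacement_frequencies_uniform_over_26_vectors(rng):
    """26,000 draws: each nonzero vector within 4 sigma of 1000."""
    counts = Counter(
        (d.dx, d.dy, d.dz) for d in (random_unit_displacement(rng) for _ in range(26_000))
    )
    assert len(counts) == 26
    bound = 4 * math.sqrt(26_000 * (1 / 26) * (25 / 26))
    assert all(abs(c - 1000) < bound for c in counts.values())


# ---------------------------------------------------------------------------
# tunnelling


def test_tunnel_takes_first_free_increment():
    assert tunnel((0, 0, 0), Displacement(1, 0, 0), {(1, 0, 0)}, 10) == (2, 0, 0)


def test_tunnel_increment_one_when_free():
    assert tunnel((0, 0, 0), Displacement(1, 0, 0), set(), 10) == (1, 0, 0)


def test_tunnel_exhaustion_signals_blocked():
    occupied = {(i, 0, 0) for i in range(1, 11)}
    assert tunnel((0, 0, 0), Displacement(1, 0, 0), occupied, 10) is None


def test_tunnel_respects_obstacle():
    wall = frozenset({(1, 0, 0), (2, 0, 0)})
    assert tunnel((0, 0, 0), Displacement(1, 0, 0), set(), 10, obstacle=wall) == (3, 0, 0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    disp=st.tuples(*(st.integers(-1, 1),) * 3).filter(lambda t: any(t)),
    blocked=st.integers(0, 6),
)
def test_tunnel_returns_smallest_free_multiple(disp, blocked):
    """Property: the result is origin + m*disp with every smaller multiple occupied."""
    d = Displacement(*disp)
    occupied = {d.scaled(i) for i in range(1, blocked + 1)}
    got = tunnel((0, 0, 0), d, occupied, 100)
    assert got == d.scaled(blocked + 1)


# ---------------------------------------------------------------------------
# chain growth


def test_single_cell_worker_is_just_the_founder(default_growth, rng):
    plan = WorkerPlan(1, 1)
    cells = grow_chain(plan, 0, set(), default_growth, rng)
    assert len(cells) == 1 and cells[0].parent_slot is None


def test_chain_parent_is_most_recent_live_cell(small_plan, default_growth, rng):
    cells = grow_chain(small_plan, 1, set(), default_growth, rng)
    assert len(cells) == small_plan.cells_per_worker
    for i in range(1, len(cells)):
        assert cells[i].parent_slot == small_plan.slot(1, i - 1)


def test_dead_cells_kept_but_skipped_as_parents():
    plan = WorkerPlan(1, 200)
    config = GrowthConfig(phenotype=Phenotype(death_prob=0.3))
    cells = grow_chain(plan, 0, set(), config, random.Random("death"))
    assert len(cells) == 200
    dead_slots = {plan.slot(0, c.local_index) for c in cells if not c.alive}
    assert dead_slots  # the death rate should have produced some
    assert all(c.parent_slot not in dead_slots for c in cells if c.parent_slot is not None)


def test_growth_error_when_fully_walled_in():
    # box the founder in completely with a tight max_increment
    wall = frozenset(
        (x, y, z)
        for x in range(-3, 4)
        for y in range(-3, 4)
        for z in range(-3, 4)
        if (x, y, z) != (0, 0, 0)
    )
    plan = WorkerPlan(1, 5, founder_coords=((0, 0, 0),))
    config = GrowthConfig(obstacle=wall, max_increment=3, max_redraws=20)
    with pytest.raises(GrowthError):
        grow_chain(plan, 0, set(), config, random.Random(1))


def test_colony_single_occupancy_and_tree_structure(default_growth):
    plan = WorkerPlan(3, 80)
    mesh = grow_colony(plan, default_growth, seed=5)
    coords = mesh.coordinates()
    assert len(set(coords)) == len(coords)
    assert mesh.n_founders == 3
    assert len(mesh.edges) == len(mesh.vertices) - 3
    # edges connect each child to an earlier slot in the same worker block
    cpw = plan.cells_per_worker
    for p, c in mesh.edges:
        assert p // cpw == c // cpw and p < c


def test_monolayer_planarity(default_growth):
    mesh = grow_colony(WorkerPlan(2, 100), GrowthConfig(frozen_axes=(2,)), seed=8)
    zs = {c[2] for c in mesh.coordinates()}
    assert len(zs) == 1


def test_obstacle_exclusion_in_grown_colony():
    wall = frozenset((5, y, z) for y in range(-30, 31) for z in range(-30, 31))
    mesh = grow_colony(WorkerPlan(1, 500), GrowthConfig(obstacle=wall), seed=2)
    assert not set(mesh.coordinates()) & wall


def test_worker_partition_arithmetic():
    plan = WorkerPlan.for_total(252_000, 50)
    assert plan.cells_per_worker == 5040
    with pytest.raises(ValueError):
        WorkerPlan.for_total(10, 3)


# ---------------------------------------------------------------------------
# phenotype inheritance


def test_no_mutation_inherits_exactly(rng):
    parent = Phenotype(mutation_prob=0.0, color=(0.1, 0.2, 0.3))
    assert inherit_phenotype(parent, rng) == parent


def test_certain_mutation_with_zero_jitter_redraws_only_color(rng):
    parent = Phenotype(mutation_prob=1.0, color=(0.1, 0.2, 0.3))
    child = inherit_phenotype(parent, rng, jitter=0.0)
    assert child.color != parent.color
    assert child.proliferation_prob == parent.proliferation_prob
    assert child.birth_length == parent.birth_length


def test_mutated_fraction_matches_binomial(rng):
    parent = Phenotype(mutation_prob=0.1)
    n = 1000
    mutated = sum(1 for _ in range(n) if inherit_phenotype(parent, rng) is not parent)
    bound = 3 * math.sqrt(0.1 * 0.9 / n)
    assert abs(mutated / n - 0.1) < bound


def test_doubling_rule():
    p = Phenotype(birth_length=1.5)
    assert p.division_length == 3.0


def test_synchronous_doubling_population():
    lengths = synchronous_doubling(13)
    assert len(lengths) == 8192
    assert all(length == 1.5 for length in lengths)


# ---------------------------------------------------------------------------
# on-lattice Monte-Carlo


def test_lattice_zero_probability_never_seeds(rng):
    world = grow_on_lattice(LatticeWorld(5, founder=(2, 2, 2)), 0.0, 10, rng)
    assert world.occupancy == {(2, 2, 2)}


def test_lattice_centered_founder_seeds_exactly_one_per_sweep(rng):
    """Only cells occupied at sweep start act, so sweep 1 yields exactly 2."""
    world = LatticeWorld(3, founder=(1, 1, 1))
    grow_on_lattice(world, 1.0, 1, rng)
    assert world.occupied_count == 2


def test_lattice_occupancy_nondecreasing_and_bounded(rng):
    world = LatticeWorld(3, founder=(1, 1, 1))
    prev = 1
    for _ in range(8):
        grow_on_lattice(world, 1.0, 1, rng)
        assert world.occupied_count >= prev
        prev = world.occupied_count
    assert prev <= 27


def test_sweep_order_is_a_permutation(rng):
    world = LatticeWorld(4)
    order = _sweep_order(world, rng)
    assert sorted(order) == world.all_coords()


# ---------------------------------------------------------------------------
# OBJ IO


def test_obstacle_vertex_snapping(tmp_path):
    p = tmp_path / "obs.obj"
    p.write_text("v 0 0 0\nv 0.4 0 0\n")
    assert load_obstacle(p, voxel_size=1.0) == {(0, 0, 0)}


def test_empty_obstacle(tmp_path):
    p = tmp_path / "obs.obj"
    p.write_text("# nothing here\n")
    assert load_obstacle(p) == frozenset()


def test_malformed_obstacle_names_line(tmp_path):
    p = tmp_path / "obs.obj"
    p.write_text("v 0 0 0\nv broken\n")
    with pytest.raises(ValueError, match=":2"):
        load_obstacle(p)


def test_obj_body_layout(tmp_path, default_growth):
    """Worker 2 with cells_per_worker 3: its first cell (slot 6) is the 7th v line."""
    plan = WorkerPlan(3, 3)
    mesh = grow_colony(plan, default_growth, seed=4)
    path = write_obj(mesh, tmp_path / "c.obj")
    lines = path.read_text().splitlines()
    v_lines = [ln for ln in lines if ln.startswith("v ")]
    assert len(v_lines) == 9
    assert plan.slot(worker_id=2, local_index=0) == 6
    assert v_lines[6] == "v {} {} {}".format(*plan.founder_coords[2])
    # edges are 1-based slot references
    l_lines = [ln for ln in lines if ln.startswith("l ")]
    assert len(l_lines) == 6
    verts, edges = read_obj(path)
    assert verts == mesh.coordinates()
    assert edges == mesh.edges


def test_minimal_obj_encoding(tmp_path):
    from stochcolony import CellVertex, ColonyMesh

    mesh = ColonyMesh(
        vertices=[
            CellVertex((0, 0, 0), None, 0, 0, Phenotype()),
            CellVertex((1, 0, 0), 0, 0, 1, Phenotype()),
        ],
        edges=[(0, 1)],
    )
    body = write_obj(mesh, tmp_path / "m.obj").read_text()
    assert body == "v 0 0 0\nv 1 0 0\nl 1 2\n"


def test_dangling_edge_rejected(tmp_path):
    from stochcolony import CellVertex, ColonyMesh

    mesh = ColonyMesh(
        vertices=[CellVertex((0, 0, 0), None, 0, 0, Phenotype())],
        edges=[(0, 5)],
    )
    with pytest.raises(ValueError, match="dangling|edge"):
        write_obj(mesh, tmp_path / "m.obj")


def test_fixed_seed_obj_byte_identical(tmp_path, default_growth):
    plan = WorkerPlan(2, 60)
    a = write_obj(grow_colony(plan, default_growth, seed=9), tmp_path / "a.obj")
    b = write_obj(grow_colony(plan, default_growth, seed=9), tmp_path / "b.obj")
    assert a.read_bytes() == b.read_bytes()


# ---------------------------------------------------------------------------
# morphology search


def test_morphology_search_reaches_limit_when_certain(rng):
    records = morphology_search(
        {"proliferation_prob": (1.0, 1.0)}, cell_limit=30, stagnation_timeout=50,
        n_cycles=5, rng=rng,
    )
    assert len(records) == 5
    for pheno, summary in records:
        assert summary["final_count"] == 30
        assert summary["stagnated"] is False


def test_morphology_search_stagnates_without_proliferation(rng):
    records = morphology_search(
        {"proliferation_prob": (0.0, 0.0)}, cell_limit=30, stagnation_timeout=10,
        n_cycles=3, rng=rng,
    )
    for pheno, summary in records:
        assert summary["final_count"] == 1
        assert summary["stagnated"] is True
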