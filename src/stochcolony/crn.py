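"""Serial-pathway chemical reaction network benchmark models.

Builds families of enzymatic serial pathways S0 -> S1 -> ... -> Sn in two
topologies:

* ``multi_enz`` — reaction i is catalysed by its own enzyme Ei, so the only
  coupling between consecutive reactions is the shared intermediate substrate.
* ``single_enz`` — every reaction is catalysed by one shared enzyme E, which
  couples the propensity of *all* reactions through a single species.

Each reaction is elementary mass-action ``S_{i-1} + E -> S_i + E`` with rate
constant ``k``.  The default parameterisation (high substrate, low enzyme,
small k) keeps all propensities low, the regime in which tau-leaping is
expected to outperform exact methods.

Topological summary statistics (reaction-graph and species-graph density) are
the quantities algorithm-recommendation heuristics consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import networkx as nx

__all__ = [
    "Species",
    "Reaction",
    "CRNModel",
    "TopologyStats",
    "build_serial_pathway",
    "network_properties",
    "MODEL_SIZE_SUITE",
]

#: reaction counts of the benchmark suite
MODEL_SIZE_SUITE = (2, 3, 4, 8, 16, 32, 48, 64, 128)

Topology = Literal["multi_enz", "single_enz", "other"]


@dataclass(frozen=True)
class Species:
    """A chemical species with a discrete copy number."""

    id: str
    initial_count: int
    role: str = "substrate"  # "substrate" | "enzyme"

    def __post_init__(self) -> None:
        if self.initial_count < 0:
            raise ValueError(f"species {self.id!r}: initial_count must be >= 0")
        if self.role not in ("substrate", "enzyme"):
            raise ValueError(f"species {self.id!r}: unknown role {self.role!r}")


@dataclass(frozen=True)
class Reaction:
    """Mass-action reaction: reactants/products are (species id, stoichiometry)."""

    id: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    k: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"reaction {self.id!r}: k must be >= 0")
        for sid, stoich in (*self.reactants, *self.products):
            if stoich < 1 or int(stoich) != stoich:
                raise ValueError(
                    f"reaction {self.id!r}: stoichiometry of {sid!r} must be a "
                    f"positive integer, got {stoich!r}"
                )

    @property
    def species_ids(self) -> set[str]:
        return {sid for sid, _ in self.reactants} | {sid for sid, _ in self.products}

    @property
    def catalysts(self) -> set[str]:
        """Species appearing on both sides (net stoichiometry checked as sets)."""
        return {sid for sid, _ in self.reactants} & {sid for sid, _ in self.products}


@dataclass
class CRNModel:
    """Species plus an ordered list of mass-action reactions."""

    species: list[Species]
    reactions: list[Reaction]
    topology: Topology = "other"
    name: str = "crn"

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def species_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    def initial_counts(self) -> list[int]:
        return [s.initial_count for s in self.species]

    def validate(self) -> None:
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate species ids: {dupes}")
        declared = set(ids)
        for rxn in self.reactions:
            missing = rxn.species_ids - declared
            if missing:
                raise ValueError(
                    f"reaction {rxn.id!r} references undeclared species {sorted(missing)}"
                )
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise ValueError("duplicate reaction ids")

    def structurally_equal(self, other: "CRNModel") -> bool:
        """Same species (ids, counts, roles), same ordered reactions, same k."""
        return (
            [(s.id, s.initial_count) for s in self.species]
            == [(s.id, s.initial_count) for s in other.species]
            and [
                (r.id, r.reactants, r.products, r.k) for r in self.reactions
            ]
            == [(r.id, r.reactants, r.products, r.k) for r in other.reactions]
        )


@dataclass(frozen=True)
class TopologyStats:
    """Graph-density summary consumed by SSA-recommendation heuristics."""

    reaction_graph_density: float
    species_graph_density: float
    n_reactions: int
    n_species: int


def build_serial_pathway(
    n_reactions: int,
    topology: str = "multi_enz",
    substrate_init: int = 1000,
    enzyme_init: int = 10,
    k: float = 0.001,
) -> CRNModel:
    """Build a serial enzymatic pathway of ``n_reactions`` steps.

    Reaction i (1-based) is ``S_{i-1} + E_i -> S_i + E_i`` (multi_enz) or
    ``S_{i-1} + E -> S_i + E`` (single_enz).  Only S0 and the enzymes start
    with nonzero counts; all intermediates and the terminal product start
    at zero.

    Parameters
    ----------
    n_reactions
        Pathway length, >= 1.
    topology
        ``"multi_enz"`` (one enzyme per reaction) or ``"single_enz"``
        (one shared enzyme).
    substrate_init, enzyme_init
        Initial copy numbers of S0 and of each enzyme.
    k
        Mass-action rate constant shared by every reaction
        (per molecule-pair per time unit).
    """
    if n_reactions < 1:
        raise ValueError(f"n_reactions must be >= 1, got {n_reactions}")
    if topology not in ("multi_enz", "single_enz"):
        raise ValueError(f"unknown topology {topology!r}")
    if substrate_init < 0 or enzyme_init < 0:
        raise ValueError("initial counts must be >= 0")
    if k < 0:
        raise ValueError("k must be >= 0")

    species: list[Species] = [
        Species(f"S{i}", substrate_init if i == 0 else 0, "substrate")
        for i in range(n_reactions + 1)
    ]
    if topology == "multi_enz":
        enzymes = [f"E{i}" for i in range(1, n_reactions + 1)]
    else:
        enzymes = ["E"]
    species.extend(Species(e, enzyme_init, "enzyme") for e in enzymes)

    reactions = []
    for i in range(1, n_reactions + 1):
        enz = enzymes[i - 1] if topology == "multi_enz" else "E"
        reactions.append(
            Reaction(
                id=f"R{i}",
                reactants=((f"S{i - 1}", 1), (enz, 1)),
                products=((f"S{i}", 1), (enz, 1)),
                k=k,
            )
        )
    return CRNModel(
        species=species,
        reactions=reactions,
        topology=topology,  # type: ignore[arg-type]
        name=f"{topology}_{n_reactions}",
    )


def _density(graph: nx.Graph) -> float:
    # density of a graph with <= 1 node is defined as 0
    if graph.number_of_nodes() <= 1:
        return 0.0
    return nx.density(graph)


def network_properties(model: CRNModel) -> TopologyStats:
    """Reaction-graph and species-graph densities.

    Reaction graph: node per reaction, edge iff two reactions share at least
    one species.  Species graph: node per species, edge iff two species
    co-occur in at least one reaction.  Density is ``2E / (V(V-1))``.
    """
    rg = nx.Graph()
    rg.add_nodes_from(r.id for r in model.reactions)
    for i, a in enumerate(model.reactions):
        for b in model.reactions[i + 1 :]:
            if a.species_ids & b.species_ids:
                rg.add_edge(a.id, b.id)

    sg = nx.Graph()
    sg.add_nodes_from(s.id for s in model.species)
    for rxn in model.reactions:
        ids = sorted(rxn.species_ids)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                sg.add_edge(a, b)

    return TopologyStats(
        reaction_graph_density=_density(rg),
        species_graph_density=_density(sg),
        n_reactions=model.n_reactions,
        n_species=model.n_species,
    )
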