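# Methods

## Benchmark model family

The generator builds serial enzymatic pathways in which reaction *i*
converts substrate S₍ᵢ₋₁₎ into Sᵢ under an enzyme that is returned
unchanged. The kinetic law is elementary mass-action, aⱼ = k·[S]·[E] for the
generated models; in general the propensity is the falling-factorial product
aⱼ = kⱼ ∏ᵢ xᵢ(xᵢ−1)⋯(xᵢ−sᵢ+1) over reactant stoichiometries (no 1/s!
factor — every generated model has stoichiometry 1, so the convention is
visible only to user-supplied models). Defaults are substrate_init = 1000,
enzyme_init = 10, k = 0.001 per molecule-pair per time unit: a
high-substrate/low-enzyme regime in which every initial propensity is at
most 10 and approximate leaping is expected to do well. The suite sizes are
{2, 3, 4, 8, 16, 32, 48, 64, 128} reactions. Identifiers are S0..Sn and
E1..En (or a single E), which makes serialisation round-trip stable.

SBML output is Level 3 Version 1 with one compartment of size 1 and species
stored as amounts (counts), the unambiguous choice for discrete stochastic
simulation. The reader accepts exactly this mass-action dialect and infers
the topology tag from the catalyst pattern: one catalyst shared by ≥ 2
reactions → `single_enz`; one distinct catalyst per reaction → `multi_enz`
(a 1-reaction pathway resolves here, since the two patterns coincide);
anything else → `other`.

Graph statistics: the reaction graph joins reactions sharing ≥ 1 species,
the species graph joins species co-occurring in ≥ 1 reaction; density is
2E/(V(V−1)), defined as 0 for V ≤ 1. For a multi-enz pathway of length
n ≥ 2 the reaction graph is a path, so the density is 2/n; the shared
enzyme of single-enz makes it complete (density 1).

## Stochastic simulation engine

Three canonical samplers are implemented against a compiled stoichiometry
(index arrays, net-change matrix, and a reaction dependency graph):

* **direct** — waiting time τ = −ln u₁/a₀; reaction index by inverse CDF on
  the cumulative propensities; only propensities affected by the fired
  reaction are recomputed.
* **next_reaction** (Gibson–Bruck) — a priority queue of putative absolute
  firing times; after a firing, affected reactions rescale their putative
  times by a_old/a_new (fresh exponentials for the fired reaction or when a
  propensity rises from zero). Stale heap entries are skipped on pop.
* **tau_leaping** — step size from the bounded-relative-propensity-change
  criterion with ε = 0.03 and order bound g = 2 (safe for at-most-bimolecular
  reactions): τ = minᵢ(max(εxᵢ/2, 1)/|μᵢ|, max(εxᵢ/2, 1)²/σᵢ²) over reactant
  species. When τ < 10/a₀ (the `exact_fallback_multiplier`) a leap is not
  worthwhile and one exact step is taken instead. Poisson firing bundles that
  would drive any count negative are rejected and the leap halved.

Sampling is piecewise-constant on the grid 0, Δ, …, T (the value at a grid
point is the state after the last event at or before it); `max_time` must be
an integer multiple of `interval`, giving a fixed-shape output (31 rows at
the reference settings Δ = 0.1, T = 3). Absorbing states hold their final
counts to the horizon, so the CSV always has the full grid — which is what
makes file-based completion detection and element-wise averaging trivial.
Multi-run simulations draw independent PCG64 substreams via
`SeedSequence(seed).spawn(n_runs)` and reduce by an order-fixed element-wise
mean; with `average=False` the per-run trajectories are returned.
`simulate` returns a single `Trajectory` when averaging (or for one run),
else a list. Trajectory CSVs are written atomically (temp file + rename)
with shortest-round-trip float formatting, so identical (model, config,
seed) gives bit-identical files and an observer can never read a torn file.

The exact-method validation rests on the 1-reaction pathway being a linear
death process at per-molecule rate c = k·E: E[S(t)] = N·e^(−ct) and
Var[S(t)] = N·e^(−ct)(1 − e^(−ct)). Tests check both at n = 2000 runs
within 3 standard errors, cross-check direct vs next-reaction final-count
distributions with a two-sample KS test (α = 0.01, 1000 runs per arm), and
require the tau-leaping mean within 1% of the direct mean.

## Colony growth

**Pseudo off-lattice chain extension.** Coordinates are integer lattice
points with unit = one cell diameter, so occupancy is a hash-set membership
test rather than a geometric overlap test. Each worker's chain head (most
recent live cell) proposes a displacement with components Random(0..2) − 1.
The all-zero vector (probability 1/27 of the raw draw) is rejected and
redrawn, since tunnelling along a zero vector cannot terminate. If the
target is occupied, tunnelling scales the displacement by increments
1, 2, … up to `max_increment` (default 10⁴) and takes the first free,
non-obstacle coordinate; a blocked direction is redrawn up to
`max_redraws` = 100 times before growth fails. Obstacles are OBJ vertex
sets snapped to the lattice (nearest integer after voxel scaling); frozen
axes pin displacement components to 0, giving monolayer (one axis) or
linear (two axes) growth.

Workers share one occupancy set. Output slots are pre-assigned by
`local_index + cells_per_worker × worker_id`, so the OBJ vertex order never
depends on scheduling; execution is serial in worker order with per-worker
RNG substreams (`random.Random(f"{seed}:{worker_id}")`), and the default
founder spacing of 2 × cells_per_worker along one axis means chains cannot
contend, making serial execution equivalent to any interleaving. Daughters
inherit the phenotype record exactly unless a neoplastic mutation fires
(probability `mutation_prob`), in which case numeric fields get a uniform
relative jitter (default amplitude 0.1, probabilities clamped to [0, 1])
and the colour is redrawn. Dead daughters (`death_prob`) remain mesh
vertices — the mesh records every created cell — but are skipped as chain
heads. Contact inhibition, adhesion and motility force are carried and
inherited as data but do not alter the batch growth rules; their physical
effects belong to a real-time physics engine, which this package
deliberately does not contain.

**On-lattice variant.** A cubic boolean array; per sweep, coordinates are
visited in a fresh uniform permutation and each cell occupied *at the start
of the sweep* seeds, with probability `p_seed`, one uniformly chosen free
26-neighbour. Snapshotting at sweep start keeps one sweep equal to one
synchronous generation under random update order (a centred founder at
p_seed = 1 yields exactly 2 cells after sweep one). The neighbourhood is
Moore (26-connectivity) in both modes, matching the {−1,0,1}³ displacement
set.

**Division rule.** Bacilli are born at 1.5 µm and divide at double size,
3 µm; `synchronous_doubling(g)` applies this rule generation-synchronously
(2^g cells, all back at birth length). The randomized morphology search
samples phenotype parameters uniformly per cycle, grows until a cell limit
or until no cell has been added for `stagnation_timeout` consecutive
updates, records summary statistics, and resets.

## Coupling and benchmarking

The tick gate is the three-state machine AWAITING = 0 → COMPLETE = 1 →
READY = 2 with transitions fire (READY→AWAITING, sets the fired flag),
output_detected (AWAITING→COMPLETE), output_cleared (COMPLETE→READY) and
divide (READY with fired set; resets the flag). Cells fire at birth — a
fresh gate defaults to READY, so the subcellular model runs before any
growth — hence total activations equal the number of cells when every
parent divides at most once, while gated divisions equal target − founders.
A parent dividing again (possible when daughters die) must complete a new
activation first. File-mode completion detection polls for a parseable CSV
whose last row is at the configured horizon, sleeping between polls
(default 10 ms) to bound CPU cost, and deletes the file on detection;
in-process mode checks a run handle directly and is the default batch
channel. Because trajectories feed nothing back, coupled and uncoupled
colonies from the same growth seed are byte-identical OBJ files — tests
enforce this, along with an audit that no division appears in the log
without a completed fire/detect/clear cycle on the dividing cell's slot.

The saturation harness submits n independent activations to a thread pool
of w workers and reports per-activation submit/complete timestamps plus
batch time-per-cell. Wall-clock values are recorded but never asserted
numerically (hardware-dependent); the only automated check is the
qualitative plateau smoke test.

## Problem sizes and numerical choices

The test suite runs the obstacle scenario at its full 10 × 60,000-cell
scale (a few seconds on one CPU), statistical SSA checks at 1000–2000 runs,
and coupled growth at 12–64 cells — sizes at which every statistical bound
stated above has comfortable power while the whole suite stays fast.
Floats are serialised with `repr` (shortest exact form) everywhere
determinism is asserted. Seeds below 2³¹ are used throughout; all
randomness derives from explicit seeds, with colony growth on Python's
`random.Random` (string-keyed per-worker substreams) and the SSA engine on
NumPy PCG64 spawned substreams.

## Known limitations

* The SBML reader covers only the mass-action subset the writer emits, not
  arbitrary exchange documents.
* Only three SSA variants are implemented; the method registry accepts
  additional kernels but none of the other direct-method refinements
  (logarithmic, optimized, partial-propensity) are present.
* Growth is rules-based on an integer lattice: no continuous-space
  mechanics, collision resolution, diffusion fields or phenotype feedback
  from the subcellular trajectories (the coupling is deliberately
  completion-only).
* Worker parallelism is logical; the saturation harness uses real threads,
  but chain growth executes serially per worker in a deterministic order.
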