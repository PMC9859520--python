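"""Gate colony divisions on subcellular stochastic runs via the tick gate.

Each cell fires one SSA run of a 4-reaction pathway at birth; its gate
walks READY -> AWAITING -> COMPLETE -> READY, and only a READY+fired cell
may divide.  The trajectories feed nothing back, so the mesh is identical
to an uncoupled colony grown from the same seed — coupling changes when
divisions happen, never where.
"""

from stochcolony import (
    GrowthConfig,
    SSAConfig,
    WorkerPlan,
    build_serial_pathway,
    grow_colony,
    run_coupled_growth,
)

model = build_serial_pathway(4, "multi_enz")
target, seed = 64, 7

mesh, records, log = run_coupled_growth(
    model, GrowthConfig(), SSAConfig(method="tau_leaping"), target=target,
    growth_seed=seed,
)
plain = grow_colony(WorkerPlan(1, target), GrowthConfig(), seed=seed)

print(f"cells                : {len(mesh.vertices)}")
print(f"gated divisions      : {len(log.divisions)}")     # target - 1 founder
print(f"completed activations: {len(records)}")           # one per cell
print(f"mesh matches uncoupled: {mesh.coordinates() == plain.coordinates()}")
print(f"batch time per cell  : {records[0].time_per_cell * 1000:.2f} ms")
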