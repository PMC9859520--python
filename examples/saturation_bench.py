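"""Saturate a worker pool with concurrent SSA activations.

Submits many independent tau-leaping runs of one benchmark model to a
thread pool and prints the batch time-per-cell for increasing activation
counts — the quantity whose plateau marks processor saturation.  Absolute
numbers are hardware-dependent; only the trend is meaningful.
"""

from stochcolony import SSAConfig, build_serial_pathway, saturate

model = build_serial_pathway(8, "multi_enz")
cfg = SSAConfig(method="tau_leaping", seed=0)

for n_activations in (1, 4, 16, 64):
    records, failures = saturate(n_activations, model, cfg, n_workers=4)
    print(
        f"activations={n_activations:3d} completed={len(records):3d} "
        f"failed={failures} time/cell={records[0].time_per_cell * 1000:7.2f} ms"
    )
# time-per-cell falls towards a plateau as concurrent activations fill the
# pool; beyond saturation it flattens out.
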