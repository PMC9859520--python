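"""Tick-gate coupling of colony growth to the SSA engine, plus the
saturation benchmark harness.

Every cell carries a three-state gate.  A fresh gate is READY (2); firing
the subcellular stochastic run sets it to AWAITING (0); detecting the run's
CSV output sets it to COMPLETE (1); clearing (deleting) the output returns
it to READY with the fired flag set, and only then may the cell divide.
Daughters start the same cycle over.  The subcellular trajectories carry no
feedback into the growth rules — completion alone gates division — so a
coupled colony is byte-identical to an uncoupled one grown from the same
growth seed; the coupling changes when divisions happen, not where.

The saturation harness submits many independent SSA activations to a worker
pool and records per-activation submit/complete timestamps plus the batch
time-per-cell, the quantity whose plateau marks processor saturation.
"""

from __future__ import annotations

import csv
import os
import tempfile
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

from .colony import ColonyMesh, GrowthConfig, WorkerPlan, grow_colony
from .crn import CRNModel
from .ssa import SSAConfig, compile_model, read_trajectory_csv, simulate, write_trajectory_csv

__all__ = [
    "GateState",
    "TickGate",
    "GateProtocolError",
    "CompletionProbe",
    "BenchRecord",
    "tick_gate_step",
    "poll_completion",
    "run_coupled_growth",
    "saturate",
    "write_bench_csv",
]


class GateState(IntEnum):
    AWAITING = 0
    COMPLETE = 1
    READY = 2


class GateProtocolError(RuntimeError):
    """An event was applied in a state where it is illegal."""


@dataclass
class TickGate:
    """Per-cell division gate; fresh gates default to READY with fired unset."""

    state: GateState = GateState.READY
    fired: bool = False


_TRANSITIONS = {
    ("fire", GateState.READY): GateState.AWAITING,
    ("output_detected", GateState.AWAITING): GateState.COMPLETE,
    ("output_cleared", GateState.COMPLETE): GateState.READY,
}


def tick_gate_step(gate: TickGate, event: str) -> TickGate:
    """Apply one gate event in place (returns the same gate for chaining).

    Legal sequence per cell cycle:
    READY --fire--> AWAITING --output_detected--> COMPLETE
    --output_cleared--> READY(fired) --divide--> READY (fired reset).
    """
    if event == "divide":
        if gate.state is not GateState.READY or not gate.fired:
            raise GateProtocolError(
                f"event 'divide' illegal in state {gate.state.name} (fired={gate.fired})"
            )
        gate.fired = False
        return gate
    key = (event, gate.state)
    if key not in _TRANSITIONS:
        raise GateProtocolError(f"event {event!r} illegal in state {gate.state.name}")
    gate.state = _TRANSITIONS[key]
    if event == "fire":
        gate.fired = True
    return gate


# ---------------------------------------------------------------------------
# completion probes


@dataclass
class CompletionProbe:
    """How completion of one subcellular run is detected.

    ``file`` mode polls for a complete trajectory CSV (exists, parses, last
    row's time equals ``expected_max_time``), sleeping between checks;
    detection deletes the file (clearing the output).  ``in_process`` mode
    checks a run handle directly.
    """

    mode: str = "in_process"  # "file" | "in_process"
    path: Path | None = None
    sleep: float = 0.01
    expected_max_time: float = 3.0

    def __post_init__(self) -> None:
        if self.mode not in ("file", "in_process"):
            raise ValueError(f"unknown probe mode {self.mode!r}")
        if self.mode == "file":
            if self.sleep <= 0:
                raise ValueError("sleep must be > 0 in file mode")
            if self.path is None:
                raise ValueError("file mode needs a path")


def _csv_complete(path: Path, expected_max_time: float) -> bool:
    try:
        traj = read_trajectory_csv(path)
    except ValueError:
        return False
    return abs(float(traj.times[-1]) - expected_max_time) < 1e-9


def poll_completion(probe: CompletionProbe, deadline: float, handle=None) -> bool:
    """Wait for run completion; True on detection (output then cleared).

    File mode sleeps ``probe.sleep`` between checks and gives up after
    ``deadline`` seconds (at least one check).  A file that is present but
    unreadable at the deadline raises OSError; a readable-but-incomplete
    file (e.g. a truncated CSV) is simply never detected.
    """
    if probe.mode == "in_process":
        return bool(handle.done()) if handle is not None else False
    assert probe.path is not None
    n_polls = max(1, int(round(deadline / probe.sleep)))
    for _ in range(n_polls):
        time.sleep(probe.sleep)
        if probe.path.exists() and _csv_complete(probe.path, probe.expected_max_time):
            probe.path.unlink()  # clear the output; deletion confirmed by unlink
            return True
    if probe.path.exists():
        try:
            probe.path.read_bytes()
        except OSError:
            raise
    return False


# ---------------------------------------------------------------------------
# coupled growth


@dataclass
class BenchRecord:
    activation_id: int
    model_size: int
    t_submit: float
    t_complete: float
    time_per_cell: float = 0.0

    def __post_init__(self) -> None:
        if self.t_complete < self.t_submit:
            raise ValueError("t_complete must be >= t_submit")


@dataclass
class CoupledRunLog:
    """Audit trail: gate events and division events per cell slot."""

    gate_events: list[tuple[int, str]] = field(default_factory=list)
    divisions: list[tuple[int, int]] = field(default_factory=list)  # (parent, child)
    activations: dict[int, list[int]] = field(default_factory=dict)  # slot -> activation ids


def run_coupled_growth(
    model: CRNModel,
    growth_config: GrowthConfig,
    ssa_cfg: SSAConfig,
    target: int,
    n_workers: int = 1,
    growth_seed: int = 0,
    probe_mode: str = "in_process",
    workdir: str | os.PathLike | None = None,
    poll_sleep: float = 0.01,
    deadline: float = 600.0,
) -> tuple[ColonyMesh, list[BenchRecord], CoupledRunLog]:
    """Grow to ``target`` cells, gating every division on one completed
    subcellular run of ``model``.

    Each cell fires its run at birth (gates default to READY, so the model
    fires before growth), hence total activations equal the number of cells
    while gated divisions equal ``target - founders``.  Trajectories are
    discarded — there is no phenotype feedback — so the mesh depends only on
    ``(growth_config, growth_seed)``.
    """
    if target < 1:
        raise ValueError("target must be >= 1")
    plan = WorkerPlan.for_total(target, n_workers)
    cm_size = model.n_reactions
    log = CoupledRunLog()
    records: list[BenchRecord] = []
    gates: dict[int, TickGate] = {}
    tmpdir = Path(workdir) if workdir is not None else None
    batch_t0 = time.perf_counter()

    def run_activation(slot: int, gate: TickGate) -> None:
        """One full gate cycle: fire, run the model, detect output, clear it."""
        activation_id = len(records)
        log.activations.setdefault(slot, []).append(activation_id)
        tick_gate_step(gate, "fire")
        log.gate_events.append((slot, "fire"))
        t_submit = time.perf_counter()
        run_cfg = SSAConfig(**{**ssa_cfg.__dict__, "seed": (ssa_cfg.seed + activation_id) % (2**31)})
        traj = simulate(model, run_cfg)
        if isinstance(traj, list):
            traj = traj[0]
        if probe_mode == "file":
            assert tmpdir is not None
            csv_path = tmpdir / f"activation_{activation_id}.csv"
            write_trajectory_csv(traj, csv_path)
            probe = CompletionProbe(
                mode="file", path=csv_path, sleep=poll_sleep,
                expected_max_time=ssa_cfg.max_time,
            )
            if not poll_completion(probe, deadline):
                raise RuntimeError(f"activation {activation_id}: output never detected")
        t_complete = time.perf_counter()
        tick_gate_step(gate, "output_detected")
        log.gate_events.append((slot, "output_detected"))
        tick_gate_step(gate, "output_cleared")
        log.gate_events.append((slot, "output_cleared"))
        records.append(BenchRecord(activation_id, cm_size, t_submit, t_complete))

    def activate(slot: int) -> None:
        """Birth-time activation: a fresh READY gate fires immediately."""
        gate = TickGate()
        gates[slot] = gate
        run_activation(slot, gate)

    def division_hook(parent_slot: int, child_slot: int) -> None:
        if parent_slot not in gates:
            activate(parent_slot)  # founder's birth activation
        gate = gates[parent_slot]
        if not gate.fired:
            # second or later division: the divide reset the flag, so a new
            # cycle's activation must complete before dividing again
            run_activation(parent_slot, gate)
        if gate.state is not GateState.READY:
            raise GateProtocolError(
                f"division of slot {parent_slot} attempted with gate "
                f"{gate.state.name} (fired={gate.fired})"
            )
        tick_gate_step(gate, "divide")
        log.gate_events.append((parent_slot, "divide"))
        log.divisions.append((parent_slot, child_slot))
        activate(child_slot)  # daughter begins its own cycle

    mesh = grow_colony(plan, growth_config, seed=growth_seed, division_hook=division_hook)
    # founders of childless (single-cell) workers still fire at birth
    for v in mesh.vertices:
        slot = plan.slot(v.worker_id, v.local_index)
        if slot not in gates:
            activate(slot)
    batch_total = time.perf_counter() - batch_t0
    per_cell = batch_total / max(len(records), 1)
    records = [
        BenchRecord(r.activation_id, r.model_size, r.t_submit, r.t_complete, per_cell)
        for r in records
    ]
    return mesh, records, log


# ---------------------------------------------------------------------------
# saturation benchmark


def saturate(
    n_activations: int,
    model: CRNModel,
    ssa_cfg: SSAConfig,
    n_workers: int,
) -> tuple[list[BenchRecord], int]:
    """Submit ``n_activations`` independent SSA runs to ``n_workers`` workers.

    Returns one record per completed activation (``time_per_cell`` filled
    with the batch total divided by completions) and the failure count;
    submitted always equals completed + failed.
    """
    if n_activations < 1 or n_workers < 1:
        raise ValueError("n_activations and n_workers must be >= 1")

    def one(activation_id: int) -> BenchRecord:
        t_submit = time.perf_counter()
        cfg = SSAConfig(**{**ssa_cfg.__dict__, "seed": (ssa_cfg.seed + activation_id) % (2**31)})
        simulate(model, cfg)
        return BenchRecord(activation_id, model.n_reactions, t_submit, time.perf_counter())

    t0 = time.perf_counter()
    records: list[BenchRecord] = []
    failures = 0
    with ThreadPoolExecutor(max_workers=n_workers) as pool:
        futures = [pool.submit(one, i) for i in range(n_activations)]
        for fut in futures:
            try:
                records.append(fut.result())
            except Exception:
                failures += 1
    batch_total = time.perf_counter() - t0
    per_cell = batch_total / max(len(records), 1)
    records = [
        BenchRecord(r.activation_id, r.model_size, r.t_submit, r.t_complete, per_cell)
        for r in records
    ]
    return records, failures


def write_bench_csv(records: list[BenchRecord], path: str | os.PathLike) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["activation_id", "model_size", "t_submit", "t_complete"])
        for r in records:
            writer.writerow([r.activation_id, r.model_size, repr(r.t_submit), repr(r.t_complete)])
    return path
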