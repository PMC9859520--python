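"""Exact and approximate Gillespie stochastic simulation of CRN models.

Three methods are registered:

``direct``
    Gillespie's direct method: waiting time tau = -ln(u1)/a0, reaction index
    by inverse-CDF on the cumulative propensities.
``next_reaction``
    Gibson–Bruck next reaction method: indexed priority queue of putative
    firing times with a reaction dependency graph; only affected propensities
    are recomputed after each firing.
``tau_leaping``
    Poisson tau-leaping with bounded-relative-propensity-change step
    selection, exact-step fallback when the chosen leap is shorter than a few
    SSA steps, and tau-halving rejection of leaps that would drive any count
    negative.

All methods sample the state on a fixed grid ``0, interval, ..., max_time``
with piecewise-constant (last event at or before the grid point) semantics,
the convention under which a trajectory CSV has a fixed shape regardless of
when the system absorbs.
"""

from __future__ import annotations

import heapq
import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np

from .crn import CRNModel

__all__ = [
    "SSAConfig",
    "SystemState",
    "Trajectory",
    "CompiledModel",
    "compile_model",
    "propensities",
    "step_direct",
    "simulate",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "METHODS",
]

METHODS = ("direct", "next_reaction", "tau_leaping")


@dataclass(frozen=True)
class SSAConfig:
    """Simulation settings.

    The reference benchmark settings are ``tau_leaping`` at interval 0.1 with
    max_time 3 over a single run.
    """

    method: str = "direct"
    interval: float = 0.1
    max_time: float = 3.0
    n_runs: int = 1
    average: bool = True
    seed: int = 0
    tau_epsilon: float = 0.03
    exact_fallback_multiplier: float = 10.0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.interval <= 0:
            raise ValueError("interval must be > 0")
        if self.max_time <= 0:
            raise ValueError("max_time must be > 0")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not (0 < self.tau_epsilon < 1):
            raise ValueError("tau_epsilon must be in (0, 1)")
        if self.exact_fallback_multiplier <= 0:
            raise ValueError("exact_fallback_multiplier must be > 0")
        n_steps = self.max_time / self.interval
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("max_time must be an integer multiple of interval")

    @property
    def n_grid(self) -> int:
        return int(round(self.max_time / self.interval)) + 1

    def grid(self) -> np.ndarray:
        return np.linspace(0.0, self.max_time, self.n_grid)


@dataclass
class SystemState:
    """Instantaneous state of one stochastic run."""

    t: float
    counts: np.ndarray
    propensities: np.ndarray
    a0: float


@dataclass
class Trajectory:
    """Counts sampled on a fixed time grid (one run, or a mean over runs)."""

    times: np.ndarray
    counts: np.ndarray  # shape (n_grid, n_species)
    species_ids: list[str]
    n_runs_averaged: int = 1

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.times), len(self.species_ids)):
            raise ValueError("counts shape does not match grid and species list")

    def column(self, species_id: str) -> np.ndarray:
        return self.counts[:, self.species_ids.index(species_id)]

    def final_counts(self) -> np.ndarray:
        return self.counts[-1]


# ---------------------------------------------------------------------------
# compiled stoichiometry


class CompiledModel:
    """Model reduced to index arrays for fast propensity and state updates."""

    def __init__(self, model: CRNModel):
        self.model = model
        self.species_ids = model.species_ids
        index = model.species_index()
        self.n_species = model.n_species
        self.n_reactions = model.n_reactions
        self.k = np.array([r.k for r in model.reactions], dtype=float)
        # per-reaction reactant (index, stoich) arrays
        self.reactant_idx = [
            np.array([index[sid] for sid, _ in r.reactants], dtype=np.intp)
            for r in model.reactions
        ]
        self.reactant_stoich = [
            np.array([s for _, s in r.reactants], dtype=np.intp)
            for r in model.reactions
        ]
        # net state-change matrix, shape (n_reactions, n_species)
        self.delta = np.zeros((self.n_reactions, self.n_species), dtype=np.int64)
        for j, r in enumerate(model.reactions):
            for sid, s in r.reactants:
                self.delta[j, index[sid]] -= s
            for sid, s in r.products:
                self.delta[j, index[sid]] += s
        # dependency graph: affects[j] = reactions whose propensity changes
        # when reaction j fires (reactant sets intersect j's changed species)
        changed = [set(np.nonzero(self.delta[j])[0]) for j in range(self.n_reactions)]
        reactant_sets = [set(idx.tolist()) for idx in self.reactant_idx]
        self.affects = [
            np.array(
                [i for i in range(self.n_reactions) if reactant_sets[i] & changed[j]],
                dtype=np.intp,
            )
            for j in range(self.n_reactions)
        ]

    def propensity(self, j: int, counts: np.ndarray) -> float:
        a = self.k[j]
        for idx, s in zip(self.reactant_idx[j], self.reactant_stoich[j]):
            x = counts[idx]
            for m in range(s):
                a *= x - m
        return max(a, 0.0)

    def all_propensities(self, counts: np.ndarray) -> np.ndarray:
        if np.any(counts < 0):
            raise ValueError("negative molecule counts")
        return np.array(
            [self.propensity(j, counts) for j in range(self.n_reactions)], dtype=float
        )


def compile_model(model: CRNModel) -> CompiledModel:
    return CompiledModel(model)


def propensities(counts, model: CRNModel | CompiledModel) -> np.ndarray:
    """Mass-action propensities a_j = k_j * prod falling-factorial(x_i, s_i)."""
    cm = model if isinstance(model, CompiledModel) else CompiledModel(model)
    return cm.all_propensities(np.asarray(counts, dtype=np.int64))


def initial_state(cm: CompiledModel) -> SystemState:
    counts = np.array(cm.model.initial_counts(), dtype=np.int64)
    a = cm.all_propensities(counts)
    return SystemState(t=0.0, counts=counts, propensities=a, a0=float(a.sum()))


def step_direct(state: SystemState, model: CRNModel | CompiledModel, rng) -> SystemState | None:
    """One direct-method step; returns None in an absorbing state (a0 = 0)."""
    cm = model if isinstance(model, CompiledModel) else CompiledModel(model)
    if state.a0 <= 0.0:
        return None
    u1 = rng.random()
    tau = -math.log(u1) / state.a0
    u2 = rng.random()
    j = int(np.searchsorted(np.cumsum(state.propensities), u2 * state.a0))
    j = min(j, cm.n_reactions - 1)
    counts = state.counts + cm.delta[j]
    a = cm.all_propensities(counts)
    return SystemState(t=state.t + tau, counts=counts, propensities=a, a0=float(a.sum()))


# ---------------------------------------------------------------------------
# run kernels: each yields (event_time, counts_after_event) increments


class _GridSampler:
    """Fill a sampling grid with piecewise-constant sample-path values."""

    def __init__(self, grid: np.ndarray, n_species: int):
        self.grid = grid
        self.out = np.empty((len(grid), n_species), dtype=float)
        self.cursor = 0

    def advance(self, t_next_event: float, counts_now: np.ndarray) -> None:
        """Record ``counts_now`` for every grid point strictly before the next event."""
        while self.cursor < len(self.grid) and self.grid[self.cursor] < t_next_event:
            self.out[self.cursor] = counts_now
            self.cursor += 1

    def finish(self, counts_final: np.ndarray) -> np.ndarray:
        while self.cursor < len(self.grid):
            self.out[self.cursor] = counts_final
            self.cursor += 1
        return self.out


def _run_direct(cm: CompiledModel, cfg: SSAConfig, rng: np.random.Generator) -> np.ndarray:
    grid = cfg.grid()
    sampler = _GridSampler(grid, cm.n_species)
    counts = np.array(cm.model.initial_counts(), dtype=np.int64)
    t = 0.0
    a = cm.all_propensities(counts)
    a0 = float(a.sum())
    cum = np.cumsum(a)
    while a0 > 0.0:
        tau = -math.log(rng.random()) / a0
        t_new = t + tau
        if t_new > cfg.max_time:
            break
        sampler.advance(t_new, counts)
        j = int(np.searchsorted(cum, rng.random() * a0))
        j = min(j, cm.n_reactions - 1)
        counts = counts + cm.delta[j]
        for i in cm.affects[j]:
            a[i] = cm.propensity(i, counts)
        a0 = float(a.sum())
        cum = np.cumsum(a)
        t = t_new
    return sampler.finish(counts)


def _run_next_reaction(cm: CompiledModel, cfg: SSAConfig, rng: np.random.Generator) -> np.ndarray:
    grid = cfg.grid()
    sampler = _GridSampler(grid, cm.n_species)
    counts = np.array(cm.model.initial_counts(), dtype=np.int64)
    a = cm.all_propensities(counts)
    # putative absolute firing times
    tau_abs = np.where(a > 0, -np.log(rng.random(cm.n_reactions)) / np.where(a > 0, a, 1.0), np.inf)
    heap = [(tau_abs[j], j) for j in range(cm.n_reactions)]
    heapq.heapify(heap)
    t = 0.0
    while heap:
        t_j, j = heapq.heappop(heap)
        if t_j != tau_abs[j]:  # stale entry
            continue
        if not math.isfinite(t_j) or t_j > cfg.max_time:
            break
        sampler.advance(t_j, counts)
        counts = counts + cm.delta[j]
        t = t_j
        for i in cm.affects[j]:
            a_old = a[i]
            a_new = cm.propensity(i, counts)
            a[i] = a_new
            if i == j:
                tau_abs[j] = (
                    t - math.log(rng.random()) / a_new if a_new > 0 else math.inf
                )
            elif a_new > 0:
                if math.isfinite(tau_abs[i]) and a_old > 0:
                    tau_abs[i] = t + (a_old / a_new) * (tau_abs[i] - t)
                else:
                    tau_abs[i] = t - math.log(rng.random()) / a_new
            else:
                tau_abs[i] = math.inf
            heapq.heappush(heap, (tau_abs[i], i))
        if j not in cm.affects[j]:
            a_new = cm.propensity(j, counts)
            a[j] = a_new
            tau_abs[j] = t - math.log(rng.random()) / a_new if a_new > 0 else math.inf
            heapq.heappush(heap, (tau_abs[j], j))
    return sampler.finish(counts)


def _select_tau(cm: CompiledModel, counts: np.ndarray, a: np.ndarray, eps: float) -> float:
    """Bounded relative propensity change (species-based step selection)."""
    mu = a @ cm.delta  # expected net change per unit time, per species
    sigma2 = (a @ (cm.delta.astype(float) ** 2))
    tau = math.inf
    reactant_species = set()
    for idx in cm.reactant_idx:
        reactant_species.update(idx.tolist())
    for i in reactant_species:
        # g_i = 2 is a safe order bound for at-most-bimolecular reactions
        bound = max(eps * counts[i] / 2.0, 1.0)
        if mu[i] != 0:
            tau = min(tau, bound / abs(mu[i]))
        if sigma2[i] > 0:
            tau = min(tau, bound * bound / sigma2[i])
    return tau


def _run_tau_leaping(cm: CompiledModel, cfg: SSAConfig, rng: np.random.Generator) -> np.ndarray:
    grid = cfg.grid()
    sampler = _GridSampler(grid, cm.n_species)
    counts = np.array(cm.model.initial_counts(), dtype=np.int64)
    t = 0.0
    while True:
        a = cm.all_propensities(counts)
        a0 = float(a.sum())
        if a0 <= 0.0:
            break
        tau = _select_tau(cm, counts, a, cfg.tau_epsilon)
        if tau < cfg.exact_fallback_multiplier / a0:
            # leap not worthwhile: take one exact step instead
            tau_exact = -math.log(rng.random()) / a0
            t_new = t + tau_exact
            if t_new > cfg.max_time:
                t = cfg.max_time
                break
            sampler.advance(t_new, counts)
            j = int(np.searchsorted(np.cumsum(a), rng.random() * a0))
            j = min(j, cm.n_reactions - 1)
            counts = counts + cm.delta[j]
            t = t_new
            continue
        tau = min(tau, cfg.max_time - t)
        if tau <= 0:
            break
        # Poisson bundle; halve tau until no count goes negative
        while True:
            firings = rng.poisson(a * tau)
            new_counts = counts + firings @ cm.delta
            if np.all(new_counts >= 0):
                break
            tau /= 2.0
        t_new = t + tau
        # the leap's firings land at t_new: grid points strictly inside the
        # leap keep the old state, a grid point == t_new takes the new one
        sampler.advance(t_new, counts)
        counts = new_counts
        t = t_new
        if t >= cfg.max_time:
            break
    return sampler.finish(counts)


_KERNELS: dict[str, Callable[[CompiledModel, SSAConfig, np.random.Generator], np.ndarray]] = {
    "direct": _run_direct,
    "next_reaction": _run_next_reaction,
    "tau_leaping": _run_tau_leaping,
}


def simulate(model: CRNModel, cfg: SSAConfig) -> Trajectory | list[Trajectory]:
    """Run ``cfg.n_runs`` independent runs of the selected method.

    Returns the element-wise mean trajectory when ``cfg.average`` is true (or
    when there is a single run); otherwise the list of per-run trajectories.
    Runs use independent deterministic substreams spawned from ``cfg.seed``.
    """
    cm = compile_model(model)
    kernel = _KERNELS[cfg.method]
    grid = cfg.grid()
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_runs)
    mats = [kernel(cm, cfg, np.random.Generator(np.random.PCG64(s))) for s in streams]
    if cfg.average or cfg.n_runs == 1:
        mean = np.mean(mats, axis=0)
        return Trajectory(grid, mean, cm.species_ids, n_runs_averaged=cfg.n_runs)
    return [Trajectory(grid, m, cm.species_ids) for m in mats]


# ---------------------------------------------------------------------------
# CSV output (the completion artifact polled by the coupling layer)


def write_trajectory_csv(traj: Trajectory, path: str | os.PathLike) -> Path:
    """Write ``time,<species...>`` CSV atomically (temp file, then rename)."""
    if not traj.species_ids:
        raise ValueError("trajectory has an empty species list")
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    lines = ["time," + ",".join(traj.species_ids)]
    for t, row in zip(traj.times, traj.counts):
        lines.append(repr(float(t)) + "," + ",".join(repr(float(v)) for v in row))
    tmp.write_text("\n".join(lines) + "\n")
    os.replace(tmp, path)
    return path


def read_trajectory_csv(path: str | os.PathLike) -> Trajectory:
    """Parse a CSV written by :func:`write_trajectory_csv` (exact round-trip)."""
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln]
    if not lines:
        raise ValueError(f"{path}: empty trajectory file")
    header = lines[0].split(",")
    if header[0] != "time" or len(header) < 2:
        raise ValueError(f"{path}: bad header {lines[0]!r}")
    species_ids = header[1:]
    times, rows = [], []
    for ln in lines[1:]:
        parts = ln.split(",")
        if len(parts) != len(header):
            raise ValueError(f"{path}: ragged row {ln!r}")
        times.append(float(parts[0]))
        rows.append([float(v) for v in parts[1:]])
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return Trajectory(np.array(times), np.array(rows), species_ids)
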