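"""Gillespie engine: propensities, stepping, sampling, CSV output."""

import math

import numpy as np
import pytest

from stochcolony import (
    SSAConfig,
    build_serial_pathway,
    propensities,
    read_trajectory_csv,
    simulate,
    step_direct,
    write_trajectory_csv,
)
from stochcolony.crn import CRNModel, Reaction, Species
from stochcolony.ssa import compile_model, initial_state


class FakeRng:
    """Deterministic uniform stream for closed-form step checks."""

    def __init__(self, values):
        self.values = list(values)

    def random(self):
        return self.values.pop(0)


# ---------------------------------------------------------------------------
# propensities


def test_mass_action_propensity_value(decay_model):
    a = propensities([1000, 0, 10], decay_model)
    assert a.tolist() == [0.001 * 1000 * 10]  # == 10.0


def test_zero_reactant_count_zeroes_propensity(multi4):
    counts = [0] * multi4.n_species
    assert propensities(counts, multi4).tolist() == [0.0] * 4


def test_zero_rate_constant():
    m = build_serial_pathway(1, k=0.0)
    assert propensities(m.initial_counts(), m).tolist() == [0.0]


def test_falling_factorial_for_higher_stoichiometry():
    m = CRNModel(
        species=[Species("A", 5), Species("B", 0)],
        reactions=[Reaction("dim", (("A", 2),), (("B", 1),), 2.0)],
    )
    # k * A*(A-1) = 2 * 5*4
    assert propensities([5, 0], m).tolist() == [40.0]


def test_negative_counts_rejected(decay_model):
    with pytest.raises(ValueError, match="negative"):
        propensities([-1, 0, 10], decay_model)


# ---------------------------------------------------------------------------
# direct-method stepping


def test_direct_step_waiting_time_closed_form():
    """u1 = 0.5 with a0 = 2 gives tau = ln(2)/2."""
    m = build_serial_pathway(1, substrate_init=200, enzyme_init=1, k=0.01)  # a0 = 2
    cm = compile_model(m)
    state = initial_state(cm)
    assert state.a0 == pytest.approx(2.0)
    new = step_direct(state, cm, FakeRng([0.5, 0.3]))
    assert new.t == pytest.approx(math.log(2) / 2)


def test_single_reaction_always_selected(decay_model):
    cm = compile_model(decay_model)
    state = initial_state(cm)
    new = step_direct(state, cm, FakeRng([0.9, 0.999]))
    assert new.counts.tolist() == [999, 1, 10]


def test_absorbing_state_signalled():
    m = CRNModel(
        species=[Species("A", 1), Species("B", 0)],
        reactions=[Reaction("R1", (("A", 1),), (("B", 1),), 1.0)],
    )
    cm = compile_model(m)
    state = step_direct(initial_state(cm), cm, FakeRng([0.5, 0.5]))
    assert state.counts.tolist() == [0, 1]
    assert state.a0 == 0.0
    assert step_direct(state, cm, FakeRng([0.5, 0.5])) is None


# ---------------------------------------------------------------------------
# trajectories


@pytest.mark.parametrize("method", ["direct", "next_reaction", "tau_leaping"])
def test_fast_single_firing_reaches_absorbing_final_state(method):
    m = CRNModel(
        species=[Species("A", 1), Species("E", 1), Species("B", 0)],
        reactions=[Reaction("R1", (("A", 1), ("E", 1)), (("B", 1), ("E", 1)), 1e6)],
    )
    traj = simulate(m, SSAConfig(method=method, seed=2))
    assert traj.final_counts().tolist() == [0.0, 1.0, 1.0]


@pytest.mark.parametrize("method", ["direct", "next_reaction", "tau_leaping"])
def test_empty_substrate_trajectory_constant(method):
    m = build_serial_pathway(4, substrate_init=0)
    traj = simulate(m, SSAConfig(method=method, seed=0))
    assert np.all(traj.counts == traj.counts[0])


def test_grid_shape_reference_settings(decay_model, reference_cfg):
    """interval 0.1, max_time 3 -> 31 grid points, last at exactly 3.0."""
    traj = simulate(decay_model, reference_cfg)
    assert len(traj.times) == 31
    assert traj.times[0] == 0.0 and traj.times[-1] == 3.0
    assert np.allclose(np.diff(traj.times), 0.1)


@pytest.mark.parametrize("method", ["direct", "next_reaction"])
def test_conservation_along_exact_trajectory(method, multi4):
    """Enzyme counts constant; substrate total constant (single run)."""
    traj = simulate(multi4, SSAConfig(method=method, n_runs=1, seed=9))
    for e in ("E1", "E2", "E3", "E4"):
        assert np.all(traj.column(e) == 10)
    substrate_total = sum(traj.column(f"S{i}") for i in range(5))
    assert np.all(substrate_total == 1000)


def test_analytic_mean_and_variance_of_death_process(decay_model):
    """S(t) is a linear death process at rate c = kE = 0.01:
    mean N e^{-ct}, variance N e^{-ct}(1 - e^{-ct}); checked within 3 SE."""
    n_runs = 2000
    runs = simulate(decay_model, SSAConfig(method="direct", n_runs=n_runs, average=False, seed=42))
    finals = np.array([r.column("S0")[-1] for r in runs])
    p = math.exp(-0.01 * 3.0)
    mean_th, var_th = 1000 * p, 1000 * p * (1 - p)
    assert abs(finals.mean() - mean_th) < 3 * math.sqrt(var_th / n_runs)
    var_se = var_th * math.sqrt(2.0 / (n_runs - 1))
    assert abs(finals.var(ddof=1) - var_th) < 3 * var_se


def test_tau_leaping_mean_matches_direct(decay_model):
    """Tau-leaping mean of S at t=3 within 1% of direct at matched runs."""
    tau = simulate(decay_model, SSAConfig(method="tau_leaping", n_runs=2000, seed=43))
    direct = simulate(decay_model, SSAConfig(method="direct", n_runs=2000, seed=44))
    d = direct.column("S0")[-1]
    assert abs(tau.column("S0")[-1] - d) / d < 0.01


def test_direct_and_next_reaction_distributions_equivalent(multi4):
    """Two-sample KS on final S1 counts, alpha = 0.01, n = 1000 per arm."""
    from scipy.stats import ks_2samp

    a = simulate(multi4, SSAConfig(method="direct", n_runs=1000, average=False, seed=10))
    b = simulate(multi4, SSAConfig(method="next_reaction", n_runs=1000, average=False, seed=11))
    fa = [r.column("S1")[-1] for r in a]
    fb = [r.column("S1")[-1] for r in b]
    assert ks_2samp(fa, fb).pvalue > 0.01


def test_tau_leaping_counts_never_negative():
    """Aggressive rates must not drive any species below zero."""
    m = build_serial_pathway(4, substrate_init=50, enzyme_init=50, k=0.5)
    runs = simulate(m, SSAConfig(method="tau_leaping", n_runs=20, average=False, seed=3))
    for r in runs:
        assert np.all(r.counts >= 0)


def test_averaging_is_elementwise_mean(decay_model):
    cfg_all = SSAConfig(method="direct", n_runs=8, average=False, seed=5)
    cfg_avg = SSAConfig(method="direct", n_runs=8, average=True, seed=5)
    runs = simulate(decay_model, cfg_all)
    avg = simulate(decay_model, cfg_avg)
    assert np.allclose(avg.counts, np.mean([r.counts for r in runs], axis=0))


def test_unknown_method_rejected():
    with pytest.raises(ValueError, match="unknown method"):
        SSAConfig(method="leapfrog")


# ---------------------------------------------------------------------------
# CSV


def test_csv_shape_and_round_trip(tmp_path, decay_model, reference_cfg):
    traj = simulate(decay_model, reference_cfg)
    path = write_trajectory_csv(traj, tmp_path / "t.csv")
    lines = path.read_text().splitlines()
    assert lines[0] == "time,S0,S1,E1"
    assert len(lines) == 32  # header + 31 grid rows
    assert float(lines[-1].split(",")[0]) == 3.0
    back = read_trajectory_csv(path)
    assert np.array_equal(back.counts, traj.counts)
    assert np.array_equal(back.times, traj.times)


def test_csv_write_is_atomic(tmp_path, decay_model, reference_cfg):
    traj = simulate(decay_model, reference_cfg)
    write_trajectory_csv(traj, tmp_path / "t.csv")
    assert list(tmp_path.iterdir()) == [tmp_path / "t.csv"]  # no temp leftovers


def test_csv_empty_species_rejected(tmp_path, decay_model, reference_cfg):
    traj = simulate(decay_model, reference_cfg)
    traj.species_ids = []
    traj.counts = traj.counts[:, :0]
    with pytest.raises(ValueError):
        write_trajectory_csv(traj, tmp_path / "t.csv")


def test_identical_seed_gives_bit_identical_csv(tmp_path, multi4):
    cfg = SSAConfig(method="tau_leaping", n_runs=3, seed=77)
    for name in ("a.csv", "b.csv"):
        write_trajectory_csv(simulate(multi4, cfg), tmp_path / name)
    assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
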