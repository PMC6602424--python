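"""Stochastic engines: analytic means, cross-method agreement, reproducibility."""

import math

import numpy as np
import pytest

import sbkernel as sk
from sbkernel.simulate_ssa import (
    PropensityError,
    SsaSettings,
    dependency_graph,
    simulate_direct,
    simulate_next_reaction,
    simulate_tau_leap,
)

PURE_DEATH = "model pd\nspecies X = 100\nconst k = 1\nJ1: X -> ; k*X\n"


def _system(text):
    d, m = sk.read_text(text)
    return sk.compile_system(d, m, "stochastic")


def _within_3se(values, target):
    se = values.std(ddof=1) / math.sqrt(len(values))
    return abs(values.mean() - target) < 3 * se + 1e-12


@pytest.mark.parametrize("runner, method, seed", [
    (simulate_direct, "direct", 101),
    (simulate_next_reaction, "next_reaction", 102),
])
def test_pure_death_mean_matches_analytic(runner, method, seed):
    system = _system(PURE_DEATH)
    res = runner(system, SsaSettings(t_end=1.0, n_replicates=2000, seed=seed, method=method))
    assert _within_3se(res.final("X").astype(float), 100 * math.exp(-1))


def test_immigration_death_stationary_mean():
    d, m = sk.canonical("immigration_death")
    system = sk.compile_system(d, m, "stochastic")
    res = simulate_direct(system, SsaSettings(t_end=8.0, n_replicates=2000, seed=7))
    assert _within_3se(res.final("X").astype(float), 10.0)


def test_zero_propensity_model_never_fires():
    system = _system("model z\nspecies X = 5\nconst k = 0\nJ1: X -> ; k*X\n")
    res = simulate_direct(system, SsaSettings(t_end=5.0, n_replicates=3, seed=1))
    assert np.all(res.states == 5)
    assert np.all(res.event_counts == 0)


def test_seed_reproducibility_bit_identical():
    system = _system(PURE_DEATH)
    for runner, method in ((simulate_direct, "direct"),
                           (simulate_next_reaction, "next_reaction")):
        s = SsaSettings(t_end=1.0, n_replicates=5, seed=42, method=method)
        a, b = runner(system, s), runner(system, s)
        assert all(np.array_equal(x, y) for x, y in zip(a.event_times, b.event_times))
        assert np.array_equal(a.states, b.states)


def test_dependency_graph_of_linear_chain():
    system = _system(
        "model c\nspecies A = 5\nspecies B = 0\nspecies C = 0\nconst k = 1\n"
        "J1: A -> B; k*A\nJ2: B -> C; k*B\n"
    )
    assert dependency_graph(system) == {0: [1], 1: []}


def test_direct_and_next_reaction_agree_on_three_reaction_network():
    """First two moments agree within 3 combined standard errors (5000 reps)."""
    text = (
        "model net\nspecies A = 0\nspecies B = 0\nconst lam = 5\nconst k = 1\n"
        "const mu = 0.5\nJ1:  -> A; lam\nJ2: A -> B; k*A\nJ3: B -> ; mu*B\n"
    )
    system = _system(text)
    n = 5000
    ra = simulate_direct(system, SsaSettings(t_end=2.0, n_replicates=n, seed=21))
    rb = simulate_next_reaction(
        system, SsaSettings(t_end=2.0, n_replicates=n, seed=22, method="next_reaction")
    )
    for sid in ("A", "B"):
        xa = ra.final(sid).astype(float)
        xb = rb.final(sid).astype(float)
        for moment in (lambda v: v, lambda v: v**2):
            ma, mb = moment(xa), moment(xb)
            se = math.sqrt(ma.var(ddof=1) / n + mb.var(ddof=1) / n)
            assert abs(ma.mean() - mb.mean()) < 3.3 * se


def test_ensemble_mean_tracks_ode_in_large_copy_number_limit():
    system = _system(PURE_DEATH)
    res = simulate_direct(system, SsaSettings(t_end=1.0, n_points=11,
                                              n_replicates=1000, seed=3))
    d, m = sk.read_text(PURE_DEATH)
    ode = sk.simulate_ode(
        sk.compile_system(d, m, "ode"),
        sk.OdeSettings(t_end=1.0, n_points=11, rel_tol=1e-10, abs_tol=1e-12),
    )
    mean = res.column_mean("X")
    se = res.states[:, :, 0].std(axis=0, ddof=1) / math.sqrt(1000)
    assert np.all(np.abs(mean - ode.column("X")) <= 3 * se + 1e-9)


def test_tau_leap_mean_and_bias_ordering():
    d, m = sk.canonical("dimerization")
    system = sk.compile_system(d, m, "stochastic")
    exact = simulate_direct(system, SsaSettings(t_end=0.5, n_replicates=600, seed=5))
    coarse = simulate_tau_leap(
        system, SsaSettings(t_end=0.5, n_replicates=600, seed=6, method="tau_leap", tau=0.1)
    )
    fine = simulate_tau_leap(
        system, SsaSettings(t_end=0.5, n_replicates=600, seed=7, method="tau_leap", tau=0.001)
    )
    target = exact.final("A").astype(float).mean()
    bias_coarse = abs(coarse.final("A").astype(float).mean() - target)
    bias_fine = abs(fine.final("A").astype(float).mean() - target)
    assert bias_fine < bias_coarse
    # fine tau agrees with the exact method within 3 se
    se = exact.final("A").astype(float).std(ddof=1) / math.sqrt(600)
    assert bias_fine < 3 * se + 1.0


def test_tau_leap_requires_positive_tau():
    system = _system(PURE_DEATH)
    with pytest.raises(ValueError, match="tau"):
        simulate_tau_leap(system, SsaSettings(t_end=1.0, seed=1, method="tau_leap", tau=0.0))


def test_negative_propensity_names_reaction():
    system = _system("model n\nspecies X = 5\nconst k = 1\nJ1: X -> ; -k*X\n")
    with pytest.raises(PropensityError, match="J1"):
        simulate_direct(system, SsaSettings(t_end=1.0, seed=1))


def test_states_remain_nonnegative_integers():
    d, m = sk.canonical("dimerization")
    system = sk.compile_system(d, m, "stochastic")
    res = simulate_direct(system, SsaSettings(t_end=1.0, n_replicates=20, seed=9))
    assert res.states.dtype.kind == "i"
    assert np.all(res.states >= 0)
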