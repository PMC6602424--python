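"""Objective construction and global-optimizer behaviour."""

import numpy as np
import pandas as pd
import pytest

import sbkernel as sk
from sbkernel.fitting import (
    ExperimentData,
    FitProblem,
    PsoSettings,
    SresSettings,
    fit_pso,
    fit_sres,
    objective,
)


def _decay_data(t_end=3.0, n=13, noise=0.0, seed=None, scale=1.0):
    d, m = sk.canonical("decay")
    system = sk.compile_system(d, m, "ode")
    ts = np.linspace(0.0, t_end, n)
    traj = sk.simulate_ode(
        system, sk.OdeSettings(t_end=t_end, times=ts, rel_tol=1e-10, abs_tol=1e-13)
    )
    values = scale * traj.column("A")
    if noise:
        rng = np.random.default_rng(seed)
        values = values * (1 + noise * rng.standard_normal(n))
    return pd.DataFrame({"time": ts, "A": values})


def _decay_problem(df, relative=()):
    _, m = sk.canonical("decay")
    return FitProblem(
        model=m,
        free_parameters=[("k", 0.01, 10.0)],
        experiments=[ExperimentData.from_frame(df, relative=relative)],
    )


def test_objective_is_zero_at_truth_and_positive_off_truth():
    prob = _decay_problem(_decay_data())
    assert objective(prob, [1.0]) < 1e-12
    assert objective(prob, [2.0]) > 1e-3


def test_relative_observations_are_scale_invariant():
    prob = _decay_problem(_decay_data(scale=3.7), relative={"A"})
    assert objective(prob, [1.0]) < 1e-12


def test_missing_observed_symbol_is_rejected_at_build():
    _, m = sk.canonical("decay")
    df = pd.DataFrame({"time": [0.0, 1.0], "ghost": [1.0, 0.5]})
    with pytest.raises(ValueError, match="ghost"):
        FitProblem(
            model=m,
            free_parameters=[("k", 0.01, 10.0)],
            experiments=[ExperimentData.from_frame(df)],
        )


def test_steady_state_experiment_compares_at_steady_state():
    _, m = sk.canonical("two_step_pathway")
    exp = ExperimentData.from_frame(pd.DataFrame({"S": [1.0]}), kind="steady_state")
    prob = FitProblem(
        model=m, free_parameters=[("k1", 0.01, 10.0)], experiments=[exp]
    )
    assert objective(prob, [1.0]) < 1e-10  # S* = k1*S0/(k1+k2) = 1 at k1=k2=1
    assert objective(prob, [3.0]) > 1e-3


def test_sres_recovers_decay_rate_from_noiseless_data():
    prob = _decay_problem(_decay_data())
    res = fit_sres(prob, SresSettings(generations=40, lambda_=30, mu=5, seed=3))
    assert abs(res.best_parameters["k"] - 1.0) < 1e-3


def test_pso_recovers_decay_rate_from_noiseless_data():
    prob = _decay_problem(_decay_data())
    res = fit_pso(prob, PsoSettings(iterations=80, swarm_size=15, seed=3))
    assert abs(res.best_parameters["k"] - 1.0) < 1e-2 * 1.0


def test_sres_recovers_two_parameters_of_two_step_pathway():
    d, m = sk.canonical("two_step_pathway")
    system = sk.compile_system(d, m, "ode")
    ts = np.linspace(0.0, 3.0, 13)
    traj = sk.simulate_ode(
        system, sk.OdeSettings(t_end=3.0, times=ts, rel_tol=1e-10, abs_tol=1e-13)
    )
    df = pd.DataFrame({"time": ts, "S": traj.column("S")})
    prob = FitProblem(
        model=m,
        free_parameters=[("k1", 0.01, 10.0), ("k2", 0.01, 10.0)],
        experiments=[ExperimentData.from_frame(df)],
    )
    res = fit_sres(prob, SresSettings(generations=60, lambda_=40, mu=7, seed=2))
    assert abs(res.best_parameters["k1"] - 1.0) < 0.01
    assert abs(res.best_parameters["k2"] - 1.0) < 0.01


def test_pso_minimizes_sphere_function():
    _, m = sk.canonical("decay")
    prob = FitProblem(
        model=m,
        free_parameters=[(f"k", -5.0, 5.0)],
        experiments=[],
    )
    prob.free_parameters = [("a", -5.0, 5.0), ("b", -5.0, 5.0), ("c", -5.0, 5.0)]
    res = fit_pso(
        prob,
        PsoSettings(iterations=200, swarm_size=20, seed=4),
        objective_fn=lambda x: float(np.sum(np.square(x))),
    )
    assert res.best_objective < 1e-4


def test_best_so_far_traces_are_monotone():
    prob = _decay_problem(_decay_data())
    res_s = fit_sres(prob, SresSettings(generations=10, lambda_=12, mu=3, seed=1))
    res_p = fit_pso(prob, PsoSettings(iterations=10, swarm_size=8, seed=1))
    for trace in (res_s.trace, res_p.trace):
        assert all(a >= b for a, b in zip(trace, trace[1:]))


def test_zero_generations_returns_best_of_initial_population():
    prob = _decay_problem(_decay_data())
    res = fit_sres(prob, SresSettings(generations=0, lambda_=12, mu=3, seed=1))
    assert res.evaluation_count == 12
    res_p = fit_pso(prob, PsoSettings(iterations=0, swarm_size=9, seed=1))
    assert res_p.evaluation_count == 9


def test_seeded_determinism_of_both_optimizers():
    prob = _decay_problem(_decay_data())
    s = SresSettings(generations=5, lambda_=10, mu=3, seed=17)
    a, b = fit_sres(prob, s), fit_sres(prob, s)
    assert a.best_parameters == b.best_parameters and a.trace == b.trace
    ps = PsoSettings(iterations=5, swarm_size=8, seed=17)
    c, d = fit_pso(prob, ps), fit_pso(prob, ps)
    assert c.best_parameters == d.best_parameters and c.trace == d.trace


def test_population_smaller_than_parents_is_rejected():
    prob = _decay_problem(_decay_data())
    with pytest.raises(ValueError):
        fit_sres(prob, SresSettings(generations=1, lambda_=3, mu=5, seed=1))
    with pytest.raises(ValueError):
        fit_pso(prob, PsoSettings(iterations=1, swarm_size=0, seed=1))


def test_invalid_bounds_are_rejected():
    _, m = sk.canonical("decay")
    with pytest.raises(ValueError, match="bounds"):
        FitProblem(model=m, free_parameters=[("k", 2.0, 1.0)], experiments=[])
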