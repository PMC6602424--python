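"""Composition and agent-based co-simulation against the flattened oracle."""

import numpy as np
import pytest

import sbkernel as sk
from sbkernel.modular import (
    CompositionError,
    Connection,
    ModularModel,
    ScheduleSettings,
    compose,
    simulate_agents,
)
from sbkernel.preprocess import flatten


def _chain():
    return sk.canonical("decay_chain_modular")


def _flat_oracle(t_end, n_points=101):
    mm = _chain()
    _, flat = flatten(mm)
    system = sk.compile_system(None, flat, "ode")
    return sk.simulate_ode(
        system, sk.OdeSettings(t_end=t_end, n_points=n_points, rel_tol=1e-12, abs_tol=1e-14)
    )


def test_compose_two_valid_modules():
    mm = _chain()
    rebuilt = compose(mm.modules, mm.connections)
    assert len(rebuilt.modules) == 2
    assert len(rebuilt.connections) == 1
    assert rebuilt.diagnostics == []


def test_compose_rejects_missing_symbol():
    mm = _chain()
    bad = Connection("directed", [("M1", "nope"), ("M2", "B")])
    with pytest.raises(CompositionError, match="nope"):
        compose(mm.modules, [bad])


def test_compose_rejects_missing_module():
    mm = _chain()
    bad = Connection("directed", [("MX", "A"), ("M2", "B")])
    with pytest.raises(CompositionError, match="MX"):
        compose(mm.modules, [bad])


def test_zero_connections_is_valid_independent_cosimulation():
    mm = _chain()
    free = compose(mm.modules, [])
    traj = simulate_agents(free, ScheduleSettings(t_end=1.0, exchange_step=0.1))
    assert traj.states.shape[0] == 101


def test_agent_simulation_tracks_flattened_oracle():
    mm = _chain()
    oracle = _flat_oracle(5.0)
    traj = simulate_agents(mm, ScheduleSettings(t_end=5.0, exchange_step=0.01))
    pairs = (("M1__A", "M1__A"), ("M1__B", "M1__B"), ("M2__C", "M2__C"))
    dev = max(np.max(np.abs(traj.column(a) - oracle.column(b))) for a, b in pairs)
    assert dev < 0.01


def test_agent_deviation_decreases_with_exchange_step():
    mm = _chain()
    oracle = _flat_oracle(5.0)
    devs = []
    for h in (0.08, 0.04, 0.02):
        traj = simulate_agents(mm, ScheduleSettings(t_end=5.0, exchange_step=h))
        dev = max(
            np.max(np.abs(traj.column(c) - oracle.column(c)))
            for c in ("M1__A", "M1__B", "M2__C")
        )
        devs.append(dev)
    assert devs[0] > devs[1] > devs[2]


def test_single_module_agent_equals_direct_simulation():
    d, m = sk.canonical("decay")
    mm = compose({"Solo": (d, m)}, [])
    traj = simulate_agents(mm, ScheduleSettings(t_end=1.0, exchange_step=0.05))
    system = sk.compile_system(d, m, "ode")
    direct = sk.simulate_ode(
        system, sk.OdeSettings(t_end=1.0, rel_tol=1e-10, abs_tol=1e-13)
    )
    assert np.max(np.abs(traj.column("Solo__A") - direct.column("A"))) < 1e-6


def test_mass_is_conserved_across_connection_to_first_order():
    # A + (shared B) + C is conserved exactly in the flat chain;
    # the scheduler may deviate only O(h_ex).
    mm = _chain()
    h = 0.01
    traj = simulate_agents(mm, ScheduleSettings(t_end=5.0, exchange_step=h))
    total = traj.column("M1__A") + traj.column("M1__B") + traj.column("M2__C")
    assert np.max(np.abs(total - total[0])) < 10 * h


def test_scheduler_determinism():
    mm = _chain()
    s = ScheduleSettings(t_end=2.0, exchange_step=0.05)
    a = simulate_agents(mm, s)
    b = simulate_agents(mm, s)
    assert np.array_equal(a.states, b.states)
    assert a.variable_ids == b.variable_ids


def test_schedule_settings_validation():
    with pytest.raises(ValueError):
        ScheduleSettings(t_end=1.0, exchange_step=0.0)
    with pytest.raises(ValueError):
        ScheduleSettings(t_end=1.0, exchange_step=2.0)
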