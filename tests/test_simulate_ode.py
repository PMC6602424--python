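"""Deterministic engines: closed forms, convergence order, events, stiffness."""

import math

import numpy as np
import pytest

import sbkernel as sk
from sbkernel.simulate_ode import OdeSettings, simulate_ode, steady_state

from conftest import simulate_flat


def test_decay_reaches_exp_minus_one(decay):
    traj = simulate_flat(decay, 1.0, rel_tol=1e-8, abs_tol=1e-12)
    assert traj.final("A") == pytest.approx(math.exp(-1), abs=1e-6)


def test_logistic_reaches_sigmoid_value():
    traj = simulate_flat(sk.canonical("logistic"), 1.0, rel_tol=1e-8, abs_tol=1e-12)
    assert traj.final("x") == pytest.approx(1 / (1 + math.exp(-1)), abs=1e-6)


def test_euler_is_first_order_on_decay(decay):
    diagram, model = decay
    system = sk.compile_system(diagram, model, "ode")
    errors = []
    for h in (0.01, 0.005):
        traj = simulate_ode(system, OdeSettings(t_end=1.0, solver="euler", initial_step=h))
        errors.append(abs(traj.final("A") - math.exp(-1)))
    ratio = errors[0] / errors[1]
    assert 1.8 <= ratio <= 2.2


def test_event_fires_at_ln_two():
    diagram, model = sk.canonical("event_demo")
    system = sk.compile_system(diagram, model, "ode")
    traj = simulate_ode(system, OdeSettings(t_end=2.0, rel_tol=1e-10, abs_tol=1e-13))
    assert len(traj.event_log) == 1
    t_event, _ = traj.event_log[0]
    assert t_event == pytest.approx(math.log(2), abs=1e-6)


def test_event_assignment_is_applied():
    d, m = sk.read_text(
        "model ev\nspecies A = 1\nspecies y = 0\nconst k = 1\nJ1: A -> ; k*A\n"
        "at (A < 0.5): y = 1\n"
    )
    system = sk.compile_system(d, m, "ode")
    traj = simulate_ode(system, OdeSettings(t_end=2.0))
    assert traj.final("y") == 1.0
    before = traj.states[traj.times < 0.69, traj.variable_ids.index("y")]
    assert np.all(before == 0.0)


def test_delayed_event_fires_after_delay():
    d, m = sk.read_text(
        "model ev\nspecies A = 1\nspecies y = 0\nconst k = 1\nJ1: A -> ; k*A\n"
        "at (A < 0.5) delay 0.5: y = 1\n"
    )
    system = sk.compile_system(d, m, "ode")
    traj = simulate_ode(system, OdeSettings(t_end=3.0, rel_tol=1e-10, abs_tol=1e-13))
    t_fire = traj.event_log[0][0]
    assert t_fire == pytest.approx(math.log(2) + 0.5, abs=1e-6)


def test_simultaneous_events_fire_in_declaration_order():
    d, m = sk.read_text(
        "model ev\nspecies x = 0\nspecies y = 0\nrate x = 1\n"
        "at (x > 1): y = 1\nat (x > 1): y = 2\n"
    )
    system = sk.compile_system(d, m, "ode")
    traj = simulate_ode(system, OdeSettings(t_end=3.0))
    assert [eid for _, eid in traj.event_log] == ["e1", "e2"]
    assert traj.final("y") == 2.0  # the later declaration wins


def test_constraint_halts_at_forced_time():
    diagram, model = sk.canonical("constraint_demo")
    model = sk.constraints_to_events(model)
    system = sk.compile_system(diagram, model, "ode")
    traj = simulate_ode(system, OdeSettings(t_end=10.0, rel_tol=1e-10, abs_tol=1e-13))
    assert traj.halt is not None
    t_halt, message = traj.halt
    assert t_halt == pytest.approx(5.0, abs=1e-6)
    assert "x exceeded 5" in message
    assert traj.times[-1] == pytest.approx(5.0, abs=1e-6)


def test_robertson_conserves_mass_with_stiff_solver():
    traj = simulate_flat(
        sk.canonical("robertson"), 100.0, solver="stiff_multistep",
        rel_tol=1e-8, abs_tol=1e-12, n_points=51,
    )
    total = traj.states.sum(axis=1)
    assert np.max(np.abs(total - 1.0)) < 1e-6


def test_tightening_rtol_does_not_worsen_decay_error(decay):
    diagram, model = decay
    system = sk.compile_system(diagram, model, "ode")
    errs = {}
    for rtol in (1e-4, 1e-8):
        traj = simulate_ode(system, OdeSettings(t_end=1.0, rel_tol=rtol, abs_tol=1e-14))
        errs[rtol] = abs(traj.final("A") - math.exp(-1))
    assert errs[1e-8] <= errs[1e-4]


def test_output_grid_is_exactly_as_requested(decay):
    traj = simulate_flat(decay, 2.0, n_points=41)
    assert len(traj.times) == 41
    assert traj.times[0] == 0.0 and traj.times[-1] == 2.0
    assert np.all(np.diff(traj.times) > 0)


def test_steady_state_of_two_step_pathway(two_step):
    diagram, model = two_step
    system = sk.compile_system(diagram, model, "ode")
    assert steady_state(system)[0] == pytest.approx(1.0, abs=1e-8)


def test_steady_state_closed_form_with_asymmetric_rates():
    _, model = sk.canonical("two_step_pathway")
    model.parameter("k1").value = 2.0
    model.parameter("S0").value = 3.0
    system = sk.compile_system(None, model, "ode")
    # S* = k1*S0/(k1+k2), cross-checked by integrating to large time
    assert steady_state(system)[0] == pytest.approx(2.0, abs=1e-8)
    long = simulate_ode(system, OdeSettings(t_end=40.0, rel_tol=1e-12, abs_tol=1e-14))
    assert long.final("S") == pytest.approx(2.0, abs=1e-8)


def test_steady_state_of_decay_is_zero(decay):
    diagram, model = decay
    system = sk.compile_system(diagram, model, "ode")
    assert abs(steady_state(system, tol=1e-10)[0]) < 1e-9


def test_settings_validation():
    with pytest.raises(ValueError):
        OdeSettings(t_end=0.0)
    with pytest.raises(ValueError):
        OdeSettings(t_end=1.0, rel_tol=-1)
    with pytest.raises(ValueError):
        OdeSettings(t_end=1.0, solver="rk4")
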