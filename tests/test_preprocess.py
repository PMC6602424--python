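"""Preprocessor transforms and compilation contracts."""

import numpy as np
import pytest
import sympy as sp

import sbkernel as sk
from sbkernel.modular import Connection
from sbkernel.preprocess import (
    EngineCompatibilityError,
    FlattenError,
    UnsupportedTransformationError,
    compile_system,
    constraints_to_events,
    fast_to_algebraic,
    flatten,
)


def _two_modules():
    return sk.read_text(
        "module M1\n  species A = 1\n  species B = 0\n  const k1 = 1\n"
        "  J1: A -> B; k1*A\nend\n"
        "module M2\n  species B = 0\n  species C = 0\n  const k2 = 1\n"
        "  J2: B -> C; k2*B\nend\n"
        "connect M1.B = M2.B master M1.B\n"
    )


def test_flatten_merges_connected_species():
    _, flat = flatten(_two_modules())
    assert len([v for v in flat.variables]) == 3  # A, shared B, C
    assert len(flat.reactions) == 2
    ids = {v.id for v in flat.variables}
    assert ids == {"M1__A", "M1__B", "M2__C"}


def test_flatten_single_module_is_identity_up_to_namespacing():
    mm = sk.read_text(
        "module Solo\n  species A = 1\n  const k = 2\n  J1: A -> ; k*A\nend\n"
    )
    _, flat = flatten(mm)
    assert [v.id for v in flat.variables] == ["Solo__A"]
    assert flat.reactions[0].kinetic_law == sp.Symbol("Solo__k") * sp.Symbol("Solo__A")


def test_undirected_connection_of_two_ode_variables_without_master_errors():
    mm = _two_modules()
    mm.connections = [Connection("undirected", [("M1", "B"), ("M2", "B")], master=None)]
    with pytest.raises(FlattenError, match="master"):
        flatten(mm)


def test_flatten_preserves_dynamics_against_monolithic_model():
    _, flat = flatten(_two_modules())
    sys_flat = compile_system(None, flat, "ode")
    _, mono = sk.read_text(
        "model chain\nspecies A = 1\nspecies B = 0\nspecies C = 0\n"
        "const k1 = 1\nconst k2 = 1\nJ1: A -> B; k1*A\nJ2: B -> C; k2*B\n"
    )
    sys_mono = compile_system(None, mono, "ode")
    settings = sk.OdeSettings(t_end=5.0, rel_tol=1e-12, abs_tol=1e-14)
    tf = sk.simulate_ode(sys_flat, settings)
    tm = sk.simulate_ode(sys_mono, settings)
    for a, b in (("M1__A", "A"), ("M1__B", "B"), ("M2__C", "C")):
        assert np.max(np.abs(tf.column(a) - tm.column(b))) < 1e-9


def test_constraint_becomes_negated_halt_event():
    _, m = sk.read_text('model c\nspecies x = 0\nrate x = 1\nconstraint (x < 5): "boom"\n')
    out = constraints_to_events(m)
    assert out.constraints == []
    assert len(out.events) == 1
    ev = out.events[0]
    assert ev.halt and ev.message == "boom"
    assert ev.trigger == sp.Not(sp.Symbol("x") < 5)
    # model without constraints passes through unchanged
    assert constraints_to_events(out) is out


def test_two_constraints_give_two_halt_events_in_order():
    _, m = sk.read_text(
        'model c\nspecies x = 0\nrate x = 1\n'
        'constraint (x < 5): "first"\nconstraint (x < 7): "second"\n'
    )
    out = constraints_to_events(m)
    assert [e.message for e in out.events] == ["first", "second"]


def test_fast_reaction_becomes_equilibrium_plus_pool():
    _, m = sk.canonical("fast_equilibrium_demo")
    out = fast_to_algebraic(m)
    kinds = [r.kind for r in out.rules]
    assert kinds.count("algebraic") == 2  # equilibrium + pool constraint
    assert kinds.count("rate") == 1
    assert all(not r.fast for r in out.reactions)
    alg = [r for r in out.rules if r.kind == "algebraic"][0]
    a, b, kf, kr = sp.symbols("A B kf kr")
    assert sp.simplify(alg.expression - (kf * a - kr * b)) == 0


def test_fast_to_algebraic_without_fast_reactions_is_identity():
    _, m = sk.canonical("decay")
    assert fast_to_algebraic(m) is m


def test_irreversible_fast_reaction_is_unsupported():
    _, m = sk.read_text(
        "model f\nspecies A = 1\nspecies B = 0\nconst k = 1\nfast J1: A -> B; k*A\n"
    )
    with pytest.raises(UnsupportedTransformationError):
        fast_to_algebraic(m)


def test_compiled_rhs_equals_stoichiometry_times_velocities():
    _, m = sk.read_text("model t\nspecies A = 3\nspecies B = 0\nconst k = 2\nJ1: A -> B; k*A\n")
    system = compile_system(None, m, "ode")
    dy = system.rhs(0.0, system.initial_state, system.parameter_values)
    assert np.allclose(dy, [-6.0, 6.0])


def test_stoichiometry_column_for_2a_plus_b():
    _, m = sk.read_text(
        "model t\nspecies A = 1\nspecies B = 1\nspecies C = 0\nconst k = 1\n"
        "J1: 2 A + B -> C; k*A*A*B\n"
    )
    system = compile_system(None, m, "ode")
    assert list(system.stoichiometry[:, 0]) == [-2.0, -1.0, 1.0]


def test_rhs_is_n_dot_v_on_random_states(rng):
    _, m = sk.canonical("enzyme_mm")
    system = compile_system(None, m, "ode")
    for _ in range(20):
        y = rng.uniform(0, 5, size=len(system.state_ids))
        v = system.velocities(0.0, y, (), system.parameter_values)
        assert np.allclose(system.rhs(0.0, y, system.parameter_values),
                           system.stoichiometry @ v, atol=1e-12)


def test_stochastic_compile_rejects_rate_rules():
    _, m = sk.canonical("logistic")
    with pytest.raises(EngineCompatibilityError):
        compile_system(None, m, "stochastic")


def test_stochastic_compile_rejects_fractional_stoichiometry():
    _, m = sk.read_text(
        "model t\nspecies A = 2\nspecies B = 0\nconst k = 1\nJ1: 1/2 A -> B; k*A\n"
    )
    with pytest.raises(EngineCompatibilityError, match="stoichiometry"):
        compile_system(None, m, "stochastic")


def test_compile_is_deterministic(rng):
    _, m = sk.canonical("enzyme_mm")
    s1 = compile_system(None, m, "ode")
    s2 = compile_system(None, m, "ode")
    assert s1.state_ids == s2.state_ids
    assert s1.parameter_ids == s2.parameter_ids
    for _ in range(10):
        y = rng.uniform(0, 3, size=len(s1.state_ids))
        assert np.array_equal(
            s1.rhs(0.5, y, s1.parameter_values), s2.rhs(0.5, y, s2.parameter_values)
        )
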