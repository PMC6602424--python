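import numpy as np
import pytest
import sympy as sp

import sbkernel as sk


def expr_equal(a, b) -> bool:
    if a is None or b is None:
        return a is b
    if a == b:
        return True
    try:
        return sp.simplify(a - b) == 0
    except Exception:
        return False


def models_equal(a, b) -> bool:
    """Element-wise model identity: ids, values, stoichiometries, expressions."""
    if [v.id for v in a.variables] != [v.id for v in b.variables]:
        return False
    for va, vb in zip(a.variables, b.variables):
        if (va.dynamics, va.compartment) != (vb.dynamics, vb.compartment):
            return False
        if abs(va.initial_value - vb.initial_value) > 1e-12:
            return False
    if [(p.id, p.value, p.constant) for p in a.parameters] != [
        (p.id, p.value, p.constant) for p in b.parameters
    ]:
        return False
    if a.compartment_sizes != b.compartment_sizes:
        return False
    if len(a.reactions) != len(b.reactions):
        return False
    for ra, rb in zip(a.reactions, b.reactions):
        if (ra.id, ra.reactants, ra.products, ra.modifiers, ra.fast, ra.reversible) != (
            rb.id, rb.reactants, rb.products, rb.modifiers, rb.fast, rb.reversible
        ):
            return False
        if not expr_equal(ra.kinetic_law, rb.kinetic_law):
            return False
    if len(a.rules) != len(b.rules):
        return False
    for ra, rb in zip(a.rules, b.rules):
        if (ra.kind, ra.target) != (rb.kind, rb.target) or not expr_equal(
            ra.expression, rb.expression
        ):
            return False
    if len(a.events) != len(b.events):
        return False
    for ea, eb in zip(a.events, b.events):
        if (ea.id, ea.use_trigger_time_values, ea.halt) != (
            eb.id, eb.use_trigger_time_values, eb.halt
        ):
            return False
        if not expr_equal(ea.trigger, eb.trigger):
            return False
        if [t for t, _ in ea.assignments] != [t for t, _ in eb.assignments]:
            return False
        for (_, xa), (_, xb) in zip(ea.assignments, eb.assignments):
            if not expr_equal(xa, xb):
                return False
    if len(a.constraints) != len(b.constraints):
        return False
    for ca, cb in zip(a.constraints, b.constraints):
        if ca.message != cb.message or not expr_equal(ca.condition, cb.condition):
            return False
    return True


@pytest.fixture
def decay():
    return sk.canonical("decay")


@pytest.fixture
def two_step():
    return sk.canonical("two_step_pathway")


def simulate_flat(model_pair, t_end, **kw):
    diagram, model = model_pair
    system = sk.compile_system(diagram, model, "ode")
    settings = sk.OdeSettings(t_end=t_end, **kw)
    return sk.simulate_ode(system, settings)


def flat_catalogue_names():
    return [n for n in sk.fixtures.canonical_names() if n != "decay_chain_modular"]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
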