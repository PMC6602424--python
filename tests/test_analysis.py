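"""Structural decompositions, steady-state sensitivity, and control analysis."""

import numpy as np
import pytest
import sympy as sp

import sbkernel as sk
from sbkernel.analysis import (
    StructureError,
    ZeroFluxError,
    conservation_analysis,
    mca,
    steady_state_sensitivity,
    stoichiometric_analysis,
)

from conftest import flat_catalogue_names


def test_stoichiometric_relations_of_simple_conversion():
    _, m = sk.read_text("model t\nspecies A = 1\nspecies B = 0\nconst k = 1\nJ1: A -> B; k*A\n")
    _, relations = stoichiometric_analysis(m)
    v = sp.Symbol("v_J1")
    assert relations["A"] == -v
    assert relations["B"] == v


def test_stoichiometric_relations_with_stoichiometry_two():
    _, m = sk.read_text(
        "model t\nspecies A = 1\nspecies B = 1\nspecies C = 0\nconst k = 1\n"
        "J1: 2 A + B -> C; k*A*A*B\n"
    )
    _, relations = stoichiometric_analysis(m)
    assert relations["A"] == -2 * sp.Symbol("v_J1")


def test_empty_network_has_empty_relations():
    _, m = sk.canonical("logistic")
    n, relations = stoichiometric_analysis(m)
    assert relations == {}
    assert n.matrix.shape[0] == 0


def test_species_with_reactions_and_rate_rule_is_structure_error():
    _, m = sk.read_text(
        "model bad\nspecies A = 1\nconst k = 1\nJ1: A -> ; k*A\nrate A = 1\n"
    )
    with pytest.raises(StructureError, match="A"):
        stoichiometric_analysis(m)


def test_reversible_pair_has_single_conservation_vector():
    _, m = sk.read_text(
        "model ab\nspecies A = 1\nspecies B = 0\nconst kf = 1\nconst kr = 1\n"
        "J1: A <-> B; kf*A - kr*B\n"
    )
    dec = conservation_analysis(m)
    assert dec.conservation_vectors == [(1, 1)]
    assert len(dec.independent) == 1


def test_enzyme_mechanism_moiety_conservation():
    _, m = sk.canonical("enzyme_mm")
    dec = conservation_analysis(m)
    assert dec.reduced.rows == 2  # rank(N) = 2
    assert len(dec.conservation_vectors) == 2
    # the basis spans {E+ES, S+ES+P}: check both textbook moieties are in the span
    basis = sp.Matrix([list(v) for v in dec.conservation_vectors])
    for moiety in ([1, 0, 1, 0], [0, 1, 1, 1]):  # order: E, S, ES, P
        target = sp.Matrix([moiety])
        assert basis.T.rank() == sp.Matrix.hstack(basis.T, target.T).rank()


def test_open_chain_has_no_conservation():
    _, m = sk.canonical("immigration_death")
    assert conservation_analysis(m).conservation_vectors == []


def test_link_matrix_reconstructs_n_exactly():
    for name in ("enzyme_mm", "robertson", "dimerization"):
        _, m = sk.canonical(name)
        dec = conservation_analysis(m)
        assert (dec.link * dec.reduced - dec.matrix).is_zero_matrix
        for vec in dec.conservation_vectors:
            assert (sp.Matrix([list(vec)]) * dec.matrix).is_zero_matrix


def test_conservation_vectors_hold_along_trajectories():
    for name in ("enzyme_mm", "robertson", "dimerization"):
        diagram, m = sk.canonical(name)
        dec = conservation_analysis(m)
        system = sk.compile_system(diagram, m, "ode")
        traj = sk.simulate_ode(
            system,
            sk.OdeSettings(t_end=5.0, solver="stiff_multistep",
                           rel_tol=1e-10, abs_tol=1e-12),
        )
        cols = np.array([[traj.column(s)] for s in dec.species_ids]).squeeze(1)
        for vec in dec.conservation_vectors:
            m_vec = np.array([float(x) for x in vec])
            tot = m_vec @ cols
            assert np.max(np.abs(tot - tot[0])) < 1e-6


def test_steady_state_sensitivity_closed_forms(two_step):
    _, model = two_step
    sens, species, params = steady_state_sensitivity(model, parameters=["k1", "k2"])
    assert species == ["S"]
    # S* = k1*S0/(k1+k2): dS*/dk1 = k2*S0/(k1+k2)^2 = 0.5, dS*/dk2 = -0.5
    assert sens[0, 0] == pytest.approx(0.5, abs=1e-5)
    assert sens[0, 1] == pytest.approx(-0.5, abs=1e-5)


def test_absent_parameter_gives_zero_column(two_step):
    _, model = two_step
    sens, _, params = steady_state_sensitivity(model, parameters=["k1", "phantom"])
    assert params == ["k1", "phantom"]
    assert np.all(sens[:, 1] == 0.0)


def test_mca_symmetric_two_step_splits_control_evenly(two_step):
    _, model = two_step
    report = mca(model)
    assert np.allclose(report.flux_control, 0.5, atol=1e-6)


def test_mca_flux_control_closed_form_asymmetric():
    _, model = sk.canonical("two_step_pathway")
    model.parameter("k1").value = 2.0
    report = mca(model)
    # C^J = (k2, k1)/(k1+k2) = (1/3, 2/3)
    assert report.flux_control[0, 0] == pytest.approx(1 / 3, abs=1e-4)
    assert report.flux_control[0, 1] == pytest.approx(2 / 3, abs=1e-4)


def test_mca_agrees_with_direct_flux_perturbation():
    """Control coefficients vs d ln J / d ln k from re-solved steady states."""
    _, model = sk.canonical("two_step_pathway")
    model.parameter("k1").value = 2.0
    report = mca(model)
    system = sk.compile_system(None, model, "ode")

    def flux_at(k1):
        p = system.parameter_values.copy()
        p[system.parameter_ids.index("k1")] = k1
        xs = sk.steady_state(system, parameters=p, tol=1e-12)
        return float(system.velocities(0.0, xs, (), p)[0])

    h = 1e-4 * 2.0
    dlnj_dlnk = (np.log(flux_at(2.0 + h)) - np.log(flux_at(2.0 - h))) / (2 * h) * 2.0
    assert report.flux_control[0, 0] == pytest.approx(dlnj_dlnk, abs=1e-4)


def test_summation_theorems_on_catalogue_and_random_networks():
    cases = []
    for name in ("two_step_pathway",):
        _, m = sk.canonical(name)
        cases.append(m)
    for seed in (3, 11):
        _, m = sk.random_mass_action(3, 4, seed=seed)
        cases.append(m)
    checked = 0
    for m in cases:
        try:
            report = mca(m)
        except Exception:
            continue  # random nets may lack a positive-flux steady state
        assert np.max(np.abs(report.flux_control.sum(axis=1) - 1.0)) < 1e-6
        assert np.max(np.abs(report.concentration_control.sum(axis=1))) < 1e-6
        checked += 1
    assert checked >= 1


def test_mca_zero_flux_is_rejected():
    _, m = sk.read_text(
        "model z\nspecies A = 0\nspecies B = 0\nconst k = 1\nJ1: A -> B; k*A\n"
    )
    with pytest.raises(ZeroFluxError, match="J1"):
        mca(m, x_star={"A": 0.0, "B": 0.0})
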