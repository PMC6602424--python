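"""Structural and steady-state analyses of reaction networks.

Structure is handled in exact rational arithmetic (sympy matrices):
:func:`stoichiometric_analysis` derives the linear relations between species
derivatives and reaction fluxes, and :func:`conservation_analysis`
decomposes the stoichiometric matrix ``N`` into independent rows ``N_R``
and a link matrix ``L`` with ``N = L·N_R``, together with an integer-scaled
basis of conservation vectors (left null space).

On top of a steady state, :func:`steady_state_sensitivity` applies the
implicit-function relation on the reduced system
(``∂x*/∂p = −L·J_R⁻¹·N_R·∂v/∂p``), and :func:`mca` computes scaled
elasticities and flux/concentration control coefficients, asserting the
summation theorems before returning.  Rate derivatives are central finite
differences with step ``max(1e-6, 1e-6·|value|)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

import numpy as np
import sympy as sp

from .metamodel import MathModel
from .preprocess import compile_system
from .simulate_ode import steady_state

__all__ = [
    "StructureError",
    "SingularityError",
    "ZeroFluxError",
    "ConservationDecomposition",
    "McaReport",
    "stoichiometric_analysis",
    "conservation_analysis",
    "steady_state_sensitivity",
    "mca",
]


class StructureError(ValueError):
    pass


class SingularityError(RuntimeError):
    pass


class ZeroFluxError(RuntimeError):
    pass


def _check_pure_network(model: MathModel):
    reacting = set()
    for r in model.reactions:
        for s, _ in r.reactants + r.products:
            reacting.add(s)
    for rule in model.rules:
        if rule.kind == "rate" and rule.target in reacting:
            raise StructureError(
                f"species {rule.target!r} is governed by both reactions and a rate rule"
            )


def _exact_n(model: MathModel):
    """Stoichiometric matrix over reacting species, exact rationals."""
    _check_pure_network(model)
    fixed = {v.id for v in model.variables if v.dynamics != "ode"}
    species = []
    for r in model.reactions:
        for s, _ in r.reactants + r.products:
            if s not in species and s not in fixed:
                species.append(s)
    n = sp.zeros(len(species), len(model.reactions))
    for j, r in enumerate(model.reactions):
        for s, st in r.reactants:
            n[species.index(s), j] -= sp.Rational(Fraction(st))
        for s, st in r.products:
            n[species.index(s), j] += sp.Rational(Fraction(st))
    return species, [r.id for r in model.reactions], n


def stoichiometric_analysis(model: MathModel):
    """Return ``(N, relations)``: dx/dt as linear combinations of fluxes.

    ``relations`` maps each reacting species to a symbolic linear
    combination of flux symbols ``v_<reaction id>``.
    """
    species, reactions, n = _exact_n(model)
    relations = {}
    for i, s in enumerate(species):
        expr = sp.Integer(0)
        for j, rid in enumerate(reactions):
            if n[i, j] != 0:
                expr += n[i, j] * sp.Symbol(f"v_{rid}")
        relations[s] = expr
    return StoichiometricMatrix(species, reactions, n), relations


@dataclass
class StoichiometricMatrix:
    species_ids: list
    reaction_ids: list
    matrix: sp.Matrix  # exact rational, species x reactions

    def to_numpy(self) -> np.ndarray:
        return np.array(self.matrix.tolist(), dtype=float)


@dataclass
class ConservationDecomposition:
    species_ids: list
    reaction_ids: list
    matrix: sp.Matrix  # N
    reduced: sp.Matrix  # N_R: independent rows of N
    link: sp.Matrix  # L with N = L * N_R (exact)
    conservation_vectors: list  # integer-scaled left null-space basis (tuples)
    independent: list  # species ids of the independent rows
    dependent: list

    def conservation_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [[int(x) if x == int(x) else float(x) for x in m] for m in self.conservation_vectors],
            columns=self.species_ids,
        )


def conservation_analysis(model: MathModel) -> ConservationDecomposition:
    """Exact link-matrix decomposition and conservation-vector basis."""
    species, reactions, n = _exact_n(model)
    if not species:
        return ConservationDecomposition(
            species, reactions, n, n, sp.eye(0), [], [], []
        )
    # pivot rows of N = pivot columns of N^T
    _, pivots = n.T.rref()
    ind = list(pivots)
    dep = [i for i in range(len(species)) if i not in ind]
    n_red = n[ind, :]
    if ind:
        sol, params = n_red.T.gauss_jordan_solve(n.T)
        if params.shape[1] != 0:
            # rank-deficient N_R cannot happen by construction, but be safe
            sol = sol.xreplace({s: 0 for s in params})
        link = sol.T
    else:
        link = sp.zeros(len(species), 0)
    vectors = []
    for m in n.T.nullspace():
        scale = sp.lcm([sp.fraction(sp.nsimplify(x))[1] for x in m])
        vec = [sp.nsimplify(x * scale) for x in m]
        nz = [x for x in vec if x != 0]
        if nz and all(x < 0 for x in nz):
            vec = [-x for x in vec]
        g = sp.gcd([x for x in vec if x != 0]) if nz else 1
        vectors.append(tuple(x / g for x in vec))
    assert (link * n_red - n).is_zero_matrix
    return ConservationDecomposition(
        species_ids=species,
        reaction_ids=reactions,
        matrix=n,
        reduced=n_red,
        link=link,
        conservation_vectors=vectors,
        independent=[species[i] for i in ind],
        dependent=[species[i] for i in dep],
    )


def _system_for(model: MathModel):
    return compile_system(None, model, "ode")


def _fd_step(value: float) -> float:
    return max(1e-6, 1e-6 * abs(value))


def _rate_derivatives(system, species, x_map, p, wrt_symbols, env_kind):
    """Central finite-difference d v / d (symbol) for each symbol in wrt."""
    state = np.array([x_map[s] for s in system.state_ids], dtype=float)
    pvec = np.array(p, dtype=float)
    n_rx = len(system.reaction_ids)
    out = np.zeros((n_rx, len(wrt_symbols)))
    for col, sym in enumerate(wrt_symbols):
        if env_kind == "state":
            idx = system.state_ids.index(sym)
            h = _fd_step(state[idx])
            up, dn = state.copy(), state.copy()
            up[idx] += h
            dn[idx] -= h
            vu = system.velocities(0.0, up, (), pvec)
            vd = system.velocities(0.0, dn, (), pvec)
        else:
            idx = system.parameter_ids.index(sym)
            h = _fd_step(pvec[idx])
            up, dn = pvec.copy(), pvec.copy()
            up[idx] += h
            dn[idx] -= h
            vu = system.velocities(0.0, state, (), up)
            vd = system.velocities(0.0, state, (), dn)
        out[:, col] = (np.asarray(vu) - np.asarray(vd)) / (2 * h)
    return out


def steady_state_sensitivity(
    model: MathModel,
    x_star: Optional[dict] = None,
    parameters: Optional[list] = None,
    tol: float = 1e-6,
):
    """Matrix ``∂x*/∂p`` of steady-state sensitivities.

    ``x_star`` maps species ids to steady-state values (computed by damped
    Newton when omitted); ``parameters`` selects columns (all model
    parameters by default).  Parameters absent from the model give zero
    columns.  Returns ``(sens, species_ids, parameter_names)``.
    """
    system = _system_for(model)
    decomp = conservation_analysis(model)
    species = decomp.species_ids
    if x_star is None:
        xs = steady_state(system, tol=max(tol * 1e-3, 1e-12))
        x_map = dict(zip(system.state_ids, xs))
    else:
        x_map = dict(x_star)
        for s in system.state_ids:
            x_map.setdefault(s, system.initial_state[system.state_ids.index(s)])
    if parameters is None:
        parameters = [p.id for p in model.parameters]
    p = system.parameter_values

    l_mat = np.array(decomp.link.tolist(), dtype=float) if species else np.zeros((0, 0))
    n_red = np.array(decomp.reduced.tolist(), dtype=float) if species else np.zeros((0, 0))
    elast = _rate_derivatives(system, species, x_map, p, species, "state")
    j_red = n_red @ elast @ l_mat
    if j_red.size and abs(np.linalg.det(j_red)) < 1e-14:
        raise SingularityError("reduced Jacobian is singular at the given steady state")

    known = set(system.parameter_ids)
    cols = [s for s in parameters if s in known]
    dv_dp = _rate_derivatives(system, species, x_map, p, cols, "param")
    sens_red = -np.linalg.solve(j_red, n_red @ dv_dp) if j_red.size else np.zeros((0, len(cols)))
    sens_full = l_mat @ sens_red
    out = np.zeros((len(species), len(parameters)))
    for j, name in enumerate(parameters):
        if name in known:
            out[:, j] = sens_full[:, cols.index(name)]
    return out, species, list(parameters)


@dataclass
class McaReport:
    species_ids: list
    reaction_ids: list
    elasticities: np.ndarray  # scaled, reactions x species
    flux_control: np.ndarray  # scaled C^J, reactions(flux) x reactions
    concentration_control: np.ndarray  # scaled C^S, species x reactions
    steady_state: dict
    fluxes: np.ndarray
    elasticities_unscaled: np.ndarray
    flux_control_unscaled: np.ndarray
    concentration_control_unscaled: np.ndarray

    def to_frames(self):
        import pandas as pd

        return {
            "elasticities": pd.DataFrame(
                self.elasticities, index=self.reaction_ids, columns=self.species_ids
            ),
            "flux_control": pd.DataFrame(
                self.flux_control, index=self.reaction_ids, columns=self.reaction_ids
            ),
            "concentration_control": pd.DataFrame(
                self.concentration_control, index=self.species_ids, columns=self.reaction_ids
            ),
        }

    def to_json_dict(self):
        frames = self.to_frames()
        return {k: v.to_dict() for k, v in frames.items()} | {
            "steady_state": self.steady_state
        }


def mca(model: MathModel, x_star: Optional[dict] = None, tol: float = 1e-9) -> McaReport:
    """Metabolic control analysis at a steady state with nonzero fluxes."""
    system = _system_for(model)
    decomp = conservation_analysis(model)
    species = decomp.species_ids
    if x_star is None:
        xs = steady_state(system, tol=tol)
        x_map = dict(zip(system.state_ids, xs))
    else:
        x_map = dict(x_star)
    p = system.parameter_values
    state = np.array([x_map[s] for s in system.state_ids], dtype=float)
    v = np.asarray(system.velocities(0.0, state, (), p), dtype=float)
    for j, flux in enumerate(v):
        if abs(flux) < 1e-12:
            raise ZeroFluxError(
                f"reaction {system.reaction_ids[j]!r} carries zero flux; "
                "scaled coefficients are undefined"
            )

    l_mat = np.array(decomp.link.tolist(), dtype=float)
    n_red = np.array(decomp.reduced.tolist(), dtype=float)
    elast = _rate_derivatives(system, species, x_map, p, species, "state")
    j_red = n_red @ elast @ l_mat
    if abs(np.linalg.det(j_red)) < 1e-14:
        raise SingularityError("reduced Jacobian is singular at the steady state")
    c_s = -l_mat @ np.linalg.solve(j_red, n_red)  # species x reactions, unscaled
    c_j = np.eye(len(v)) + elast @ c_s  # flux x reactions, unscaled

    x_vec = np.array([x_map[s] for s in species], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        eps_scaled = elast * (x_vec[None, :] / v[:, None])
        cj_scaled = c_j * (v[None, :] / v[:, None])
        cs_scaled = c_s * (v[None, :] / np.where(x_vec == 0, np.nan, x_vec)[:, None])
    cs_scaled = np.nan_to_num(cs_scaled, nan=0.0)

    row_j = cj_scaled.sum(axis=1)
    if np.max(np.abs(row_j - 1.0)) > 1e-6:
        raise SingularityError(
            f"flux control summation theorem violated: row sums {row_j}"
        )
    row_s = cs_scaled.sum(axis=1)
    if np.max(np.abs(row_s)) > 1e-6:
        raise SingularityError(
            f"concentration control summation theorem violated: row sums {row_s}"
        )
    return McaReport(
        species_ids=species,
        reaction_ids=system.reaction_ids,
        elasticities=eps_scaled,
        flux_control=cj_scaled,
        concentration_control=cs_scaled,
        steady_state={s: float(x_map[s]) for s in species},
        fluxes=v,
        elasticities_unscaled=elast,
        flux_control_unscaled=c_j,
        concentration_control_unscaled=c_s,
    )
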