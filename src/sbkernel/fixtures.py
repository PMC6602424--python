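"""Deterministic test-model generators.

Every other module is testable without downloads: :func:`canonical` serves
the models defined in the bundled catalogue document
(``data/catalog.txt``, parsed through the text-format reader, so the
catalogue text is the single source of truth), and
:func:`random_mass_action` generates connected mass-action networks with
seeded reproducibility for property tests.
"""

from __future__ import annotations

import importlib.resources
import re
from functools import lru_cache

import networkx as nx
import numpy as np

from . import expressions as ex
from .metamodel import MathModel, Parameter, Reaction, Variable, diagram_from_math, validate

__all__ = ["CATALOGUE", "canonical", "canonical_names", "random_mass_action"]


@lru_cache(maxsize=1)
def _catalogue_sections() -> dict:
    text = (
        importlib.resources.files("sbkernel").joinpath("data/catalog.txt").read_text()
    )
    sections = {}
    current = None
    for line in text.splitlines():
        m = re.match(r"^==\s*(\S+)\s*==$", line.strip())
        if m:
            current = m.group(1)
            sections[current] = []
        elif current is not None:
            sections[current].append(line)
    return {k: "\n".join(v).strip() + "\n" for k, v in sections.items()}


CATALOGUE = (
    "decay",
    "logistic",
    "two_step_pathway",
    "enzyme_mm",
    "robertson",
    "dimerization",
    "immigration_death",
    "decay_chain_modular",
    "event_demo",
    "constraint_demo",
    "fast_equilibrium_demo",
)


def canonical_names() -> tuple:
    return CATALOGUE


def canonical(name: str):
    """Return the catalogue model ``(Diagram, MathModel)`` (or ModularModel)."""
    sections = _catalogue_sections()
    if name not in sections:
        raise KeyError(
            f"unknown canonical model {name!r}; available: {', '.join(sorted(sections))}"
        )
    from .model_io import read_text

    return read_text(sections[name])


def random_mass_action(n_species: int, n_reactions: int, seed: int,
                       open_network: bool = False):
    """Generate a connected random mass-action network.

    Stoichiometries are drawn from {1, 2}, rate constants log-uniformly
    from [0.1, 10], and every kinetic law is ``k·∏ reactant^stoich``, so
    states stay nonnegative; product stoichiometry never exceeds the
    reactant side, keeping trajectories bounded.  With ``open_network`` a
    constant inflow into the first species and a first-order outflow from
    the last are appended, which typically yields a steady state with
    positive fluxes (used by the control-analysis property tests).
    Identical arguments give identical models.
    """
    if n_species < 1 or n_reactions < 1:
        raise ValueError("need at least one species and one reaction")
    rng = np.random.default_rng(np.random.SeedSequence((seed, n_species, n_reactions)))
    species = [f"S{i + 1}" for i in range(n_species)]
    for _ in range(200):
        reactions = []
        for j in range(n_reactions):
            n_re = int(rng.integers(1, min(2, n_species) + 1))
            reactants = list(rng.choice(n_species, size=n_re, replace=False))
            st_re = [int(rng.integers(1, 3)) for _ in reactants]
            others = [i for i in range(n_species) if i not in reactants]
            pool = others if others else list(range(n_species))
            # keep total product stoichiometry <= reactant side so total
            # mass never increases and trajectories stay bounded
            budget = sum(st_re)
            products, st_pr = [], []
            order = list(rng.permutation(pool))
            while budget > 0 and order and len(products) < 2:
                sid = order.pop()
                st = int(rng.integers(1, min(2, budget) + 1))
                products.append(sid)
                st_pr.append(st)
                budget -= st
                if rng.random() < 0.5:
                    break
            k = float(np.exp(rng.uniform(np.log(0.1), np.log(10.0))))
            reactions.append((reactants, st_re, products, st_pr, k))
        g = nx.Graph()
        g.add_nodes_from(range(n_species))
        for reactants, _, products, _, _ in reactions:
            involved = reactants + products
            for a, b in zip(involved, involved[1:]):
                g.add_edge(a, b)
        if nx.is_connected(g):
            break
    model = MathModel(name=f"random_{n_species}s_{n_reactions}r_{seed}")
    for s in species:
        model.variables.append(Variable(id=s, initial_value=5.0))
    for j, (reactants, st_re, products, st_pr, k) in enumerate(reactions):
        kid = f"k{j + 1}"
        model.parameters.append(Parameter(id=kid, value=k))
        law_terms = [kid] + [
            f"{species[i]}**{st}" if st > 1 else species[i]
            for i, st in zip(reactants, st_re)
        ]
        model.reactions.append(
            Reaction(
                id=f"R{j + 1}",
                reactants=[(species[i], st) for i, st in zip(reactants, st_re)],
                products=[(species[i], st) for i, st in zip(products, st_pr)],
                kinetic_law=ex.parse_expression("*".join(law_terms)),
            )
        )
    if open_network:
        k_in = float(np.exp(rng.uniform(np.log(0.1), np.log(10.0))))
        k_out = float(np.exp(rng.uniform(np.log(0.1), np.log(10.0))))
        model.parameters.append(Parameter(id="k_in", value=k_in))
        model.parameters.append(Parameter(id="k_out", value=k_out))
        model.reactions.append(
            Reaction(id="Rin", products=[(species[0], 1)],
                     kinetic_law=ex.parse_expression("k_in"))
        )
        model.reactions.append(
            Reaction(id="Rout", reactants=[(species[-1], 1)],
                     kinetic_law=ex.parse_expression(f"k_out*{species[-1]}"))
        )
    diagram = diagram_from_math(model)
    diags = validate(diagram, model)
    if diags:  # pragma: no cover - generator contract
        raise RuntimeError("generated model fails validation: " + "; ".join(map(str, diags)))
    return diagram, model
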