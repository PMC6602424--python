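"""The compartmentalized attributed graph and its executable mathematical overlay.

A model is described on two coupled levels:

* a :class:`Diagram` — a graph of species, reaction, compartment, module and
  port nodes with attributed edges, carrying free-form annotation strings in
  place of database cross-references;
* a :class:`MathModel` — the executable layer: variables, parameters,
  reactions with kinetic laws, assignment/rate/algebraic rules, discrete
  events and constraints.

Graph elements point into the mathematical layer through ``math_ref``.
:func:`validate` checks every structural invariant and returns diagnostics
(never raises); :func:`diagram_from_math` derives the canonical graph for a
mathematical model, which is how the readers and fixtures build diagrams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Union

import networkx as nx
import sympy as sp

from .expressions import (
    Expression,
    evaluate,  # re-exported: the meta-model's expression evaluator  # noqa: F401
    free_symbols,
    is_boolean_expression,
)

NODE_KINDS = ("species", "reaction", "compartment", "module", "port", "annotation")
EDGE_ROLES = ("reactant", "product", "modifier", "connection")
DYNAMICS = ("ode", "assigned", "algebraic", "constant-boundary")
RULE_KINDS = ("assignment", "rate", "algebraic")


@dataclass
class Node:
    id: str
    kind: str
    attributes: dict = field(default_factory=dict)
    math_ref: Optional[str] = None


@dataclass
class Edge:
    id: str
    source: str
    target: str
    role: str
    stoichiometry: Optional[Fraction] = None


@dataclass
class Diagram:
    name: str
    nodes: dict = field(default_factory=dict)  # id -> Node
    edges: list = field(default_factory=list)
    compartments: dict = field(default_factory=dict)  # node id -> parent compartment id
    annotations: dict = field(default_factory=dict)

    def add_node(self, node: Node) -> Node:
        if node.id in self.nodes:
            raise ValueError(f"duplicate node id {node.id!r}")
        self.nodes[node.id] = node
        return node


@dataclass
class Variable:
    id: str
    initial_value: float = 0.0
    units: str = ""
    dynamics: str = "ode"
    compartment: Optional[str] = None


@dataclass
class Parameter:
    id: str
    value: float = 0.0
    units: str = ""
    constant: bool = True


@dataclass
class Reaction:
    id: str
    reactants: list = field(default_factory=list)  # (species id, Fraction)
    products: list = field(default_factory=list)
    modifiers: list = field(default_factory=list)
    kinetic_law: Optional[Expression] = None
    fast: bool = False
    reversible: bool = False


@dataclass
class Rule:
    kind: str
    expression: Expression
    target: Optional[str] = None


@dataclass
class Event:
    id: str
    trigger: Expression
    assignments: list = field(default_factory=list)  # (target symbol, Expression)
    delay: Union[float, Expression] = 0.0
    use_trigger_time_values: bool = False
    halt: bool = False
    message: str = ""


@dataclass
class Constraint:
    id: str
    condition: Expression
    message: str = ""


@dataclass
class MathModel:
    name: str = "model"
    variables: list = field(default_factory=list)
    parameters: list = field(default_factory=list)
    reactions: list = field(default_factory=list)
    rules: list = field(default_factory=list)
    events: list = field(default_factory=list)
    constraints: list = field(default_factory=list)
    compartment_sizes: dict = field(default_factory=dict)  # id -> size
    time_symbol: str = "time"
    annotations: dict = field(default_factory=dict)

    # --- symbol table helpers -------------------------------------------------
    def variable(self, vid: str) -> Variable:
        for v in self.variables:
            if v.id == vid:
                return v
        raise KeyError(vid)

    def parameter(self, pid: str) -> Parameter:
        for p in self.parameters:
            if p.id == pid:
                return p
        raise KeyError(pid)

    def symbol_ids(self) -> set:
        ids = {v.id for v in self.variables}
        ids |= {p.id for p in self.parameters}
        ids |= set(self.compartment_sizes)
        ids.add(self.time_symbol)
        return ids

    def initial_env(self) -> dict:
        env = {v.id: float(v.initial_value) for v in self.variables}
        env.update({p.id: float(p.value) for p in self.parameters})
        env.update({c: float(s) for c, s in self.compartment_sizes.items()})
        env[self.time_symbol] = 0.0
        return env

    def reaction_expressions(self):
        for r in self.reactions:
            if r.kinetic_law is not None:
                yield f"reaction {r.id}", r.kinetic_law
        for i, rule in enumerate(self.rules):
            yield f"rule[{i}]", rule.expression
        for e in self.events:
            yield f"event {e.id} trigger", e.trigger
            if isinstance(e.delay, sp.Basic):
                yield f"event {e.id} delay", e.delay
            for tgt, expr in e.assignments:
                yield f"event {e.id} assignment {tgt}", expr
        for c in self.constraints:
            yield f"constraint {c.id}", c.condition


@dataclass
class Diagnostic:
    element: str
    rule: str
    message: str

    def __str__(self):
        return f"[{self.element}] {self.rule}: {self.message}"


def validate(diagram: Optional[Diagram], model: Optional[MathModel]) -> list:
    """Check every structural invariant; return a list of diagnostics.

    Empty list iff the pair is well-formed.  Purely observational: neither
    argument is modified, and repeated calls give identical results.
    """
    out: list[Diagnostic] = []
    if diagram is not None:
        out.extend(_validate_diagram(diagram))
    if model is not None:
        out.extend(_validate_math(model))
    if diagram is not None and model is not None:
        known = model.symbol_ids() | {r.id for r in model.reactions}
        for node in diagram.nodes.values():
            if node.math_ref is not None and node.math_ref not in known:
                out.append(
                    Diagnostic(
                        f"node {node.id}",
                        "math-ref-resolution",
                        f"math_ref {node.math_ref!r} matches no model element",
                    )
                )
    return out


def _validate_diagram(diagram: Diagram) -> list:
    out = []
    for node in diagram.nodes.values():
        if node.kind not in NODE_KINDS:
            out.append(
                Diagnostic(f"node {node.id}", "node-kind", f"unknown kind {node.kind!r}")
            )
        if node.kind == "port":
            refs = node.attributes.get("variable")
            if not isinstance(refs, str):
                out.append(
                    Diagnostic(
                        f"node {node.id}",
                        "port-variable",
                        "port nodes carry exactly one variable reference",
                    )
                )
    # compartment nesting must be a forest
    g = nx.DiGraph()
    for child, parent in diagram.compartments.items():
        if child not in diagram.nodes:
            out.append(
                Diagnostic(f"node {child}", "compartment-nesting", "unknown child node")
            )
        if parent not in diagram.nodes:
            out.append(
                Diagnostic(
                    f"node {parent}", "compartment-nesting", "unknown parent compartment"
                )
            )
        g.add_edge(child, parent)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        members = "⊂".join(a for a, _ in cycle)
        out.append(
            Diagnostic(
                f"compartments {members}",
                "compartment-acyclic",
                f"compartment nesting contains a cycle: {members}",
            )
        )
    for edge in diagram.edges:
        for endpoint in (edge.source, edge.target):
            if endpoint not in diagram.nodes:
                out.append(
                    Diagnostic(
                        f"edge {edge.id}",
                        "edge-endpoint",
                        f"endpoint {endpoint!r} names no existing node",
                    )
                )
        if edge.role not in EDGE_ROLES:
            out.append(Diagnostic(f"edge {edge.id}", "edge-role", f"unknown role {edge.role!r}"))
        if edge.role in ("reactant", "product"):
            kinds = {
                diagram.nodes[e].kind
                for e in (edge.source, edge.target)
                if e in diagram.nodes
            }
            if kinds and kinds != {"species", "reaction"}:
                out.append(
                    Diagnostic(
                        f"edge {edge.id}",
                        "reactant-product-endpoints",
                        "reactant/product edges join species and reaction nodes only",
                    )
                )
            if edge.stoichiometry is None or edge.stoichiometry <= 0:
                out.append(
                    Diagnostic(
                        f"edge {edge.id}",
                        "stoichiometry-positive",
                        "reactant/product edges need a positive stoichiometry",
                    )
                )
    return out


def _validate_math(model: MathModel) -> list:
    out = []
    seen = {}
    for kind, items in (
        ("variable", model.variables),
        ("parameter", model.parameters),
        ("reaction", model.reactions),
    ):
        for item in items:
            if item.id in seen:
                out.append(
                    Diagnostic(
                        f"{kind} {item.id}",
                        "id-unique",
                        f"id also used by {seen[item.id]}",
                    )
                )
            seen[item.id] = f"{kind} {item.id}"
    symbols = model.symbol_ids()
    for v in model.variables:
        if v.dynamics not in DYNAMICS:
            out.append(
                Diagnostic(f"variable {v.id}", "dynamics", f"unknown dynamics {v.dynamics!r}")
            )
        if not _is_finite(v.initial_value):
            out.append(
                Diagnostic(f"variable {v.id}", "initial-finite", "initial value not finite")
            )
        if v.compartment is not None and v.compartment not in model.compartment_sizes:
            out.append(
                Diagnostic(
                    f"variable {v.id}",
                    "compartment-resolution",
                    f"compartment {v.compartment!r} undeclared",
                )
            )
    for where, expr in model.reaction_expressions():
        for name in sorted(free_symbols(expr) - symbols):
            out.append(
                Diagnostic(
                    where,
                    "symbol-resolution",
                    f"symbol {name!r} resolves to no variable, parameter or time",
                )
            )
    for r in model.reactions:
        for sid, st in list(r.reactants) + list(r.products):
            if sid not in {v.id for v in model.variables}:
                out.append(
                    Diagnostic(
                        f"reaction {r.id}", "species-resolution", f"unknown species {sid!r}"
                    )
                )
            if st <= 0:
                out.append(
                    Diagnostic(
                        f"reaction {r.id}",
                        "stoichiometry-positive",
                        f"nonpositive stoichiometry for {sid!r}",
                    )
                )
    rule_targets = {}
    for i, rule in enumerate(model.rules):
        if rule.kind not in RULE_KINDS:
            out.append(Diagnostic(f"rule[{i}]", "rule-kind", f"unknown kind {rule.kind!r}"))
        if rule.kind == "algebraic":
            if rule.target is not None:
                out.append(
                    Diagnostic(f"rule[{i}]", "rule-target", "algebraic rules carry no target")
                )
        else:
            if rule.target is None:
                out.append(
                    Diagnostic(f"rule[{i}]", "rule-target", f"{rule.kind} rule needs a target")
                )
            elif rule.target in rule_targets:
                out.append(
                    Diagnostic(
                        f"rule[{i}]",
                        "single-rule-per-target",
                        f"{rule.target!r} already targeted by rule[{rule_targets[rule.target]}]",
                    )
                )
            elif rule.target not in symbols:
                out.append(
                    Diagnostic(f"rule[{i}]", "symbol-resolution", f"unknown target {rule.target!r}")
                )
            if rule.target is not None:
                rule_targets.setdefault(rule.target, i)
    for e in model.events:
        if not is_boolean_expression(e.trigger):
            out.append(
                Diagnostic(f"event {e.id}", "trigger-boolean", "trigger must be boolean")
            )
        for tgt, _ in e.assignments:
            if tgt not in symbols:
                out.append(
                    Diagnostic(
                        f"event {e.id}", "symbol-resolution", f"unknown assignment target {tgt!r}"
                    )
                )
    for c in model.constraints:
        if not is_boolean_expression(c.condition):
            out.append(
                Diagnostic(f"constraint {c.id}", "condition-boolean", "condition must be boolean")
            )
    return out


def _is_finite(x) -> bool:
    try:
        x = float(x)
    except (TypeError, ValueError):
        return False
    return x == x and abs(x) != float("inf")


def diagram_from_math(model: MathModel, name: Optional[str] = None) -> Diagram:
    """Derive the canonical graph for a mathematical model."""
    d = Diagram(name=name or model.name)
    for cid in model.compartment_sizes:
        d.add_node(Node(id=cid, kind="compartment", math_ref=cid))
    for v in model.variables:
        d.add_node(Node(id=v.id, kind="species", math_ref=v.id))
        if v.compartment is not None and v.compartment in d.nodes:
            d.compartments[v.id] = v.compartment
    for r in model.reactions:
        d.add_node(Node(id=r.id, kind="reaction", math_ref=r.id))
        for i, (sid, st) in enumerate(r.reactants):
            d.edges.append(
                Edge(f"{r.id}__re{i}", source=sid, target=r.id, role="reactant",
                     stoichiometry=Fraction(st))
            )
        for i, (sid, st) in enumerate(r.products):
            d.edges.append(
                Edge(f"{r.id}__pr{i}", source=r.id, target=sid, role="product",
                     stoichiometry=Fraction(st))
            )
        for i, sid in enumerate(r.modifiers):
            d.edges.append(Edge(f"{r.id}__mo{i}", source=sid, target=r.id, role="modifier"))
    return d
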