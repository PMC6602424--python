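"""Model preprocessors and the compiler to an executable system.

A model is brought into a simulatable state through a pipeline of
transformations: modular models are flattened into a single namespace,
constraints become halting events, fast (rapid-equilibrium) reactions become
algebraic relations plus pool conservation, boolean expressions become 0/1
numerics, and finally :func:`compile_system` emits a
:class:`CompiledSystem` — in-memory callables for the right-hand side,
event triggers/assignments, algebraic residuals and stochastic propensities,
together with the stoichiometric matrix.

Canonical state is *amount*; concentration-initialized species were already
converted by the readers, and compartment sizes enter expressions as
constant symbols.  Layouts are deterministic: variables in declaration
order, parameters in declaration order.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Optional

import numpy as np
import sympy as sp

from .expressions import boolean_to_numeric, free_symbols
from .metamodel import (
    Diagram,
    Event,
    MathModel,
    Parameter,
    Reaction,
    Rule,
    Variable,
    diagram_from_math,
    validate,
)

__all__ = [
    "CompiledSystem",
    "CompileError",
    "EngineCompatibilityError",
    "UnsupportedTransformationError",
    "flatten",
    "constraints_to_events",
    "fast_to_algebraic",
    "boolean_to_numeric",
    "compile_system",
]

HALT_TARGET = "__halt__"


class CompileError(ValueError):
    pass


class EngineCompatibilityError(CompileError):
    pass


class UnsupportedTransformationError(ValueError):
    pass


class FlattenError(ValueError):
    pass


# --------------------------------------------------------------------------
# flatten
# --------------------------------------------------------------------------

def flatten(mm) -> tuple:
    """Flatten a modular model into a single namespaced ``(Diagram, MathModel)``.

    Symbols are prefixed ``module__symbol``.  Undirected connections merge
    the connected variables into one, keeping the master's initial value;
    directed connections rewrite each consumer symbol to
    ``factor * producer``.  Name collisions and undirected connections
    between two differential variables without a master are errors.
    """
    from .modular import ModularModel

    if not isinstance(mm, ModularModel):
        raise FlattenError("flatten expects a ModularModel")
    flat = MathModel(name=mm.name)
    rename: dict[str, dict] = {m: {} for m in mm.modules}

    for mod_name in mm.modules:
        _, math = mm.modules[mod_name]
        for sym in math.symbol_ids() - {math.time_symbol}:
            rename[mod_name][sym] = f"{mod_name}__{sym}"
        rename[mod_name][math.time_symbol] = flat.time_symbol

    # resolve undirected merges: map merged symbols to the master symbol
    merged_initial = {}
    for conn in mm.connections:
        if conn.kind != "undirected":
            continue
        master = tuple(conn.master) if conn.master else None
        if master is None:
            n_ode = 0
            for mod, sym in conn.endpoints:
                _, math = mm.modules[mod]
                try:
                    if math.variable(sym).dynamics == "ode":
                        n_ode += 1
                except KeyError:
                    pass
            if n_ode > 1:
                raise FlattenError(
                    "undirected connection between two differential variables "
                    f"needs a master: {conn.endpoints}"
                )
            master = tuple(conn.endpoints[0])
        mmod, msym = master
        target = f"{mmod}__{msym}"
        for mod, sym in conn.endpoints:
            rename[mod][sym] = target
        _, mmath = mm.modules[mmod]
        try:
            merged_initial[target] = mmath.variable(msym).initial_value
        except KeyError:
            merged_initial[target] = mmath.parameter(msym).value

    # directed rewrites: consumer symbol -> factor * producer symbol
    directed_subs: dict[str, sp.Expr] = {}
    skip: set[tuple] = set()
    for conn in mm.connections:
        if conn.kind != "directed":
            continue
        pmod, psym = conn.endpoints[0]
        producer = sp.Symbol(rename[pmod][psym])
        for cmod, csym in conn.endpoints[1:]:
            cname = rename[cmod][csym]
            directed_subs[cname] = conn.factor * producer
            skip.add((cmod, csym))

    seen = {}
    for mod_name in sorted(mm.modules):
        _, math = mm.modules[mod_name]
        sub_map = {sp.Symbol(s): sp.Symbol(t) for s, t in rename[mod_name].items()}

        def rn(sym):
            return rename[mod_name][sym]

        def rewrite(expr):
            expr = expr.xreplace(sub_map)
            return expr.xreplace(
                {sp.Symbol(k): v for k, v in directed_subs.items()}
            )

        for cid, size in math.compartment_sizes.items():
            flat.compartment_sizes[rn(cid)] = size
        for v in math.variables:
            new_id = rn(v.id)
            if (mod_name, v.id) in skip:
                continue
            if new_id in seen:
                if new_id in merged_initial:
                    continue  # merged by an undirected connection
                raise FlattenError(f"name collision after namespacing: {new_id!r}")
            seen[new_id] = True
            flat.variables.append(
                Variable(
                    id=new_id,
                    initial_value=merged_initial.get(new_id, v.initial_value),
                    units=v.units,
                    dynamics=v.dynamics,
                    compartment=rn(v.compartment) if v.compartment else None,
                )
            )
        for p in math.parameters:
            new_id = rn(p.id)
            if (mod_name, p.id) in skip:
                continue
            if new_id in seen:
                if new_id in merged_initial:
                    continue
                raise FlattenError(f"name collision after namespacing: {new_id!r}")
            seen[new_id] = True
            flat.parameters.append(
                Parameter(id=new_id, value=merged_initial.get(new_id, p.value),
                          units=p.units, constant=p.constant)
            )
        for r in math.reactions:
            flat.reactions.append(
                Reaction(
                    id=rn(r.id) if r.id in rename[mod_name] else f"{mod_name}__{r.id}",
                    reactants=[(rn(s), st) for s, st in r.reactants],
                    products=[(rn(s), st) for s, st in r.products],
                    modifiers=[rn(s) for s in r.modifiers],
                    kinetic_law=rewrite(r.kinetic_law) if r.kinetic_law is not None else None,
                    fast=r.fast,
                    reversible=r.reversible,
                )
            )
        for rule in math.rules:
            flat.rules.append(
                Rule(rule.kind, rewrite(rule.expression),
                     target=rn(rule.target) if rule.target else None)
            )
        for e in math.events:
            flat.events.append(
                Event(
                    id=f"{mod_name}__{e.id}",
                    trigger=rewrite(e.trigger),
                    assignments=[(rn(t), rewrite(x)) for t, x in e.assignments],
                    delay=rewrite(e.delay) if isinstance(e.delay, sp.Basic) else e.delay,
                    use_trigger_time_values=e.use_trigger_time_values,
                    halt=e.halt,
                    message=e.message,
                )
            )
        for c in math.constraints:
            flat.constraints.append(
                copy.replace(c, id=f"{mod_name}__{c.id}", condition=rewrite(c.condition))
                if hasattr(copy, "replace")
                else type(c)(id=f"{mod_name}__{c.id}", condition=rewrite(c.condition),
                             message=c.message)
            )
    diagram = diagram_from_math(flat)
    diags = validate(diagram, flat)
    if diags:
        raise FlattenError(
            "flattened model fails validation: " + "; ".join(str(d) for d in diags)
        )
    return diagram, flat


# --------------------------------------------------------------------------
# constraint and fast-reaction transforms
# --------------------------------------------------------------------------

def constraints_to_events(model: MathModel) -> MathModel:
    """Replace each constraint by a halting event triggered by its negation."""
    if not model.constraints:
        return model
    out = copy.deepcopy(model)
    for c in out.constraints:
        out.events.append(
            Event(
                id=f"halt_{c.id}",
                trigger=sp.Not(c.condition),
                assignments=[],
                halt=True,
                message=c.message or f"constraint {c.id} violated",
            )
        )
    out.constraints = []
    return out


def _mass_action_split(rx: Reaction):
    """Split ``kf*prod(reactants) - kr*prod(products)`` or fail."""
    law = sp.expand(rx.kinetic_law)
    terms = sp.Add.make_args(law)
    if len(terms) != 2:
        raise UnsupportedTransformationError(
            f"fast reaction {rx.id!r}: kinetic law is not a two-term "
            "reversible mass-action difference"
        )
    reactant_ids = {s for s, _ in rx.reactants}
    product_ids = {s for s, _ in rx.products}
    forward = backward = None
    for term in terms:
        syms = free_symbols(term)
        coeff = term.as_coeff_Mul()[0]
        if syms & product_ids and coeff.is_negative:
            backward = -term
        elif syms & reactant_ids or not (syms & product_ids):
            forward = term
    if forward is None or backward is None:
        raise UnsupportedTransformationError(
            f"fast reaction {rx.id!r}: expected kf*reactants - kr*products form"
        )
    return forward, backward


def fast_to_algebraic(model: MathModel) -> MathModel:
    """Replace fast reversible mass-action reactions by equilibrium algebra.

    Each fast reaction contributes the relation ``kf*∏reactants = kr*∏products``;
    the species it touches become algebraic unknowns, and each conserved pool
    of the fast subnetwork gets a new differential variable whose rate
    collects the slow-reaction flux into the pool.
    """
    fast = [r for r in model.reactions if r.fast]
    if not fast:
        return model
    out = copy.deepcopy(model)
    fast = [r for r in out.reactions if r.fast]
    slow = [r for r in out.reactions if not r.fast]

    fast_species = []
    for r in fast:
        if not r.reversible:
            raise UnsupportedTransformationError(
                f"fast reaction {r.id!r} is not reversible"
            )
        for s, _ in r.reactants + r.products:
            if s not in fast_species:
                fast_species.append(s)

    # equilibrium relations
    for r in fast:
        forward, backward = _mass_action_split(r)
        out.rules.append(Rule("algebraic", forward - backward))

    # conservation pools of the fast subnetwork (left null space, rational)
    n = sp.zeros(len(fast_species), len(fast))
    for j, r in enumerate(fast):
        for s, st in r.reactants:
            n[fast_species.index(s), j] -= sp.Rational(Fraction(st))
        for s, st in r.products:
            n[fast_species.index(s), j] += sp.Rational(Fraction(st))
    pools = n.T.nullspace()

    slow_net = {s: sp.Integer(0) for s in fast_species}
    for r in slow:
        vsym = r.kinetic_law if r.kinetic_law is not None else sp.Integer(0)
        for s, st in r.reactants:
            if s in slow_net:
                slow_net[s] -= sp.Rational(Fraction(st)) * vsym
        for s, st in r.products:
            if s in slow_net:
                slow_net[s] += sp.Rational(Fraction(st)) * vsym

    for k, m in enumerate(pools):
        scale = sp.lcm([sp.fraction(x)[1] for x in m])
        m = [sp.nsimplify(x * scale) for x in m]
        pool_id = f"pool_{k + 1}"
        total0 = sum(
            float(mi) * out.variable(s).initial_value
            for mi, s in zip(m, fast_species)
        )
        out.variables.append(Variable(id=pool_id, initial_value=total0, dynamics="ode"))
        rate = sum(mi * slow_net[s] for mi, s in zip(m, fast_species))
        out.rules.append(Rule("rate", sp.expand(rate), target=pool_id))
        residual = sum(
            mi * sp.Symbol(s) for mi, s in zip(m, fast_species)
        ) - sp.Symbol(pool_id)
        out.rules.append(Rule("algebraic", residual))

    for s in fast_species:
        out.variable(s).dynamics = "algebraic"
    out.reactions = slow
    return out


# --------------------------------------------------------------------------
# compilation
# --------------------------------------------------------------------------

@dataclass
class CompiledEvent:
    id: str
    indicator: Callable  # (t, y, z, p) -> 0/1 float
    assignments: list  # [(kind, index or None, value fn)]
    delay: Callable  # (t, y, z, p) -> float
    use_trigger_time_values: bool
    halt: bool
    message: str


@dataclass
class CompiledSystem:
    """Executable form of a flat model for one engine family."""

    engine_kind: str
    state_ids: list
    algebraic_ids: list
    parameter_ids: list
    species_ids: list  # reacting species (subset of state_ids, stochastic state)
    reaction_ids: list
    initial_state: np.ndarray
    initial_algebraic: np.ndarray
    parameter_values: np.ndarray
    stoichiometry: np.ndarray  # species x reactions (float)
    stoichiometry_exact: list  # rows of Fraction
    rhs: Callable  # (t, y, p) -> dy/dt  (solves algebraic block internally)
    velocities: Callable  # (t, y, z, p) -> reaction rate vector
    residuals: Optional[Callable]  # (t, y, z, p) -> residual vector
    propensities: Optional[Callable]  # (t, y, p) -> hazards (stochastic)
    events: list = field(default_factory=list)
    model: MathModel = None
    _alg_cache: np.ndarray = None

    def solve_algebraic(self, t, y, p, guess=None):
        """Solve the algebraic block for given differential state (damped Newton)."""
        if not self.algebraic_ids:
            return np.empty(0)
        z = np.array(
            guess
            if guess is not None
            else (self._alg_cache if self._alg_cache is not None else self.initial_algebraic),
            dtype=float,
        )
        nz = len(z)
        for _ in range(50):
            r = np.asarray(self.residuals(t, y, z, p), dtype=float)
            if np.max(np.abs(r)) < 1e-12:
                break
            jac = np.empty((nz, nz))
            for j in range(nz):
                h = 1e-7 * max(1.0, abs(z[j]))
                zp = z.copy()
                zp[j] += h
                jac[:, j] = (np.asarray(self.residuals(t, y, zp, p)) - r) / h
            try:
                step = np.linalg.solve(jac, -r)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(jac, -r, rcond=None)[0]
            lam = 1.0
            base = np.max(np.abs(r))
            for _ in range(20):
                zn = z + lam * step
                rn = np.asarray(self.residuals(t, y, zn, p), dtype=float)
                if np.max(np.abs(rn)) < base:
                    z = zn
                    break
                lam *= 0.5
            else:
                z = z + step
        self._alg_cache = z.copy()
        return z

    def full_values(self, t, y, p=None):
        """Map a state vector to a symbol->value dict (including algebraic)."""
        p = self.parameter_values if p is None else p
        env = dict(zip(self.state_ids, map(float, y)))
        env.update(dict(zip(self.parameter_ids, map(float, p))))
        if self.algebraic_ids:
            z = self.solve_algebraic(t, y, p)
            env.update(dict(zip(self.algebraic_ids, map(float, z))))
        return env

    def initial_full_env(self):
        env = dict(zip(self.state_ids, map(float, self.initial_state)))
        env.update(dict(zip(self.parameter_ids, map(float, self.parameter_values))))
        env.update(dict(zip(self.algebraic_ids, map(float, self.initial_algebraic))))
        return env

    def state_from_env(self, env):
        return np.array([env[s] for s in self.state_ids], dtype=float)

    def params_from_env(self, env):
        return np.array([env[s] for s in self.parameter_ids], dtype=float)


def _substitute_assignments(model: MathModel):
    """Return substitution map eliminating assignment-rule targets."""
    assigns = {
        sp.Symbol(r.target): r.expression for r in model.rules if r.kind == "assignment"
    }
    for _ in range(len(assigns) + 1):
        changed = False
        for k in assigns:
            new = assigns[k].xreplace(assigns)
            if new != assigns[k]:
                assigns[k] = new
                changed = True
        if not changed:
            break
    else:
        raise CompileError("cyclic assignment rules")
    return assigns


def compile_system(diagram: Diagram, model: MathModel, engine_kind: str = "ode") -> CompiledSystem:
    """Compile a flat, preprocessed model into executable callables.

    ``engine_kind`` is ``"ode"`` or ``"stochastic"``.  For a pure reaction
    network the emitted right-hand side equals ``N·v(x, t)``; rate rules add
    their terms, and algebraic rules define an inner nonlinear block solved
    at each evaluation.  Stochastic compilation reinterprets kinetic laws as
    hazards over integer copy numbers and rejects rate/algebraic rules and
    non-integer stoichiometry.
    """
    if model.constraints:
        model = constraints_to_events(model)
    diags = validate(None, model)
    if diags:
        raise CompileError("model fails validation: " + "; ".join(map(str, diags)))

    assigns = _substitute_assignments(model)

    def subst(expr):
        return expr.xreplace(assigns) if isinstance(expr, sp.Basic) else expr

    rate_targets = {r.target for r in model.rules if r.kind == "rate"}
    event_targets = set()
    for e in model.events:
        for tgt, _ in e.assignments:
            event_targets.add(tgt)

    state_ids, alg_ids = [], []
    for v in model.variables:
        if v.dynamics == "ode":
            state_ids.append(v.id)
        elif v.dynamics == "algebraic":
            alg_ids.append(v.id)
    # parameters that events or rate rules drive become part of the state
    dynamic_params = [
        p.id for p in model.parameters if p.id in rate_targets or p.id in event_targets
    ]
    state_ids.extend(dynamic_params)

    param_ids = [p.id for p in model.parameters if p.id not in dynamic_params]
    param_ids += [v.id for v in model.variables if v.dynamics == "constant-boundary"]
    param_ids += list(model.compartment_sizes)

    reacting = []
    for r in model.reactions:
        for s, _ in r.reactants + r.products:
            if s not in reacting:
                reacting.append(s)
    species_ids = [s for s in state_ids if s in reacting]

    if engine_kind == "stochastic":
        if any(r.kind in ("rate", "algebraic") for r in model.rules):
            raise EngineCompatibilityError(
                "stochastic engines do not support rate or algebraic rules"
            )
        if alg_ids:
            raise EngineCompatibilityError("stochastic engines do not support algebraic variables")
        for r in model.reactions:
            for s, st in r.reactants + r.products:
                if Fraction(st).denominator != 1:
                    raise EngineCompatibilityError(
                        f"reaction {r.id!r}: non-integer stoichiometry {st} "
                        "is incompatible with stochastic simulation"
                    )

    # stoichiometric matrix over reacting state species
    n_rx = len(model.reactions)
    stoich_exact = [[Fraction(0)] * n_rx for _ in species_ids]
    index = {s: i for i, s in enumerate(species_ids)}
    for j, r in enumerate(model.reactions):
        for s, st in r.reactants:
            if s in index:
                stoich_exact[index[s]][j] -= Fraction(st)
        for s, st in r.products:
            if s in index:
                stoich_exact[index[s]][j] += Fraction(st)
    stoich = np.array([[float(x) for x in row] for row in stoich_exact]) if species_ids else np.zeros((0, n_rx))

    t_sym = sp.Symbol(model.time_symbol)
    state_syms = [sp.Symbol(s) for s in state_ids]
    alg_syms = [sp.Symbol(s) for s in alg_ids]
    param_syms = [sp.Symbol(s) for s in param_ids]
    argset = [t_sym] + state_syms + alg_syms + param_syms

    velocity_exprs = [subst(r.kinetic_law if r.kinetic_law is not None else sp.Integer(0))
                      for r in model.reactions]

    deriv = {s: sp.Integer(0) for s in state_ids}
    for i, s in enumerate(species_ids):
        for j in range(n_rx):
            if stoich_exact[index[s]][j]:
                deriv[s] += sp.Rational(stoich_exact[index[s]][j]) * velocity_exprs[j]
    for r in model.rules:
        if r.kind == "rate":
            if r.target in deriv and deriv[r.target] != 0:
                raise CompileError(
                    f"{r.target!r} is governed by both reactions and a rate rule"
                )
            if r.target in deriv:
                deriv[r.target] = subst(r.expression)
    deriv_exprs = [deriv[s] for s in state_ids]

    residual_exprs = [subst(r.expression) for r in model.rules if r.kind == "algebraic"]
    if len(residual_exprs) != len(alg_ids) and residual_exprs:
        # over/under-determined algebraic blocks: keep square by truncation check
        if len(residual_exprs) < len(alg_ids):
            raise CompileError(
                f"{len(alg_ids)} algebraic variables but only "
                f"{len(residual_exprs)} algebraic rules"
            )
        residual_exprs = residual_exprs[: len(alg_ids)]

    used = set()
    for expr in deriv_exprs + residual_exprs + velocity_exprs:
        used |= free_symbols(expr)
    unknown = used - set(state_ids) - set(alg_ids) - set(param_ids) - {model.time_symbol}
    if unknown:
        raise CompileError(f"unresolved symbols in compiled expressions: {sorted(unknown)}")

    modules = [{"Min": lambda *a: min(a), "Max": lambda *a: max(a)}, "math"]
    f_deriv = sp.lambdify(argset, deriv_exprs, modules=modules)
    f_vel = sp.lambdify(argset, velocity_exprs, modules=modules)
    f_res = sp.lambdify(argset, residual_exprs, modules=modules) if residual_exprs else None

    n_state, n_alg = len(state_ids), len(alg_ids)

    sys_ref: dict = {}

    def velocities(t, y, z, p):
        return np.asarray(f_vel(t, *y, *z, *p), dtype=float)

    def residuals(t, y, z, p):
        return np.asarray(f_res(t, *y, *z, *p), dtype=float)

    def rhs(t, y, p):
        if n_alg:
            z = sys_ref["self"].solve_algebraic(t, y, p)
        else:
            z = ()
        return np.asarray(f_deriv(t, *y, *z, *p), dtype=float)

    def propensities(t, y, p):
        a = np.asarray(f_vel(t, *y, *(), *p), dtype=float)
        return a

    init_env = model.initial_env()
    initial_state = np.array([init_env[s] for s in state_ids], dtype=float)
    initial_alg = np.array([init_env[s] for s in alg_ids], dtype=float)
    param_values = np.array([init_env[s] for s in param_ids], dtype=float)

    events = []
    state_index = {s: i for i, s in enumerate(state_ids)}
    param_index = {s: i for i, s in enumerate(param_ids)}
    for e in model.events:
        ind_expr = boolean_to_numeric(subst(e.trigger))
        f_ind = sp.lambdify(argset, ind_expr, modules=modules)
        asg = []
        for tgt, expr in e.assignments:
            f_val = sp.lambdify(argset, subst(expr), modules=modules)
            if tgt in state_index:
                asg.append(("state", state_index[tgt], f_val))
            elif tgt in param_index:
                asg.append(("param", param_index[tgt], f_val))
            else:
                raise CompileError(f"event {e.id!r}: cannot assign to {tgt!r}")
        if isinstance(e.delay, sp.Basic):
            f_delay = sp.lambdify(argset, subst(e.delay), modules=modules)
        else:
            dval = float(e.delay)
            f_delay = lambda *a, _d=dval: _d  # noqa: E731

        def make(fi):
            def indicator(t, y, z, p):
                return float(fi(t, *y, *z, *p))

            return indicator

        def make_delay(fd):
            def delay_fn(t, y, z, p):
                return float(fd(t, *y, *z, *p))

            return delay_fn

        events.append(
            CompiledEvent(
                id=e.id,
                indicator=make(f_ind),
                assignments=asg,
                delay=make_delay(f_delay),
                use_trigger_time_values=e.use_trigger_time_values,
                halt=e.halt,
                message=e.message,
            )
        )

    system = CompiledSystem(
        engine_kind=engine_kind,
        state_ids=list(state_ids),
        algebraic_ids=list(alg_ids),
        parameter_ids=list(param_ids),
        species_ids=species_ids,
        reaction_ids=[r.id for r in model.reactions],
        initial_state=initial_state,
        initial_algebraic=initial_alg,
        parameter_values=param_values,
        stoichiometry=stoich,
        stoichiometry_exact=stoich_exact,
        rhs=rhs,
        velocities=velocities,
        residuals=residuals if f_res else None,
        propensities=propensities if engine_kind == "stochastic" else None,
        events=events,
        model=model,
    )
    sys_ref["self"] = system
    return system
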