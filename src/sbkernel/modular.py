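"""Modular model composition and agent-based co-simulation.

A modular model is a set of named sub-models plus typed connections between
their variables.  Two execution routes exist: flattening into a single
namespace (``preprocess.flatten``) and co-simulation, where each module runs
its own solver and a scheduler exchanges connected values at fixed time
boundaries (:func:`simulate_agents`).

Connection semantics
--------------------
directed
    one producer endpoint, one or more consumers; at each exchange boundary
    the consumer symbol is set to ``factor * producer_value`` and held
    constant during the window (zero-order hold).
undirected
    the endpoints denote one shared quantity; a designated *master* endpoint
    supplies the initial value.  During co-simulation each module evolves its
    own copy; at each boundary the increments the non-master modules made are
    added onto the master's value and all copies are reset to the result
    (delta-exchange reconciliation, first-order accurate in the exchange
    step).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .metamodel import Diagnostic, Diagram, MathModel, validate

__all__ = [
    "Connection",
    "ModularModel",
    "ScheduleSettings",
    "CompositionError",
    "compose",
    "simulate_agents",
]


class CompositionError(ValueError):
    pass


@dataclass
class Connection:
    kind: str  # "undirected" | "directed"
    endpoints: list  # [(module name, symbol), ...]; directed: endpoints[0] is producer
    master: Optional[tuple] = None  # undirected only
    factor: float = 1.0

    def __post_init__(self):
        if self.kind not in ("undirected", "directed"):
            raise CompositionError(f"unknown connection kind {self.kind!r}")
        if len(self.endpoints) < 2:
            raise CompositionError("a connection needs at least two endpoints")
        if self.kind == "directed" and len(self.endpoints) < 2:
            raise CompositionError("directed connections need one producer and >=1 consumers")


@dataclass
class ModularModel:
    name: str = "modular"
    modules: dict = field(default_factory=dict)  # name -> (Diagram, MathModel)
    connections: list = field(default_factory=list)
    engines: dict = field(default_factory=dict)  # module name -> engine kind ("ode"/...)


@dataclass
class ScheduleSettings:
    t_end: float
    exchange_step: float
    t0: float = 0.0
    n_points: int = 101
    module_settings: dict = field(default_factory=dict)  # module name -> OdeSettings overrides
    seed: Optional[int] = None

    def __post_init__(self):
        if self.exchange_step <= 0 or self.exchange_step > self.t_end - self.t0:
            raise ValueError("exchange step must lie in (0, t_end - t0]")


def compose(modules: dict, connections: list, name: str = "modular") -> ModularModel:
    """Assemble and validate a modular model.

    ``modules`` maps names to ``(Diagram, MathModel)`` pairs.  Raises
    :class:`CompositionError` when a connection endpoint names a missing
    module or symbol; per-module structural problems surface as diagnostics
    on the returned object's ``diagnostics`` attribute.
    """
    diags: list[Diagnostic] = []
    for mname, (diagram, math) in modules.items():
        for d in validate(diagram, math):
            diags.append(Diagnostic(f"module {mname}: {d.element}", d.rule, d.message))
    for conn in connections:
        for mod, symbol in conn.endpoints:
            if mod not in modules:
                raise CompositionError(f"connection endpoint names missing module {mod!r}")
            _, math = modules[mod]
            if symbol not in math.symbol_ids():
                raise CompositionError(
                    f"connection endpoint {mod}.{symbol} names no symbol in module {mod!r}"
                )
        if conn.kind == "undirected" and conn.master is not None:
            if conn.master not in [tuple(e) for e in conn.endpoints]:
                raise CompositionError(
                    f"master {conn.master} is not one of the connection endpoints"
                )
    mm = ModularModel(name=name, modules=dict(modules), connections=list(connections))
    mm.diagnostics = diags
    # dangling ports are advisory
    for mname, (diagram, _) in modules.items():
        connected = {
            sym for conn in connections for (m, sym) in conn.endpoints if m == mname
        }
        for node in diagram.nodes.values():
            if node.kind == "port" and node.attributes.get("variable") not in connected:
                mm.diagnostics.append(
                    Diagnostic(
                        f"module {mname}: node {node.id}",
                        "dangling-port",
                        "port is not part of any connection",
                    )
                )
    return mm


def _module_order(mm: ModularModel) -> list:
    """Topological order of directed connections, name order for ties."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(sorted(mm.modules))
    for conn in mm.connections:
        if conn.kind == "directed":
            prod = conn.endpoints[0][0]
            for mod, _ in conn.endpoints[1:]:
                if prod != mod:
                    g.add_edge(prod, mod)
    try:
        return list(nx.lexicographical_topological_sort(g))
    except nx.NetworkXUnfeasible as exc:
        raise CompositionError("directed connections form a cycle") from exc


def simulate_agents(mm: ModularModel, settings: ScheduleSettings):
    """Co-simulate the modules under a fixed-step exchange scheduler.

    Each module is compiled and integrated independently inside windows of
    length ``exchange_step`` with incoming connected values held constant;
    at window boundaries the scheduler pushes values along connections (see
    module docstring for the undirected reconciliation).  The combined
    trajectory is reported on a uniform output grid with module-prefixed
    column names (``module__symbol``).
    """
    from .preprocess import compile_system, constraints_to_events
    from .simulate_ode import OdeSettings, Trajectory, simulate_ode

    order = _module_order(mm)
    systems = {}
    envs = {}
    for mname in order:
        diagram, math = mm.modules[mname]
        math = constraints_to_events(math)
        engine = mm.engines.get(mname, "ode")
        if engine != "ode":
            raise CompositionError(
                f"module {mname}: engine {engine!r} not supported by the scheduler"
            )
        systems[mname] = compile_system(diagram, math, "ode")
        envs[mname] = systems[mname].initial_full_env()

    # seed undirected copies from the master, directed consumers from producer
    _exchange(mm, envs, first=True)

    grid = np.linspace(settings.t0, settings.t_end, settings.n_points)
    columns = []
    for mname in order:
        for vid in systems[mname].state_ids:
            columns.append(f"{mname}__{vid}")
    states = np.empty((len(grid), len(columns)))
    states[0] = _collect(order, systems, envs)

    t = settings.t0
    next_out = 1
    while t < settings.t_end - 1e-12:
        t_next = min(t + settings.exchange_step, settings.t_end)
        inner = grid[(grid > t + 1e-12) & (grid < t_next - 1e-12)]
        out_times = np.concatenate([[t], inner, [t_next]])
        window_start = {m: dict(envs[m]) for m in order}
        col = 0
        for mname in order:
            sys_m = systems[mname]
            base = settings.module_settings.get(mname, {})
            ode = OdeSettings(
                t0=t,
                t_end=t_next,
                times=out_times,
                solver=base.get("solver", "dormand_prince"),
                rel_tol=base.get("rel_tol", 1e-8),
                abs_tol=base.get("abs_tol", 1e-10),
            )
            traj = simulate_ode(sys_m, ode, initial_env=envs[mname])
            width = len(sys_m.state_ids)
            # grid points strictly inside the window take the module's own
            # dense solution (connected inputs held at window-start values)
            for k, tau in enumerate(inner):
                states[next_out + k, col:col + width] = traj.states[1 + k]
            final = traj.states[-1]
            for i, vid in enumerate(sys_m.state_ids):
                envs[mname][vid] = float(final[i])
            col += width
        next_out += len(inner)
        _reconcile(mm, envs, window_start)
        t = t_next
        while next_out < len(grid) and grid[next_out] <= t + 1e-12:
            states[next_out] = _collect(order, systems, envs)
            next_out += 1
    while next_out < len(grid):
        states[next_out] = _collect(order, systems, envs)
        next_out += 1
    return Trajectory(times=grid, states=states, variable_ids=columns)


def _collect(order, systems, envs):
    row = []
    for mname in order:
        for vid in systems[mname].state_ids:
            row.append(envs[mname][vid])
    return np.array(row)


def _exchange(mm: ModularModel, envs: dict, first: bool = False):
    for conn in mm.connections:
        if conn.kind == "directed":
            pmod, psym = conn.endpoints[0]
            value = envs[pmod][psym] * conn.factor
            for cmod, csym in conn.endpoints[1:]:
                envs[cmod][csym] = value
        else:
            master = tuple(conn.master) if conn.master else tuple(conn.endpoints[0])
            mmod, msym = master
            value = envs[mmod][msym]
            for emod, esym in conn.endpoints:
                if (emod, esym) != master:
                    envs[emod][esym] = value * conn.factor


def _reconcile(mm: ModularModel, envs: dict, window_start: dict):
    for conn in mm.connections:
        if conn.kind == "directed":
            pmod, psym = conn.endpoints[0]
            value = envs[pmod][psym] * conn.factor
            for cmod, csym in conn.endpoints[1:]:
                envs[cmod][csym] = value
        else:
            master = tuple(conn.master) if conn.master else tuple(conn.endpoints[0])
            mmod, msym = master
            total = envs[mmod][msym]
            for emod, esym in conn.endpoints:
                if (emod, esym) != master:
                    total += (envs[emod][esym] - window_start[emod][esym]) / conn.factor
            envs[mmod][msym] = total
            for emod, esym in conn.endpoints:
                if (emod, esym) != master:
                    envs[emod][esym] = total * conn.factor
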