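"""Deterministic simulation engines.

Three solvers share one engine loop: a fixed-step explicit Euler
(implemented here), the adaptive embedded Dormand–Prince 5(4) pair and a
stiff variable-order multistep method (both provided by scipy's integrator
steppers; the engine contract — event location, restart semantics, halting,
dense-output sampling — is implemented in this module).

Events are located by bisection on the 0→1 flip of the trigger indicator on
the continuous (dense-output) solution, to within 1e-9 time units; triggers
already true at the initial time do not fire (SBML convention).  Delayed
events enter a pending queue; simultaneous events fire in declaration
order.  Halt events (from constraints) truncate the trajectory and record
the message.  Output values come from dense interpolation, never from
forcing integration steps onto the output grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import LSODA, RK45, DenseOutput, OdeSolver

from .preprocess import CompiledSystem

__all__ = [
    "OdeSettings",
    "Trajectory",
    "SimulationError",
    "StiffnessError",
    "simulate_ode",
    "steady_state",
]

EVENT_TIME_TOL = 1e-9


class SimulationError(RuntimeError):
    pass


class StiffnessError(SimulationError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass
class OdeSettings:
    t_end: float
    t0: float = 0.0
    n_points: int = 101
    times: Optional[np.ndarray] = None  # explicit output grid overrides n_points
    abs_tol: float = 1e-9
    rel_tol: float = 1e-6
    initial_step: Optional[float] = None  # fixed step for euler
    max_step: float = np.inf
    solver: str = "dormand_prince"

    def __post_init__(self):
        if self.t_end <= self.t0:
            raise ValueError("t_end must exceed t0")
        if self.abs_tol <= 0 or self.rel_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.solver not in ("euler", "dormand_prince", "stiff_multistep"):
            raise ValueError(f"unknown solver {self.solver!r}")

    def grid(self) -> np.ndarray:
        if self.times is not None:
            return np.asarray(self.times, dtype=float)
        return np.linspace(self.t0, self.t_end, self.n_points)


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # len(times) x n_variables
    variable_ids: list = field(default_factory=list)
    event_log: list = field(default_factory=list)  # (time, event id)
    halt: Optional[tuple] = None  # (time, message)

    def column(self, vid: str) -> np.ndarray:
        return self.states[:, self.variable_ids.index(vid)]

    def final(self, vid: str) -> float:
        return float(self.column(vid)[-1])

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=self.variable_ids)
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


class _LinearDense(DenseOutput):
    def __init__(self, t_old, t, y_old, y):
        super().__init__(t_old, t)
        self.y_old = y_old
        self.slope = (y - y_old) / (t - t_old) if t != t_old else np.zeros_like(y)

    def _call_impl(self, t):
        if np.ndim(t) == 0:
            return self.y_old + self.slope * (t - self.t_old)
        return self.y_old[:, None] + self.slope[:, None] * (np.asarray(t) - self.t_old)


class _Euler:
    """Minimal fixed-step explicit Euler with the scipy stepper interface."""

    def __init__(self, fun, t0, y0, t_bound, first_step=None, **_):
        self.fun = fun
        self.t = t0
        self.y = np.asarray(y0, dtype=float)
        self.t_bound = t_bound
        self.h = first_step if first_step else (t_bound - t0) / 1000.0
        self.status = "running"
        self._t_old = t0
        self._y_old = self.y.copy()

    def step(self):
        if self.status != "running":
            return
        self._t_old = self.t
        self._y_old = self.y.copy()
        h = min(self.h, self.t_bound - self.t)
        dy = np.asarray(self.fun(self.t, self.y), dtype=float)
        self.y = self.y + h * dy
        self.t = self.t + h
        if not np.all(np.isfinite(self.y)):
            self.status = "failed"
        elif self.t >= self.t_bound - 1e-15:
            self.status = "finished"

    def dense_output(self):
        return _LinearDense(self._t_old, self.t, self._y_old, self.y)


def _make_stepper(settings: OdeSettings, fun, t0, y0, t_bound):
    if settings.solver == "euler":
        return _Euler(fun, t0, y0, t_bound, first_step=settings.initial_step)
    kwargs = dict(
        rtol=settings.rel_tol,
        atol=settings.abs_tol,
        max_step=settings.max_step,
    )
    if settings.initial_step:
        kwargs["first_step"] = settings.initial_step
    cls = RK45 if settings.solver == "dormand_prince" else LSODA
    return cls(fun, t0, np.asarray(y0, dtype=float), t_bound, **kwargs)


def simulate_ode(
    system: CompiledSystem,
    settings: OdeSettings,
    initial_env: Optional[dict] = None,
    parameters: Optional[np.ndarray] = None,
) -> Trajectory:
    """Integrate a compiled system, locating events and honoring halts."""
    if system.engine_kind != "ode":
        raise SimulationError("system was not compiled for the ode engine")
    grid = settings.grid()
    p = np.array(
        parameters
        if parameters is not None
        else (
            system.params_from_env(initial_env)
            if initial_env is not None
            else system.parameter_values
        ),
        dtype=float,
    )
    y = (
        system.state_from_env(initial_env)
        if initial_env is not None
        else system.initial_state.copy()
    )
    t = settings.t0

    def fun(tt, yy):
        dy = system.rhs(tt, yy, p)
        return dy

    def z_at(tt, yy):
        if system.algebraic_ids:
            return system.solve_algebraic(tt, yy, p)
        return ()

    def indicator_values(tt, yy):
        z = z_at(tt, yy)
        return np.array([ev.indicator(tt, yy, z, p) for ev in system.events])

    n_out = len(grid)
    out = np.empty((n_out, len(y)))
    out_idx = 0
    event_log: list = []
    halt: Optional[tuple] = None
    pending: list = []  # (fire time, event, captured (t, y) or None), FIFO per time

    prev_ind = indicator_values(t, y) if system.events else np.empty(0)

    def fill_until(t_stop, dense):
        nonlocal out_idx
        while out_idx < n_out and grid[out_idx] <= t_stop + 1e-12:
            tau = min(max(grid[out_idx], dense.t_old if dense is not None else t_stop), t_stop)
            out[out_idx] = dense(tau) if dense is not None else y
            out_idx += 1

    if grid[0] <= t + 1e-12:
        out[0] = y
        out_idx = 1

    def apply_events(fire_now, t_act, y_act):
        """Apply a batch of events at t_act in declaration order.

        Returns (y, halted).  ``fire_now`` is a list of
        (declaration index, event, captured (t,y) or None).
        """
        nonlocal p, halt
        yy = y_act.copy()
        for _, ev, captured in sorted(fire_now, key=lambda it: it[0]):
            event_log.append((t_act, ev.id))
            if ev.halt:
                halt = (t_act, ev.message)
                return yy, True
            if captured is not None:
                tc, yc = captured
                zc = z_at(tc, yc)
                values = [fn(tc, *yc, *zc, *p) for _, _, fn in ev.assignments]
            else:
                zz = z_at(t_act, yy)
                values = [fn(t_act, *yy, *zz, *p) for _, _, fn in ev.assignments]
            for (kind, idx, _), val in zip(ev.assignments, values):
                if kind == "state":
                    yy[idx] = val
                else:
                    p[idx] = val
        return yy, False

    ev_index = {ev.id: i for i, ev in enumerate(system.events)}

    while t < settings.t_end - 1e-14:
        stepper = _make_stepper(settings, fun, t, y, settings.t_end)
        restart = False
        while stepper.status == "running":
            try:
                stepper.step()
            except (FloatingPointError, ValueError) as exc:
                raise SimulationError(f"integrator failure at t={stepper.t}: {exc}") from exc
            if stepper.status == "failed":
                if settings.solver != "stiff_multistep":
                    raise StiffnessError(
                        f"step-size underflow at t={stepper.t}; the problem may be "
                        "stiff — try solver='stiff_multistep'"
                    )
                raise SimulationError(f"integration failed at t={stepper.t}")
            if not np.all(np.isfinite(stepper.y)):
                raise SimulationError(
                    f"non-finite state at t={stepper.t}: {stepper.y}"
                )
            dense = stepper.dense_output()
            t_new = stepper.t
            y_new = stepper.y.copy()

            # candidate action times: trigger flips and pending delayed events
            t_act = None
            if system.events:
                cur_ind = indicator_values(t_new, y_new)
                flips = [
                    i
                    for i in range(len(system.events))
                    if prev_ind[i] < 0.5 <= cur_ind[i]
                ]
                for i in flips:
                    tf = _bisect_flip(
                        lambda tt: indicator_values(tt, dense(tt))[i],
                        dense.t_old,
                        t_new,
                    )
                    if t_act is None or tf < t_act[0] - EVENT_TIME_TOL:
                        t_act = (tf, [i], [])
                    elif abs(tf - t_act[0]) <= EVENT_TIME_TOL:
                        t_act[1].append(i)
            due = [q for q in pending if q[0] <= t_new + 1e-14]
            if due:
                tq = min(q[0] for q in due)
                if t_act is None or tq < t_act[0] - EVENT_TIME_TOL:
                    t_act = (tq, [], [q for q in due if abs(q[0] - tq) <= EVENT_TIME_TOL])
                elif abs(tq - t_act[0]) <= EVENT_TIME_TOL:
                    t_act[2].extend(q for q in due if abs(q[0] - tq) <= EVENT_TIME_TOL)

            if t_act is None:
                fill_until(t_new, dense)
                t, y = t_new, y_new
                if system.events:
                    prev_ind = cur_ind
                continue

            ta, trig_idx, due_batch = t_act
            ta = min(ta, t_new)
            fill_until(ta, dense)
            y_at = dense(ta) if ta > dense.t_old else dense(dense.t_old)
            fire_now = []
            for i in trig_idx:
                ev = system.events[i]
                z = z_at(ta, y_at)
                d = ev.delay(ta, y_at, z, p)
                if d > 0:
                    captured = (ta, y_at.copy()) if ev.use_trigger_time_values else None
                    pending.append((ta + d, ev, captured))
                else:
                    fire_now.append((i, ev, None))
            for q in due_batch:
                pending.remove(q)
                fire_now.append((ev_index[q[1].id], q[1], q[2]))
            t, y = ta, y_at.copy()
            if fire_now:
                y, halted = apply_events(fire_now, ta, y_at)
                if halted:
                    times = np.append(grid[:out_idx], ta)
                    states = np.vstack([out[:out_idx], y[None, :]])
                    return Trajectory(
                        times=times,
                        states=states,
                        variable_ids=list(system.state_ids),
                        event_log=event_log,
                        halt=halt,
                    )
            if system.events:
                prev_ind = indicator_values(t, y)
            restart = True
            break
        if not restart:
            t = settings.t_end
    while out_idx < n_out:
        out[out_idx] = y
        out_idx += 1
    return Trajectory(
        times=grid,
        states=out,
        variable_ids=list(system.state_ids),
        event_log=event_log,
        halt=halt,
    )


def _bisect_flip(g, lo, hi, tol=EVENT_TIME_TOL):
    """Earliest time in (lo, hi] where the 0/1 indicator g becomes 1."""
    if g(lo) >= 0.5:
        return lo
    for _ in range(200):
        if hi - lo <= tol:
            break
        mid = 0.5 * (lo + hi)
        if g(mid) >= 0.5:
            hi = mid
        else:
            lo = mid
    return hi


def steady_state(
    system: CompiledSystem,
    guess: Optional[np.ndarray] = None,
    tol: float = 1e-9,
    parameters: Optional[np.ndarray] = None,
    max_iter: int = 100,
) -> np.ndarray:
    """Find a state with ``||rhs||_inf < tol`` by damped Newton iteration.

    The Jacobian is finite-difference; singular directions (conserved
    moieties) are handled by a least-squares step, which keeps the iterate
    on the stoichiometric subspace through the residual itself.  When Newton
    stalls the routine falls back to integrating towards large time.
    """
    p = system.parameter_values if parameters is None else np.asarray(parameters, float)
    x = np.array(guess if guess is not None else system.initial_state, dtype=float)
    n = len(x)
    if n == 0:
        return x

    def f(xx):
        return np.asarray(system.rhs(0.0, xx, p), dtype=float)

    for _ in range(max_iter):
        r = f(x)
        if np.max(np.abs(r)) < tol:
            return x
        jac = np.empty((n, n))
        for j in range(n):
            h = 1e-7 * max(1.0, abs(x[j]))
            xp = x.copy()
            xp[j] += h
            jac[:, j] = (f(xp) - r) / h
        step, *_ = np.linalg.lstsq(jac, -r, rcond=None)
        lam = 1.0
        base = np.max(np.abs(r))
        improved = False
        for _ in range(30):
            xn = x + lam * step
            if np.max(np.abs(f(xn))) < base:
                x = xn
                improved = True
                break
            lam *= 0.5
        if not improved:
            break

    # fall back to integrating to large time
    t_end = 100.0
    for _ in range(4):
        settings = OdeSettings(
            t_end=t_end, n_points=2, solver="stiff_multistep", rel_tol=1e-10, abs_tol=1e-12
        )
        env = system.initial_full_env()
        for i, s in enumerate(system.state_ids):
            env[s] = x[i]
        traj = simulate_ode(system, settings, initial_env=env, parameters=p)
        x = traj.states[-1].copy()
        if np.max(np.abs(f(x))) < tol:
            return x
        t_end *= 100.0
    r = f(x)
    raise ConvergenceError(
        f"steady state not found: residual {np.max(np.abs(r)):.3e} exceeds {tol:.1e}"
    )
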