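"""Parameter estimation by global stochastic optimization.

A :class:`FitProblem` binds a model to one or more experiments —
time-course or steady-state observations, exact or relative — and exposes a
weighted-least-squares objective.  Two optimizers are provided:

* :func:`fit_sres` — a (μ, λ) evolution strategy with log-normal
  self-adaptive step sizes and stochastic-ranking constraint handling
  (bound violations are the constraint penalty; with probability ``pf`` an
  infeasible pair is still compared by objective during the ranking
  bubble-sort sweeps);
* :func:`fit_pso` — global-best particle swarm optimization with velocity
  clamping and reflection at the bound box.

Relative observations (known shape, unknown scale) are matched after an
analytic per-(experiment, symbol) least-squares scale factor, so no scale
parameters enter the search space.  Simulation failures score ``+inf``.
Both optimizers keep a monotone best-so-far trace and are reproducible
under a fixed seed; objective evaluations within a generation are
independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .preprocess import CompiledSystem, compile_system, constraints_to_events
from .simulate_ode import OdeSettings, simulate_ode, steady_state

__all__ = [
    "Observation",
    "ExperimentData",
    "FitProblem",
    "FitResult",
    "SresSettings",
    "PsoSettings",
    "objective",
    "fit_sres",
    "fit_pso",
]


@dataclass
class Observation:
    symbol: str
    value: float
    time: Optional[float] = None  # None for steady-state observations
    weight: float = 1.0
    relative: bool = False
    missing: bool = False


@dataclass
class ExperimentData:
    kind: str  # "time_course" | "steady_state"
    observations: list = field(default_factory=list)
    name: str = "experiment"
    initial_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("time_course", "steady_state"):
            raise ValueError(f"unknown experiment kind {self.kind!r}")
        for o in self.observations:
            if o.weight <= 0:
                raise ValueError("observation weights must be positive")

    @classmethod
    def from_frame(cls, df, kind="time_course", name="experiment", weights=None,
                   relative=()):
        obs = []
        if kind == "time_course":
            tcol = df.columns[0]
            for col in df.columns[1:]:
                for t, val in zip(df[tcol], df[col]):
                    missing = val != val  # NaN
                    obs.append(
                        Observation(
                            symbol=col,
                            value=0.0 if missing else float(val),
                            time=float(t),
                            weight=(weights or {}).get(col, 1.0),
                            relative=col in relative,
                            missing=missing,
                        )
                    )
        else:
            for col in df.columns:
                for val in df[col]:
                    missing = val != val
                    obs.append(
                        Observation(
                            symbol=col,
                            value=0.0 if missing else float(val),
                            weight=(weights or {}).get(col, 1.0),
                            relative=col in relative,
                            missing=missing,
                        )
                    )
        return cls(kind=kind, observations=obs, name=name)

    def times(self) -> np.ndarray:
        ts = sorted({o.time for o in self.observations if o.time is not None})
        return np.array(ts, dtype=float)

    def symbols(self) -> list:
        seen = []
        for o in self.observations:
            if o.symbol not in seen:
                seen.append(o.symbol)
        return seen


@dataclass
class FitProblem:
    model: object  # MathModel
    free_parameters: list  # [(name, lower, upper)]
    experiments: list
    objective_kind: str = "weighted_sse"
    simulator_settings: dict = field(default_factory=dict)  # experiment name -> overrides

    system: CompiledSystem = None
    failure_count: int = 0

    def __post_init__(self):
        for name, lo, hi in self.free_parameters:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name!r} must be finite with lower < upper")
        model = constraints_to_events(self.model)
        self.system = compile_system(None, model, "ode")
        known = set(self.system.parameter_ids)
        for name, *_ in self.free_parameters:
            if name not in known:
                raise ValueError(f"free parameter {name!r} is not a model parameter")
        observable = set(self.system.state_ids) | set(self.system.algebraic_ids) | known
        for exp in self.experiments:
            for sym in exp.symbols():
                if sym not in observable:
                    raise ValueError(
                        f"observed symbol {sym!r} (experiment {exp.name!r}) "
                        "is not in the model"
                    )

    @property
    def bounds(self):
        lo = np.array([b[1] for b in self.free_parameters], dtype=float)
        hi = np.array([b[2] for b in self.free_parameters], dtype=float)
        return lo, hi

    def parameter_vector(self, theta) -> np.ndarray:
        p = self.system.parameter_values.copy()
        for (name, _, _), val in zip(self.free_parameters, theta):
            p[self.system.parameter_ids.index(name)] = float(val)
        return p


@dataclass
class FitResult:
    best_parameters: dict
    best_objective: float
    trace: list  # best-so-far objective per generation/iteration
    evaluation_count: int
    seed: int


def objective(problem: FitProblem, theta) -> float:
    """Weighted sum of squared residuals over all experiments.

    Relative observations are compared after the closed-form least-squares
    scale ``c = Σw·y·ŷ / Σw·ŷ²`` per (experiment, symbol).  Steady-state
    experiments are compared at the computed steady state.  Any simulation
    failure scores ``+inf`` and increments ``problem.failure_count``.
    """
    system = problem.system
    p = problem.parameter_vector(theta)
    total = 0.0
    for exp in problem.experiments:
        try:
            if exp.kind == "steady_state":
                xs = steady_state(system, parameters=p, tol=1e-8)
                env = dict(zip(system.state_ids, xs))
                env.update(dict(zip(system.parameter_ids, p)))
                sim_of = lambda o: env[o.symbol]  # noqa: E731
            else:
                times = exp.times()
                overrides = problem.simulator_settings.get(exp.name, {})
                grid = times if times[0] == 0.0 else np.concatenate([[0.0], times])
                settings = OdeSettings(
                    t_end=float(grid[-1]) if grid[-1] > 0 else 1.0,
                    times=grid,
                    solver=overrides.get("solver", "dormand_prince"),
                    rel_tol=overrides.get("rel_tol", 1e-8),
                    abs_tol=overrides.get("abs_tol", 1e-10),
                )
                init_env = None
                if exp.initial_overrides:
                    init_env = system.initial_full_env()
                    init_env.update(exp.initial_overrides)
                traj = simulate_ode(system, settings, initial_env=init_env, parameters=p)
                tindex = {t: i for i, t in enumerate(grid)}
                penv = dict(zip(system.parameter_ids, p))

                def sim_of(o, _traj=traj, _tindex=tindex, _penv=penv):
                    if o.symbol in _penv:
                        return _penv[o.symbol]
                    return float(_traj.column(o.symbol)[_tindex[o.time]])

        except Exception:
            problem.failure_count += 1
            return float("inf")
        groups: dict = {}
        for o in exp.observations:
            if o.missing:
                continue
            groups.setdefault((o.symbol, o.relative), []).append(o)
        for (symbol, relative), obs in groups.items():
            sim = np.array([sim_of(o) for o in obs])
            y = np.array([o.value for o in obs])
            w = np.array([o.weight for o in obs])
            if relative:
                denom = np.sum(w * sim * sim)
                c = np.sum(w * sim * y) / denom if denom > 0 else 0.0
                sim = c * sim
            total += float(np.sum(w * (y - sim) ** 2))
    if not np.isfinite(total):
        problem.failure_count += 1
        return float("inf")
    return total


def _violation(theta, lo, hi) -> float:
    return float(np.sum(np.maximum(lo - theta, 0) ** 2 + np.maximum(theta - hi, 0) ** 2))


def _stochastic_rank(f, phi, pf, rng):
    """Stochastic-ranking bubble sort; returns an index permutation."""
    idx = list(range(len(f)))
    n = len(idx)
    for _ in range(n):
        swapped = False
        for i in range(n - 1):
            a, b = idx[i], idx[i + 1]
            both_feasible = phi[a] == 0 and phi[b] == 0
            if both_feasible or rng.random() < pf:
                if f[a] > f[b]:
                    idx[i], idx[i + 1] = b, a
                    swapped = True
            else:
                if phi[a] > phi[b]:
                    idx[i], idx[i + 1] = b, a
                    swapped = True
        if not swapped:
            break
    return idx


@dataclass
class SresSettings:
    generations: int = 100
    lambda_: int = 105
    mu: int = 15
    pf: float = 0.45
    seed: int = 0


def fit_sres(problem: FitProblem, settings: SresSettings) -> FitResult:
    """Stochastic-ranking (μ, λ) evolution strategy over the bound box."""
    if settings.lambda_ < settings.mu:
        raise ValueError("population lambda must be at least the parent count mu")
    lo, hi = problem.bounds
    n = len(lo)
    rng = np.random.default_rng(settings.seed)
    tau = 1.0 / np.sqrt(2.0 * np.sqrt(n))
    tau_prime = 1.0 / np.sqrt(2.0 * n)

    pop = lo + rng.random((settings.lambda_, n)) * (hi - lo)
    sigma = np.tile((hi - lo) / np.sqrt(n), (settings.lambda_, 1))

    def evaluate(x):
        clipped = np.clip(x, lo, hi)
        return objective(problem, clipped), _violation(x, lo, hi)

    evals = 0
    f = np.empty(settings.lambda_)
    phi = np.empty(settings.lambda_)
    for i in range(settings.lambda_):
        f[i], phi[i] = evaluate(pop[i])
    evals += settings.lambda_

    best_x, best_f = None, np.inf
    trace = []

    def note_best():
        nonlocal best_x, best_f
        for i in range(settings.lambda_):
            if phi[i] == 0 and f[i] < best_f:
                best_f = f[i]
                best_x = np.clip(pop[i], lo, hi).copy()
        if best_x is None:  # all infeasible: fall back to least violating
            i = int(np.argmin(phi))
            best_f = f[i]
            best_x = np.clip(pop[i], lo, hi).copy()

    note_best()
    trace.append(best_f)

    for _ in range(settings.generations):
        order = _stochastic_rank(f, phi, settings.pf, rng)
        parents = order[: settings.mu]
        new_pop = np.empty_like(pop)
        new_sigma = np.empty_like(sigma)
        for k in range(settings.lambda_):
            j = parents[int(rng.integers(settings.mu))]
            g = rng.standard_normal()
            zs = rng.standard_normal(n)
            s = sigma[j] * np.exp(tau_prime * g + tau * zs)
            s = np.minimum(s, hi - lo)
            x = pop[j] + s * rng.standard_normal(n)
            new_pop[k] = x
            new_sigma[k] = s
        pop, sigma = new_pop, new_sigma
        for i in range(settings.lambda_):
            f[i], phi[i] = evaluate(pop[i])
        evals += settings.lambda_
        note_best()
        trace.append(best_f)

    names = [b[0] for b in problem.free_parameters]
    return FitResult(
        best_parameters=dict(zip(names, map(float, best_x))),
        best_objective=float(objective(problem, best_x)),
        trace=trace,
        evaluation_count=evals,
        seed=settings.seed,
    )


@dataclass
class PsoSettings:
    iterations: int = 200
    swarm_size: int = 20
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    seed: int = 0


def fit_pso(problem: FitProblem, settings: PsoSettings,
            objective_fn=None) -> FitResult:
    """Global-best PSO with velocity clamping and reflection at bounds.

    ``objective_fn(theta)`` may replace the model objective (used for
    optimizer sanity checks on analytic test functions).
    """
    if settings.swarm_size < 1:
        raise ValueError("swarm size must be positive")
    lo, hi = problem.bounds
    n = len(lo)
    rng = np.random.default_rng(settings.seed)
    span = hi - lo
    vmax = 0.5 * span
    fobj = objective_fn if objective_fn is not None else (lambda x: objective(problem, x))

    x = lo + rng.random((settings.swarm_size, n)) * span
    v = (rng.random((settings.swarm_size, n)) - 0.5) * span
    pbest = x.copy()
    pbest_f = np.array([fobj(xi) for xi in x])
    evals = settings.swarm_size
    g = int(np.argmin(pbest_f))
    gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
    trace = [gbest_f]

    for _ in range(settings.iterations):
        r1 = rng.random((settings.swarm_size, n))
        r2 = rng.random((settings.swarm_size, n))
        v = (
            settings.inertia * v
            + settings.cognitive * r1 * (pbest - x)
            + settings.social * r2 * (gbest[None, :] - x)
        )
        v = np.clip(v, -vmax, vmax)
        x = x + v
        # reflect at the bound box
        over = x > hi
        under = x < lo
        x = np.where(over, 2 * hi - x, x)
        x = np.where(under, 2 * lo - x, x)
        v = np.where(over | under, -v, v)
        x = np.clip(x, lo, hi)
        for i in range(settings.swarm_size):
            fi = fobj(x[i])
            evals += 1
            if fi < pbest_f[i]:
                pbest_f[i] = fi
                pbest[i] = x[i].copy()
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest_f = float(pbest_f[g])
            gbest = pbest[g].copy()
        trace.append(gbest_f)

    names = [b[0] for b in problem.free_parameters]
    return FitResult(
        best_parameters=dict(zip(names, map(float, gbest))),
        best_objective=gbest_f,
        trace=trace,
        evaluation_count=evals,
        seed=settings.seed,
    )
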