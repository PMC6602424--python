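"""Exact and approximate stochastic simulation.

The reaction network is interpreted as a continuous-time Markov chain over
integer copy numbers: each kinetic law, evaluated at the current state, is
the reaction's propensity (hazard).  Three methods are provided:

* :func:`simulate_direct` — Gillespie's direct method (exact);
* :func:`simulate_next_reaction` — the Gibson–Bruck next-reaction method
  (exact; reaction dependency graph plus an indexed priority queue of
  tentative firing times with rescaling on propensity change);
* :func:`simulate_tau_leap` — fixed-step Poisson tau-leaping with
  reject-and-halve handling of negative excursions.

Kinetic laws are used as propensities verbatim; no combinatorial
``k·A·(A−1)/2`` correction is applied silently — models meant for
stochastic simulation state their propensities explicitly.  Replicates draw
from independent spawned substreams of one seeded generator, so runs are
reproducible and replicates are order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .preprocess import CompiledSystem

__all__ = [
    "SsaSettings",
    "EnsembleResult",
    "PropensityError",
    "simulate_direct",
    "simulate_next_reaction",
    "simulate_tau_leap",
    "dependency_graph",
]


class PropensityError(RuntimeError):
    pass


@dataclass
class SsaSettings:
    t_end: float
    t0: float = 0.0
    n_points: int = 101
    n_replicates: int = 1
    seed: int = 0
    method: str = "direct"
    tau: Optional[float] = None

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        if self.method not in ("direct", "next_reaction", "tau_leap"):
            raise ValueError(f"unknown method {self.method!r}")

    def grid(self):
        return np.linspace(self.t0, self.t_end, self.n_points)


@dataclass
class EnsembleResult:
    times: np.ndarray
    states: np.ndarray  # (n_replicates, n_points, n_species), integer
    species_ids: list
    event_counts: np.ndarray  # (n_replicates, n_reactions)
    method: str
    seed: int
    event_times: list = field(default_factory=list)  # per replicate, firing times

    def mean(self) -> np.ndarray:
        return self.states.mean(axis=0)

    def variance(self) -> np.ndarray:
        return self.states.var(axis=0, ddof=1)

    def column_mean(self, sid: str) -> np.ndarray:
        return self.mean()[:, self.species_ids.index(sid)]

    def final(self, sid: str) -> np.ndarray:
        """Per-replicate values of a species at the last grid point."""
        return self.states[:, -1, self.species_ids.index(sid)]

    def summary_frame(self):
        import pandas as pd

        mean = self.mean()
        var = self.variance() if self.states.shape[0] > 1 else np.zeros_like(mean)
        cols = {"time": self.times}
        for i, sid in enumerate(self.species_ids):
            cols[f"{sid}_mean"] = mean[:, i]
            cols[f"{sid}_var"] = var[:, i]
        return pd.DataFrame(cols)

    def to_csv(self, path):
        self.summary_frame().to_csv(path, index=False)


def _prepare(system: CompiledSystem):
    if system.engine_kind != "stochastic":
        raise PropensityError("system was not compiled for the stochastic engine")
    n = system.stoichiometry.astype(np.int64)
    x0 = system.initial_state
    sp_idx = [system.state_ids.index(s) for s in system.species_ids]
    x0 = x0[sp_idx]
    if np.max(np.abs(x0 - np.round(x0))) > 1e-9:
        raise PropensityError("stochastic simulation needs an integer initial state")
    return n, np.round(x0).astype(np.int64)


def _propensities(system, t, x, p):
    a = np.asarray(system.propensities(t, x.astype(float), p), dtype=float)
    if np.any(a < 0):
        j = int(np.argmin(a))
        raise PropensityError(
            f"negative propensity for reaction {system.reaction_ids[j]!r} "
            f"at state {dict(zip(system.species_ids, x))}"
        )
    return a


def _record(grid, times, snapshots, x_final):
    """Sample a jump trajectory onto the grid, last value carried forward."""
    n_t = len(grid)
    out = np.empty((n_t, len(x_final)), dtype=np.int64)
    k = 0
    current = snapshots[0]
    for i, tau in enumerate(grid):
        while k < len(times) and times[k] <= tau:
            current = snapshots[k]
            k += 1
        out[i] = current
    return out


def _ensemble(system, settings, kernel):
    n, x0 = _prepare(system)
    grid = settings.grid()
    p = system.parameter_values
    streams = np.random.SeedSequence(settings.seed).spawn(settings.n_replicates)
    states = np.empty((settings.n_replicates, len(grid), len(x0)), dtype=np.int64)
    counts = np.zeros((settings.n_replicates, n.shape[1]), dtype=np.int64)
    all_times = []
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        times, snaps, cnt = kernel(system, n, x0, p, settings, rng)
        states[r] = _record(grid, times, snaps, snaps[-1])
        counts[r] = cnt
        all_times.append(np.asarray(times[1:]))
    return EnsembleResult(
        times=grid,
        states=states,
        species_ids=list(system.species_ids),
        event_counts=counts,
        method=settings.method,
        seed=settings.seed,
        event_times=all_times,
    )


# --------------------------------------------------------------------------
# Gillespie direct method
# --------------------------------------------------------------------------

def _direct_kernel(system, n, x0, p, settings, rng):
    t = settings.t0
    x = x0.copy()
    times = [t]
    snaps = [x.copy()]
    counts = np.zeros(n.shape[1], dtype=np.int64)
    while True:
        a = _propensities(system, t, x, p)
        a0 = a.sum()
        if a0 <= 0.0:
            break
        t = t + rng.exponential(1.0 / a0)
        if t > settings.t_end:
            break
        j = int(np.searchsorted(np.cumsum(a), rng.random() * a0))
        x = x + n[:, j]
        counts[j] += 1
        times.append(t)
        snaps.append(x.copy())
    return times, snaps, counts


def simulate_direct(system: CompiledSystem, settings: SsaSettings) -> EnsembleResult:
    """Statistically exact realizations via Gillespie's direct method."""
    return _ensemble(system, settings, _direct_kernel)


# --------------------------------------------------------------------------
# Gibson–Bruck next-reaction method
# --------------------------------------------------------------------------

def dependency_graph(system: CompiledSystem) -> dict:
    """Edges j -> k when firing j changes a species that propensity k reads."""
    from .expressions import free_symbols

    n_rx = len(system.reaction_ids)
    affects = []
    for j in range(n_rx):
        affects.append(
            {
                system.species_ids[i]
                for i in range(len(system.species_ids))
                if system.stoichiometry[i, j] != 0
            }
        )
    reads = []
    for j, r in enumerate(system.model.reactions):
        syms = free_symbols(r.kinetic_law) if r.kinetic_law is not None else set()
        reads.append(syms & set(system.species_ids))
    deps = {}
    for j in range(n_rx):
        deps[j] = sorted(
            k for k in range(n_rx) if k != j and (affects[j] & reads[k])
        )
    return deps


class _IndexedHeap:
    """Binary min-heap over (time, reaction) with positional index for rekeying."""

    def __init__(self, values):
        self.key = list(values)
        self.heap = sorted(range(len(values)), key=lambda i: values[i])
        self.pos = [0] * len(values)
        for slot, node in enumerate(self.heap):
            self.pos[node] = slot

    def top(self):
        node = self.heap[0]
        return self.key[node], node

    def update(self, node, new_key):
        self.key[node] = new_key
        self._sift_up(self.pos[node])
        self._sift_down(self.pos[node])

    def _swap(self, i, j):
        self.heap[i], self.heap[j] = self.heap[j], self.heap[i]
        self.pos[self.heap[i]] = i
        self.pos[self.heap[j]] = j

    def _sift_up(self, slot):
        while slot > 0:
            parent = (slot - 1) // 2
            if self.key[self.heap[slot]] < self.key[self.heap[parent]]:
                self._swap(slot, parent)
                slot = parent
            else:
                break

    def _sift_down(self, slot):
        size = len(self.heap)
        while True:
            left, right = 2 * slot + 1, 2 * slot + 2
            smallest = slot
            if left < size and self.key[self.heap[left]] < self.key[self.heap[smallest]]:
                smallest = left
            if right < size and self.key[self.heap[right]] < self.key[self.heap[smallest]]:
                smallest = right
            if smallest == slot:
                break
            self._swap(slot, smallest)
            slot = smallest


def _next_reaction_kernel(system, n, x0, p, settings, rng):
    deps = dependency_graph(system)
    t = settings.t0
    x = x0.copy()
    times = [t]
    snaps = [x.copy()]
    n_rx = n.shape[1]
    counts = np.zeros(n_rx, dtype=np.int64)
    a = _propensities(system, t, x, p)
    taus = [
        t + rng.exponential() / a[j] if a[j] > 0 else np.inf for j in range(n_rx)
    ]
    heap = _IndexedHeap(taus)
    while True:
        tau, mu = heap.top()
        if not np.isfinite(tau) or tau > settings.t_end:
            break
        t = tau
        x = x + n[:, mu]
        counts[mu] += 1
        times.append(t)
        snaps.append(x.copy())
        a_new = _propensities(system, t, x, p)
        for k in deps[mu]:
            if a_new[k] > 0:
                if a[k] > 0 and np.isfinite(heap.key[k]):
                    heap.update(k, t + (a[k] / a_new[k]) * (heap.key[k] - t))
                else:
                    heap.update(k, t + rng.exponential() / a_new[k])
            else:
                heap.update(k, np.inf)
        if a_new[mu] > 0:
            heap.update(mu, t + rng.exponential() / a_new[mu])
        else:
            heap.update(mu, np.inf)
        a = a_new
    return times, snaps, counts


def simulate_next_reaction(system: CompiledSystem, settings: SsaSettings) -> EnsembleResult:
    """Gibson–Bruck next-reaction method; distributionally identical to direct."""
    return _ensemble(system, settings, _next_reaction_kernel)


# --------------------------------------------------------------------------
# tau-leaping
# --------------------------------------------------------------------------

def _tau_leap_kernel(system, n, x0, p, settings, rng):
    if settings.tau is None or settings.tau <= 0:
        raise ValueError("tau-leaping needs tau > 0")
    t = settings.t0
    x = x0.copy()
    times = [t]
    snaps = [x.copy()]
    counts = np.zeros(n.shape[1], dtype=np.int64)
    while t < settings.t_end - 1e-14:
        a = _propensities(system, t, x, p)
        if a.sum() <= 0:
            break
        tau = min(settings.tau, settings.t_end - t)
        for _ in range(60):  # reject-and-halve on negative excursions
            k = rng.poisson(a * tau)
            x_new = x + n @ k
            if np.all(x_new >= 0):
                break
            tau *= 0.5
        else:
            x_new = np.maximum(x + n @ k, 0)
        t += tau
        x = x_new
        counts += k
        times.append(t)
        snaps.append(x.copy())
    return times, snaps, counts


def simulate_tau_leap(system: CompiledSystem, settings: SsaSettings) -> EnsembleResult:
    """Fixed-step Poisson tau-leaping; converges to the exact law as tau -> 0."""
    return _ensemble(system, settings, _tau_leap_kernel)
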