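# sbkernel

A desk-scale modelling kernel for biochemical reaction networks.  It is
aimed at systems biologists who want the computational core of a
simulation platform — executable models, standard-format I/O,
deterministic and stochastic engines, modular composition, parameter
estimation and steady-state analyses — as an ordinary Python library with
a small CLI, with every piece testable offline.

## What it does

Models are compartmentalized attributed graphs (species, reactions,
compartments, modules, ports) bound to an executable mathematical layer:
variables, parameters, reactions with symbolic kinetic laws,
assignment/rate/algebraic rules, discrete events and constraints.  On top
of that:

* **I/O** — an SBML Level-3-core subset (content MathML kinetic laws) and
  a human-readable text format (`docs/format.md`), both with exact
  round-trip guarantees; delimited time-course/steady-state tables.
* **Preprocessors** — modular-model flattening, constraints → halting
  events, fast (rapid-equilibrium) reactions → algebraic relations plus
  conserved-pool ODEs, boolean → 0/1 numeric encoding, and compilation to
  in-memory callables with the right-hand side `dx/dt = N·v(x, t)`.
* **Deterministic engines** — fixed-step Euler, adaptive Dormand–Prince
  5(4) and a stiff multistep method, all with event location by bisection
  on the dense solution, delayed events, and constraint halting.
* **Stochastic engines** — Gillespie's direct method, the Gibson–Bruck
  next-reaction method (dependency graph + indexed priority queue) and
  fixed-step tau-leaping, with per-replicate seeded substreams.
* **Modular models** — flattening with connection resolution, or
  agent-based co-simulation where each module runs its own solver and a
  scheduler exchanges connected values at fixed time boundaries.
* **Parameter estimation** — a stochastic-ranking (μ, λ) evolution
  strategy and global-best particle swarm optimization over bound boxes,
  multi-experiment objectives with exact or relative observations.
* **Analyses** — stoichiometric relations, exact conservation/link-matrix
  decomposition `N = L·N_R`, steady-state sensitivities
  `∂x*/∂p = −L·J_R⁻¹·N_R·∂v/∂p`, and metabolic control analysis with the
  summation theorems (`ΣC^J = 1`, `ΣC^S = 0`) checked before reporting.

See `docs/methods.md` for the numerical methods and design choices.

## Worked example

The bundled two-step pathway (`v1 = k1·(S0 − S)`, `v2 = k2·S` with
`k1 = k2 = 1`, `S0 = 2`) relaxes to the steady state
`S* = k1·S0/(k1+k2)`:

```python
import sbkernel as sk

diagram, model = sk.canonical("two_step_pathway")
system = sk.compile_system(diagram, model, "ode")
traj = sk.simulate_ode(system, sk.OdeSettings(t_end=5.0, n_points=6,
                                              rel_tol=1e-8, abs_tol=1e-12))
print(traj.to_frame().to_string(index=False))
```

```
 time        S
  0.0 0.000000
  1.0 0.864665
  2.0 0.981684
  3.0 0.997521
  4.0 0.999665
  5.0 0.999955
```

`S` approaches 1.0 = 1·2/(1+1).  Doubling the first rate constant and
running metabolic control analysis:

```python
model.parameter("k1").value = 2.0
report = sk.mca(model)
print(report.steady_state)   # {'S': 1.3333333335417086}
print(report.flux_control)   # [[0.333333 0.666667]
                             #  [0.333333 0.666667]]
```

The steady state moves to `2·2/(2+1) = 4/3`, and the flux control
coefficients are `(k2, k1)/(k1+k2) = (1/3, 2/3)`: the slower second step
holds twice the control over the pathway flux, and each row sums to 1 as
the summation theorem requires.

The same models are reachable from the shell:

```sh
sbkernel fixtures export decay --format sbml --out decay.xml
sbkernel simulate --model decay.xml --t-end 1 --solver dormand_prince
sbkernel analyze --model decay.xml --what conservation
```

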