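# Methods

## The model representation

A model is a pair of coupled layers.  The *diagram* is a compartmentalized
attributed graph: species, reaction, compartment, module, port and
annotation nodes joined by reactant/product/modifier/connection edges, with
compartment nesting restricted to a forest.  The *mathematical model* is
the executable layer: variables (with dynamics `ode`, `assigned`,
`algebraic` or `constant-boundary`), parameters, reactions with symbolic
kinetic laws, assignment/rate/algebraic rules, discrete events (trigger,
optional delay, assignments), and constraints.  Database cross-references
are deliberately reduced to free-form annotation strings; no external
resource is contacted.  All expressions are sympy trees over a fixed
operator core (arithmetic, `exp`/`ln`/`log10`, `min`/`max`/`abs`,
piecewise, comparisons, boolean connectives); anything outside the core is
an import error, never a silent drop.

The canonical state is **amount**.  Species initialized by concentration
are converted to amounts with the (constant) compartment size when the
document is loaded; since compartment sizes never change within the
supported subset this is equivalent to converting at compile time, and it
lets the deterministic and stochastic engines share one state layout.
Units are carried as labels and never converted.

## Preprocessing pipeline

Simulation engines consume a `CompiledSystem` produced by a pipeline of
source-to-source transforms followed by compilation to in-memory callables
(closures generated through `sympy.lambdify`, not external source code):

* **Flattening** namespaces every module symbol as `module__symbol`,
  merges each undirected connection into the master endpoint's variable
  (the master's initial value wins; merging two differential variables
  without a master designation is an error, not a guess), and rewrites
  directed consumers to `factor * producer`.  Collisions are errors, never
  silent renames.
* **Constraints** become halting events triggered by the negated
  condition, carrying the constraint message.
* **Fast reactions** (reversible mass action only, the case with a closed
  algebraic form) are removed and replaced by an equilibrium relation
  `kf·∏reactants − kr·∏products = 0` per reaction plus one new
  differential pool variable per conserved moiety of the fast subnetwork,
  whose rate collects the slow-reaction flux into the pool.  The touched
  species become algebraic unknowns, solved by a damped Newton inner loop
  (finite-difference Jacobian, warm-started from the previous solution) at
  each right-hand-side evaluation.
* **Boolean triggers** are encoded as 0/1 numerics: comparisons become
  indicator piecewises, conjunction a product, disjunction a saturating
  sum `min(1, Σ)`, negation `1 − x`.  The encoding agrees with the boolean
  form on every environment (property-tested on randomized expressions).

For a pure reaction network the emitted right-hand side is exactly `N·v`;
rate rules add their terms, and event-driven parameters are promoted into
the state vector with zero derivative.  Layouts follow declaration order,
so compilation is deterministic.

## Deterministic simulation

Three solvers share one engine loop: fixed-step explicit Euler (in-repo),
the Dormand–Prince 5(4) embedded pair and a stiff variable-order multistep
method, the latter two delegated to scipy's `RK45` and `LSODA` stepper
objects — the engine contract (event location, restart semantics, halting,
dense-output sampling) is this package's own, the Butcher tableaux are
not re-derived.  Euler's fixed step is `initial_step` (default
`(t_end−t0)/1000`).  Dormand–Prince runs adaptively only; there is no
fixed-step mode.

Events are located by bisecting the 0→1 flip of the trigger indicator on
the dense-output solution to within 1e-9 time units.  Triggers already
true at `t0` do not fire (the SBML convention); delayed events enter a
pending queue, capturing assignment-time values when
`use_trigger_time_values` is set, and overlapping delayed firings are
processed in fire-time order.  Simultaneous events fire in declaration
order.  Halting events truncate the trajectory and record `(time,
message)`.  Output values always come from dense interpolation — the
integrator's step sequence is never distorted by the output grid.

Steady states are found by damped Newton with a finite-difference Jacobian
and least-squares steps (so conserved-moiety null directions do not break
the iteration), falling back to integration towards large time when Newton
stalls.

## Stochastic simulation

Kinetic laws are reinterpreted verbatim as propensities of a continuous
time Markov chain over integer copy numbers; no combinatorial correction
(`k·A·(A−1)/2` versus `k·A²`) is applied silently — models intended for
stochastic simulation state their propensities explicitly.  The direct
method draws exponential waiting times and categorical reaction indices;
the next-reaction method keeps absolute tentative firing times in an
indexed binary heap, updates only reactions whose propensities a firing
can change (a dependency graph built from which species each propensity
reads), rescales pending times by the propensity ratio, and draws fresh
exponentials only when a propensity rises from zero — per step cost
O(log R + degree).  Fixed-step tau-leaping draws Poisson increments and
rejects-and-halves the step when a species would go negative; it is the
representative approximation method.  Replicates use independent spawned
substreams of one seeded generator, so ensembles are bit-reproducible and
replicate order is immaterial.  Grid sampling is last-value-carried-forward.

## Modular co-simulation

The scheduler advances time in fixed exchange windows `h_ex`.  Within a
window each module integrates independently with incoming connected values
held constant (zero-order hold).  At window boundaries directed consumers
are refreshed from their producers (times the conversion factor);
undirected connections use *delta-exchange* reconciliation: the increments
the non-master modules made to their copies during the window are added to
the master's value and all copies reset to the result.  This makes the
scheme first-order accurate in `h_ex` — halving the exchange step roughly
halves the deviation from the flattened model, which the tests check at
three step sizes.  Grid points inside a window take the owning module's
own dense solution.  Module update order is the topological order of
directed connections with name order breaking ties, so runs are
deterministic.

## Parameter estimation

The objective is the raw weighted sum of squared residuals over all
experiments (no per-experiment normalization; experiments of different
sizes weigh in proportion to their observation count, which the weights
can override).  Relative observations are matched after an analytic
least-squares scale `c = Σw·y·ŷ / Σw·ŷ²` per (experiment, symbol), so no
scale parameters enlarge the search space.  Steady-state experiments are
compared at the computed steady state.  A failed simulation scores `+inf`.

SRES is a (μ, λ) evolution strategy with log-normal self-adaptive step
sizes (learning rates `τ = 1/√(2√n)`, `τ′ = 1/√(2n)`), bound violations as
the constraint penalty, and stochastic-ranking bubble sort: when comparing
an infeasible pair, rank by objective with probability `pf`.  Defaults
λ=105, μ=15, pf=0.45 (λ=7μ literature defaults; the tests use smaller
populations sized to their problems).  PSO is global-best with inertia
0.72 and cognitive/social weights 1.49, velocity clamped to half the box
width and positions reflected at the bounds.  Both optimizers track a
monotone best-so-far trace and are deterministic under a fixed seed;
objective evaluations within a generation are independent, so they may be
evaluated in any order.

## Structural and steady-state analyses

Stoichiometric structure is handled in exact rational arithmetic:
independent rows of `N` are the pivot rows of `Nᵀ`'s reduced row-echelon
form, the link matrix solves `N = L·N_R` exactly, and conservation vectors
are an integer-scaled basis of `Nᵀ`'s null space — exactness is what lets
the cross-module tests demand `mᵀx(t)` constant to 1e-6 along simulated
trajectories.  Constant-boundary species are excluded from `N` (their
derivative is identically zero).

Steady-state sensitivities use the implicit-function relation on the
reduced system, `∂x*/∂p = −L·(N_R E L)⁻¹·N_R·∂v/∂p`, with central
finite differences (step `max(1e-6, 1e-6·|value|)`) for the rate
derivatives.  Metabolic control analysis computes unscaled coefficients
`C_S = −L·J_R⁻¹·N_R` and `C_J = I + E·C_S`, scales them by fluxes and
concentrations, and asserts the summation theorems (`ΣC^J = 1`,
`ΣC^S = 0`, tolerance 1e-6) before returning; zero-flux reactions are a
hard error since scaled coefficients are then undefined.

## Test fixtures

The canonical catalogue (decay, logistic, two-step pathway, mass-action
enzyme mechanism, the classic stiff three-reaction autocatalytic benchmark,
dimerization, immigration–death, a two-module decay chain, event,
constraint and rapid-equilibrium demos) lives in one human-readable
document (`src/sbkernel/data/catalog.txt`) in the text format; the
fixtures module parses it through the ordinary reader, so the document is
the single source of truth.  Parameter values are the closed-form-friendly
unit rates used throughout the tests.

`random_mass_action` draws connected networks with stoichiometries in
{1, 2} and log-uniform rate constants in [0.1, 10]; kinetic laws are plain
mass action, so states stay nonnegative, and the total product
stoichiometry of each reaction never exceeds the reactant side, keeping
total mass non-increasing and trajectories bounded (an unbounded random
fixture tests nothing but overflow handling).  The `open_network` flag
appends a constant inflow and a linear outflow, which typically produces
the positive-flux steady states the control-analysis property tests need.

What the synthetic fixtures do *not* emulate: cellular-scale model sizes
(hundreds of species), heterogeneous real time-course data (irregular
sampling, systematic error, missingness patterns), or cross-compartment
transport with changing volumes.  Passing tests demonstrate correctness of
the numerics and transforms on well-posed small networks, not robustness
to the pathologies of real experimental datasets.

## Problem sizes and numerical choices

Stochastic checks use 2000 replicates against analytic means (3 standard
errors) and 5000 replicates for cross-method moment comparisons; the
noisy-recovery study uses 20 repetitions of a 13-point, 1%-noise decay
time course.  Event times are located to 1e-9; algebraic blocks are solved
to 1e-12 residual; structural decompositions are exact.  Ties between
simultaneous events are broken by declaration order, and degenerate inputs
(empty networks, zero propensities, zero generations/iterations) return
well-defined results exercised by the tests.

## Known limitations

No delay differential equations, no PDEs, no general DAE index reduction
beyond the rapid-equilibrium form, no hybrid ODE/SSA partitioning, no
adaptive tau selection, no identifiability analysis or confidence
intervals.  The SBML subset excludes all extension packages; hierarchical
composition is expressed only in the text format.  Events are not handled
by the stochastic engines.
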