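# Text model format reference

A line-oriented reaction-and-equation language.  Comments start with `#` or
`//`; blank lines are ignored.  Every statement lives on one line.

## Flat models

```
model decay                     # optional model name

compartment cell = 1            # compartment with size
species A = 10 in cell          # species with initial amount, optional compartment
species $B = 5                  # $ prefix: boundary/constant species
const k1 = 0.5                  # parameter (param is a synonym)
A = 10                          # bare assignment: species initial if A is a
                                # species, otherwise a parameter

J1: A + 2 B -> C; k1*A*B        # reaction: name, sides, semicolon, kinetic law
J2: A <-> C; kf*A - kr*C        # <-> marks a reversible reaction
fast J3: C <-> D; kf*C - kr*D   # fast (rapid-equilibrium) reaction
Jin:  -> A; v0                  # empty side = source/sink

rate x = x*(1 - x)              # rate rule  dx/dt = ...
assign y = 2*x                  # assignment rule
algebraic 0 = A*kf - B*kr       # algebraic rule (residual = 0)

at (A < 0.5): y = 1, z = 2      # event: trigger, comma-separated assignments
at (A < 0.5) delay 1.5: y = 1   # delayed event
at (A < 0.5): halt "message"    # halting event
constraint (x < 5): "message"   # constraint (violation halts simulation)
```

Species are recognized from `species` declarations, reaction sides, and
rule targets; all other assigned names are parameters.  Species that appear
in a kinetic law without being a reactant or product of that reaction are
recorded as modifiers.

Expression grammar: `+ - * / ^` (or `**`), `exp`, `ln`, `log10`, `sqrt`,
`min`, `max`, `abs`, `floor`, `ceil`, `piecewise(v1, c1, ..., default)`,
comparisons `< <= > >= == !=`, boolean `& | ~`, numeric literals and
symbols.

## Modular models

```
module M1
  species A = 1
  const k1 = 1
  J1: A -> B; k1*A
end
module M2
  species B = 0
  const k2 = 1
  J2: B -> C; k2*B
end
connect M1.B = M2.B master M1.B   # undirected: merge into one quantity;
                                  # master supplies the initial value
connect M1.A -> M2.inp factor 2   # directed: producer -> consumer(s)
engine M1 ode                     # per-module engine for co-simulation
```

## SBML subset

The SBML side of the I/O layer covers Level 3 core: compartments, species
(amounts or concentrations; concentrations are converted to amounts at load
using the compartment size), parameters, reactions with content-MathML-core
kinetic laws, assignment/rate/algebraic rules, events (with delays),
constraints and initial assignments (folded into initial values at load).
Extension packages (`comp`, `fbc`, ...), `factorial`, and MathML `delay`
are rejected with an error naming each offending element.  Hierarchical
models are expressed only in the text format.  A document whose only
compartment is `default` with size 1 is treated as having an implicit
compartment, so text-format models round-trip through SBML unchanged.

## Observation tables

Comma-separated (tab auto-detected), decimal point only.  Time-course
tables have time in the first column and one observed symbol per remaining
column; blank cells are retained and marked missing.  Steady-state tables
have no time column and are read with `steady_state=True`.
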