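# Canonical model catalogue.
# Each "== name ==" section is a complete model in the bundled text format;
# fixtures.canonical(name) parses the section through model_io.read_text.
# This file is the single source of truth for the catalogue models.

== decay ==
model decay
species A = 1
const k = 1
J1: A -> ; k*A

== logistic ==
model logistic
species x = 0.5
rate x = x*(1 - x)

== two_step_pathway ==
model two_step_pathway
species S = 0
const k1 = 1
const k2 = 1
const S0 = 2
v1:  -> S; k1*(S0 - S)
v2: S -> ; k2*S

== enzyme_mm ==
model enzyme_mm
species E = 1
species S = 10
species ES = 0
species P = 0
const k1 = 1
const k2 = 1
const k3 = 1
binding: E + S -> ES; k1*E*S
unbinding: ES -> E + S; k2*ES
catalysis: ES -> E + P; k3*ES

== robertson ==
model robertson
species A = 1
species B = 0
species C = 0
const p1 = 0.04
const p2 = 30000000
const p3 = 10000
J1: A -> B; p1*A
J2: 2 B -> B + C; p2*B*B
J3: B + C -> A + C; p3*B*C

== dimerization ==
model dimerization
species A = 200
species B = 0
const c = 0.01
J1: 2 A -> B; c*A*(A - 1)/2

== immigration_death ==
model immigration_death
species X = 0
const lam = 10
const mu = 1
birth:  -> X; lam
death: X -> ; mu*X

== decay_chain_modular ==
model decay_chain_modular
module M1
  species A = 1
  species B = 0
  const k1 = 1
  J1: A -> B; k1*A
end
module M2
  species B = 0
  species C = 0
  const k2 = 1
  J2: B -> C; k2*B
end
connect M1.B = M2.B master M1.B

== event_demo ==
model event_demo
species A = 1
const k = 1
const y = 0
J1: A -> ; k*A
at (A < 0.5): y = 1

== constraint_demo ==
model constraint_demo
species x = 0
rate x = 1
constraint (x < 5): "x exceeded 5"

== fast_equilibrium_demo ==
model fast_equilibrium_demo
species A = 1
species B = 0
const kf = 2
const kr = 1
const v0 = 1
feed:  -> A; v0
fast Jeq: A <-> B; kf*A - kr*B
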