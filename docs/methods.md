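# Methods

## Model

A program is a finite set of context-free stochastic rewrite rules, at most
one per species:

```
A --r--> {S1}_p1 | {S2}_p2 | ... | {Sn}_pn
```

Individuals of `A` fire independently at per-capita rate `r` (units:
events per individual per time unit); a firing replaces the individual with
one outcome group `S_i` (0, 1 or 2 products; the empty group is death),
chosen with probability `p_i`, `sum p_i = 1`.  The `ow` sentinel in program
files stands for one minus the sum of the other probabilities and is
resolved at validation.  Rules are context-free — individuals never interact
directly — but `r` and `p_i` may be functions of the *global* state
(population sizes, elapsed time), which is how predator–prey style coupling
is expressed without pairwise interaction terms.

For simulation each rule is translated into `n` reaction channels with rates
`c_i = r * p_i`; the propensity of a channel is `c_i` times the current
population of its left-hand species.  Events are sampled with the Gillespie
Direct Method: waiting time `tau = ln(1/u1) / a0` and channel `j` = smallest
index whose cumulative propensity exceeds `u2 * a0`, with `a0` the total
propensity.  This is exact for the underlying continuous-time Markov chain;
no tau-leaping or other approximation is used.

Because individuals of a species are exchangeable under mass-action
kinetics, the firing individual is chosen uniformly among the living members
of the left-hand species.  Products are always *new* lineage nodes, even
when a species reproduces itself: the parent node is closed (cause
`division`, or `death` for the empty group) and children open at the event
time.  This keeps the recorded history a strict forest — one tree per
initial individual — whose edges satisfy `child.birth_time ==
parent.end_time` by construction.

## Internal states and inheritance

A species may declare named internal states, each with an initial value, an
updating function and a duplication number `dup` (independent instances per
individual; e.g. a vector of microsatellite loci).  Values are assigned when
a node is created and are constant over its life; the updater acts at
inheritance.  When a rule firing creates a child:

* a state defined on the child and present on the parent is set to
  `updater(parent value)`, independently per child and per instance;
* a state defined on the child but absent on the parent starts at its
  declared initial value (this is how a generation counter resets to 1 at a
  differentiation event);
* parental states not declared on the child's species are dropped.

Built-in updaters: `ms_step` (symmetric single-step microsatellite model:
±1 repeat with probability p/2 each, default p = 0.01 per locus per
division — a small, plausible somatic mutation rate; repeat counts are
stored as reals but stay integer-valued, initial value 30 repeats),
`gen_increment` (exact +1), `stochastic_counter` (adds a Normal(1, 0.1)
draw), `identity`.  Custom callables register under fresh names; built-in
names are immutable.  In program files a `FuncName` that is not a bare
identifier is compiled as a safe expression over `x` (see below).

## Conditional transitions

After every event, living individuals of species with conditional
transitions are examined once; an individual whose condition (a boolean
expression over its internal states) holds is transformed into the target
species — its node closes with cause `transform` and a single child of the
target opens at the same time — or, for the termination target, closes as
`death`.  Shared states carry over unchanged, states new to the target
start at their initial values, others are dropped; the carried counter is
what lets a death threshold act on a value accumulated in a previous
species.  Transform children created during a sweep are not re-examined
until the next event, which bounds the work per event and makes the sweep
deterministic (individuals are visited in node-id order; conditionals of a
species apply in program order, first match wins).

Since state values are constant over a node's life, a condition that does
not call `pop()`, `time()` or `normrnd()` has a fixed outcome per node, and
the sweep examines only nodes created since the previous event; this is an
exact optimization, not a semantic change (verified against the full sweep
in the tests).  Conditions using those functions fall back to the full
per-event sweep.

## Global updating functions

A registered global updater maps `(populations, time, constants)` to new
`(rate, probabilities)` per rule; outputs are re-validated (rate finite and
non-negative, probabilities summing to 1 within 1e-9) and channels rebuilt,
restoring `sum_i c_i = r` exactly.  The built-in `lotka_volterra` updater
implements

```
r1 = c1 + c2*|Predator|   p1 = c1 / r1          (Prey divides, else dies)
r2 = c2*|Prey| + c3       p2 = c2*|Prey| / r2   (Predator divides, else dies)
```

whose channel decomposition `r1*p1 = c1`, `r1*(1-p1) = c2*|Predator|`
recovers the mass-action birth/death reactions of the classical ODEs.
Defaults `c1 = c3 = 10`, `c2 = 0.01` put the stochastic equilibrium at
1000/1000, close to the bundled 900/900 start, so oscillation is visible
within the 10-unit span.

Program files carry arbitrary placeholder rates/probabilities that the
updater overwrites.  By default the updater runs once at t = 0, so the first
event is already sampled under environment-consistent parameters; the
`legacy_first_update` flag instead keeps the placeholders until after the
first execution, reproducing the behavior of tools that update only on
event execution.  The updater also runs after every event (after the
conditional sweep), so parameter changes driven by conditional transforms
take effect immediately.

## Randomness and reproducibility

One PCG64 stream per run, seeded by the run seed.  Consumption order per
event is fixed: `u1` (waiting time), `u2` (channel), one draw selecting the
firing individual, then state-updater draws in (child x state x dup) order;
conditional-sweep draws (only for conditions calling `normrnd`) follow.
Identical `(program, seed, t_span)` therefore reproduces a bit-identical
history across processes.  Batch runs are independent per seed; duplicate
seeds are allowed with a warning and produce identical runs.

## Spans, censoring, degenerate inputs

The tentative event whose time would exceed the span is discarded; clocks
stop at the span and living nodes are censored there (cause `censored`,
counted as alive through the censoring time).  When total propensity
reaches zero the run ends with reason `extinction` (remaining inert
individuals are censored at the span).  An optional `max_events` cap guards
against runaway growth (e.g. prey released from predation grow at
per-capita rate `c1 = 10`); a capped run is censored at the cap time with
reason `event-cap`.  Species with rate 0 or probability-0 outcomes are
legal: their channels have zero propensity and never fire, which is how
pure sink species (arrested cells) are declared.  Probability bookkeeping
uses absolute tolerance 1e-12 at validation and 1e-9 for updater outputs.

## Program files and the expression dialect

Programs are XML (`fixtures/program.xsd` is the reference schema): execution
parameters, an optional global-updater name, and one `Rule` element per
species with products, probabilities, internal states and conditional
transitions.  Identifiers are case-sensitive; whitespace is insignificant.
Conditions and inline updaters are compiled against a whitelisted expression
dialect (arithmetic, comparisons, boolean logic, `abs/min/max/floor/ceil/
exp/log/sqrt`, `normrnd(mu, sigma)`, `pop("Species")`, `time()`); program
files can therefore never execute arbitrary code.  Global updaters are
deliberately *not* expressible in XML — they are registered Python
callables — since they return structured per-rule output.

## Lineage export

Newick export writes one tree per root (or one merged tree under a
zero-length pseudo-root, excluded from all statistics), labels
`<species>_<node_id>` with a `_dead` suffix on death leaves, branch length
= node lifetime.  Lengths are printed with 12 significant digits so that an
independent parser recovers them to 1e-9 for spans up to ~1000 time units.
`living_only` prunes subtrees without living descendants and collapses
unary chains, summing lengths and keeping the surviving child's label.
Internal-state tables are tab-separated with one row per node per dup
instance; because values are fixed at creation, birth and end values
coincide and both columns are emitted for uniformity.

## Bundled programs and what they do (not) show

The four bundled programs are the package's synthetic test-beds; their
defaults are fixed once:

* `lotka_volterra` — 900 prey + 900 predators, 10 units (printed
  configuration); constants as above.  Exhibits anti-phase oscillation and
  the lineage bottleneck (most sub-lineages extinct through troughs).
* `stem_cell_ms` — rates/probabilities 0.1, 50/50; 1, 49/51 as printed;
  5 microsatellite loci at 30 repeats, p = 0.01; generation counter on
  differentiated cells.  Initial populations and span are not printed
  anywhere, so 50 SC / 0 Diff over 10 units were chosen to give
  hundreds of events per run at desk scale.
* `conditional_toy` — counter thresholds 5 (transform) and 10 (death),
  Normal(1, 0.1) increments as printed; 1 SCASym + 1 SCSym over 100 units
  (the 0.1 division rate needs ~50 units for a counter born at 0 to cross
  5).
* `clone_expansion` — an *analog* of repeated clonal expansion: a
  generation counter arrests cells past generation 10 (clone size caps near
  2^10 ≈ 1000) and a rare (p = 0.002) `Founder` outcome restarts the
  counter, seeding fresh clones.  A global population cap cannot arrest one
  clone while another grows (global updaters see totals only), so the
  per-individual counter is the honest mechanism at this scale.  It
  reproduces the grow/arrest/re-seed phenomenology, not any particular
  experiment.

These programs emulate well-mixed, non-interacting populations with
environment-mediated coupling only.  Passing tests therefore say nothing
about spatial structure, direct cell–cell interaction, or rate laws outside
mass action; they do validate the sampler (exponential waiting times,
Kolmogorov–Smirnov), branching-process means (Yule growth `N0*e^{lt}`,
critical flatness, subcritical decay `e^{-0.02 t}` implied by the 0.49/0.51
split at rate 1), parameter recovery from recorded histories, and the
structural contracts of the forest.

## Verification sizes

Stochastic checks use fixed seeds and 3-standard-error bands (99% chi-square
band for standard deviations): ≥20,000 firings per rule for outcome
probabilities and per-capita rates, ≥10,000 counter increments, 200–500
replicate runs for the branching-process means, 10,000 draws for the KS
test.  One full predator–prey run (~400k events) is computed once per test
session and shared.

## Limitations

No direct individual interactions (by design of the formalism); outcome
groups are capped at two products; no tau-leaping, so stiff or explosive
parameter regimes are slow; per-clone control must be encoded through
internal states, as global updaters see only totals; MATLAB-style session
persistence and interactive tree browsing are out of scope (archives and
static plots replace them).
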