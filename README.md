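# estg

Stochastic simulation of rule-based population dynamics with **complete
lineage-tree recording**.

`estg` executes programs written as environment-dependent stochastic tree
grammars: context-free rewrite rules, one per species, of the form

```
A --r--> {S1}_p1 | {S2}_p2 | ... | {Sn}_pn ,      sum_i p_i = 1
```

where species `A` fires at rate `r` and rewrites into one outcome group
`S_i` (zero, one or two product species; the empty group means death),
chosen with probability `p_i`.  Rates and probabilities may be rewritten
after every event by a *global updating function* of the system state
(population sizes, elapsed time), and every individual can carry *internal
states* — per-individual numeric values (a microsatellite repeat vector, a
generation counter, a stochastic clock) updated by named functions at each
inheritance and optionally driving *conditional transitions* that transform
or kill an individual when a condition on its states holds.

Execution is exact: each rule is translated into `n` reaction channels with
rates `c_i = r * p_i`, channel propensities are `c_i * |A|`, and event times
and identities are sampled with the Gillespie Direct Method.  Unlike plain
population-level simulators, the engine records the **full execution
history**: every individual ever alive becomes a node of a lineage forest
with birth/end times, end cause (division, death, transform, censored),
parent/child links and internal-state values — extinct lineages included.
That makes the tool useful for developmental modeling, *in silico*
evaluation of phylogenetic reconstruction from somatic mutations, and any
question about the history behind a final population, not just its size.

Intended users: systems/computational biologists who want a small, scriptable
simulator whose outputs are trees and tables rather than only time series.

## Quick start

```python
import estg
from estg.cli import fixture_path

program = estg.validate_program(
    estg.parse_program(fixture_path("stem_cell_ms").read_text())
)
runs = estg.run_batch(program, seeds=range(1, 11))

from estg.stats import rule_execution_histogram, clone_size_histogram
hist = rule_execution_histogram(runs)
print(dict(zip(hist.labels, hist.counts)))
```

The `stem_cell_ms` program models stem-cell differentiation: `SC` divides
symmetrically at rate 0.1, self-renewing or differentiating with equal
probability; `Diff` proliferates (49%) or dies (51%) at rate 1.  Each cell
carries a 5-locus microsatellite vector (symmetric one-step mutation,
change probability 0.01 per locus per division) and differentiated cells a
generation counter.  Output of the snippet above (10 seeds, 10 time units,
50 founders each):

```
rule firings: {'SC': 530, 'Diff': 2850}
seed 1: 242 events, final populations: {'SC': 56, 'Diff': 34}
```

`Diff` fires ~5x more often than `SC` on comparable populations, as the
10:1 rate ratio times the shorter differentiated-cell lifetime dictates.
Clone-size statistics over the same runs (percentage of founders with a
given number of living descendants at the end of the span):

```
clone sizes: {0: 14.8%, 1: 44.6%, 2: 17.4%, 3: 7.8%, 4: 3.6%, ...}
```

and each founder's full history exports as a Newick tree with branch
lengths equal to waiting times:

```
(((SC_289:0.985417580913,SC_290:0.985417580913)SC_265:0.684090206748,S...
```

## Command line

```
estg fixtures                                    # bundled example programs
estg run lotka_volterra --seeds 1,2 --out arch/  # simulate + archive history
estg stats arch/ --which clones --out tables/    # histograms & averages
estg export-newick arch/ --merge --out trees/    # (re-)export trees
```

Bundled programs: `lotka_volterra` (900 prey + 900 predators over 10 time
units, rates/probabilities rewritten from both population sizes after every
event), `stem_cell_ms` (above), `conditional_toy` (stochastic-counter-driven
transform and death thresholds), `clone_expansion` (clones grow to ~1000
cells, arrest, and rare founder cells re-seed fresh clones).

Archives are plain text (TSV event logs, node tables, population series,
Newick trees, JSON manifest); reloading one reproduces every statistic
bit-identically without re-simulation, and rerunning with the same seeds
rewrites byte-identical files.

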