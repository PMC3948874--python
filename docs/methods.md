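# Methods

## The simulated system

`aposim` models a closed predator–prey world on a toroidal grid of cells
(default 251×251). Three prey morph classes — non-poisonous, poisonous, and
mimic — forage on separate resource layers; each layer regrows linearly at
`inflow_rate` (default 0.01 units/cell/update) to `max_per_cell` (default 1
unit), and a prey's `eat` instruction harvests up to one unit of its own
class's resource from its current cell. The displayed class of every prey is
visible to others; only mimics can make it differ from their true class.

Behaviour is encoded in a linear genome over a closed set of 22 opcodes:
eight modifier no-ops (`nop-A`…`nop-H`), `turn-left`/`turn-right`, `move`,
`sense-food`, `sense-class`, `eat`, `attack`, `set-display`,
`if-less`/`if-greater`, `add`/`sub`/`swap`, `reproduce`. The instruction
pointer wraps; the scheduler grants each organism exactly `exec_budget` (30)
instructions per update, in a freshly shuffled organism order, so
nonterminating programs are harmless. `attack` and `set-display` read their
argument from the following instruction in the genome: attack targeting
follows the nine-sequence table (generalist; `nop-A/E` → non-poisonous only;
`nop-B/F` → mimic only; `nop-C/G` → generalist; `nop-D/H` → poisonous only),
and display requests map the same way, with any non-modifier follower
reverting the mimic to honesty. This instruction set is a deliberate
simplification of a full self-replicating digital-organism architecture: it
preserves the evolvable repertoire that matters here (finding food, killing
selectively, dishonest display) while keeping the chance discovery of
`attack`+`nop` and `set-display`+`nop` sequences probable in runs of
modest length.

Founding organisms ("ancestors", one prey per class, genome length 100) are
random foragers built from movement, eating, sensing and reproduction
opcodes only — no attack, no display change. Offspring genomes pass through
three independent mutation events: a single uniform substitution with
probability 0.25 (the replacement may silently equal the original), a single
insertion with probability 0.05, and a single deletion with probability 0.05
(skipped at length 1; insertion is skipped at the 400-instruction ceiling,
which balanced insertion/deletion rates never approach).

## Interaction rules

An attack resolves in a fixed order: (1) while total prey abundance is below
the prey floor (default 900) every attack is blocked — the floor itself
permits attacks; (2) the target is the first prey in the attacker's faced
cell (cells may hold several organisms; the occupancy list is
last-in-first-out); (3) the attacker perceives the target's displayed class
with probability `fidelity` and its true class otherwise — for honest prey
the two coincide; a perceived class outside the attack's target set fails
the attack; (4) the kill removes the victim. A poisonous victim costs the
attacker `poison_level × victim.stored` resources (floored at zero, no
gain); any other victim yields `conversion_efficiency × victim.stored`
(default 0.25). The first kill permanently converts the attacker into a
predator: it leaves its prey class (and that class's counts), its offspring
are predators outside the three prey classes, and it no longer eats
environmental resource.

Reproduction requires `reproduction_threshold` (10) stored units, which the
parent spends; the newborn starts empty in a uniformly random neighbouring
cell and first executes in the following update. Prey offspring draw their
class independently at birth — 25% non-poisonous, 25% mimic, 50% poisonous —
display honestly, and if their class would exceed `class_cap` (1,000) a
uniformly random incumbent of that class (never the newborn) is evicted.
Displayed class is not inherited: every mimic must rediscover dishonesty by
executing `set-display` itself.

## Mortality, predator persistence, and capacity

The only age-based mortality is `max_age` (default 1,000 updates), applied
to every organism. This default matters for the ecology: a predator must
accumulate 10 units at 25% conversion of victims typically holding a few
units each, i.e. tens of kills per reproduction. Lifespans of a few hundred
updates starve predator lineages entirely — predation then consists of
isolated converted prey and never becomes heritable, which contradicts the
phenomenon the system exists to study (predator subpopulations that evolve
prey preferences). At 1,000 updates (~25 desk-scale prey generation times) a
competent predator completes several reproduction cycles, heritable
predation establishes readily, and prey scarcity — not the lifespan — is
what limits predator numbers, visible as top-down suppression of prey
classes at low poison levels.

Predators have no ecological cap. The array backend does need a finite slot
pool: capacity is `3 × class_cap + predator_headroom` (headroom defaults to
`4 × class_cap`). Births refused for lack of a slot are counted and exposed
(`World.births_refused`); the acceptance experiments assert this never
triggers. Prey classes cannot exceed their caps regardless.

## Statistical pipeline

A run's binary outcome is *under predation pressure*: final poisonous
abundance strictly below `cutoff` (800, i.e. 80% of the cap); "avoidance
evolved" is the complement. The avoidance model is a run-level Bernoulli
logistic regression of avoidance on poison level, fitted by maximum
likelihood on per-level aggregated binomial counts (an equivalent
likelihood). The headline fit uses the statsmodels binomial GLM; complete
separation and constant outcomes have no finite MLE and are flagged as
degenerate fits whose curve is the empirical per-level step function
(nearest observed level), never silently divergent coefficients.

Uncertainty is percentile bootstrap throughout, seed-deterministic:

* **Avoidance curve band** — case resampling stratified within poison level
  (equivalently, per-level binomial resampling of outcome counts), refitting
  each resample with an internal Newton/IRLS solver that the test suite pins
  to statsmodels at 1e−8; resamples without a finite MLE are skipped and
  counted, with a warning flag above 10% skipped. Default 10,000 resamples.
* **Trajectory summaries** — whole replicates are resampled and per-update
  means recomputed (weight-matrix formulation, so 10,000 resamples are one
  matrix product per series).
* **Imperfect-mimicry ratio** — the ratio of mean final proportions of
  mimic-class organisms displaying poisonous (low-fidelity group over
  perfect-fidelity group), resampling runs within both groups (default
  1,000 iterations). Runs with no surviving mimics carry no proportion and
  are excluded; a zero denominator flags the ratio undefined.

Percentile bands are clipped to contain the point estimate, so reported
intervals always bracket the reported value. The percentile variant (rather
than BCa) is the package's choice; the resampling unit for the ratio is the
run.

## Synthetic fixtures

The fixture generators produce inputs with exactly the statistical structure
the pipeline assumes, so every analysis stage is testable without running
evolution. Logistic-outcome fixtures draw avoidance from a known logistic
curve and synthesize final abundances in classifier-consistent disjoint
ranges (avoid: 900–1,000; not: 300–700), which keeps classifier tests and
model tests from interacting. Time-series fixtures are known mean functions
plus iid Gaussian noise with display counts split by fixed proportions
(largest-remainder rounding). The worked-example scenario is a deterministic
miniature world encoding the poisoned-predator bookkeeping: a 9-unit
predator eats a 10-unit poisonous prey at poison level 0.1 (dropping to 8
units) and then needs either eight 1-unit prey or one 8-unit prey to reach
the 10-unit reproduction threshold at 25% conversion.

What the fixtures do **not** emulate: autocorrelated trajectories,
predator–prey feedback, or any genetic structure. Passing fixture-based
tests validates the statistical machinery, not the evolutionary dynamics;
those are exercised by the simulator tests and the desk-scale experiments.

## Experiment scales and what they show

The full-scale configuration (251×251 grid, caps 1,000, floor 900, 500,000
updates, 30 replicates per treatment, poison-level sweep 0.01–1.0) is the
package default and is what configuration echoes record. Routine testing and
the acceptance experiments run at two reduced problem sizes, chosen as the
package's standard desk scales:

* **Predator-free saturation**: full grid, attack opcode excluded, 1,500
  updates — populations saturate all three caps within ~200 updates, so the
  run length exceeds saturation several-fold.
* **Desk scale** (`desk_scale()`): 50×50 grid, caps 100, floor 90, 20,000
  updates, 10 replicates. At this scale the directional effect of poison
  potency is decisive: poisonous-class final abundance at p = 1.0
  (~98–100) stochastically exceeds that at p = 0.01 (~30–55, suppressed by
  thriving predators), one-sided Wilcoxon rank-sum p < 1e−4 over 10
  replicates per arm.

Desk-scale runs are an analogue, not a reproduction: evolved predator
*selectivity* (preferential targeting via `attack`+`nop` sequences) and
evolved poisonous-mimicry preferences develop weakly or not at all in
20,000 updates, so quantitative full-scale outcomes (fitted avoidance
curves from evolution, mimicry-ratio values) are outside what these runs
demonstrate. The bootstrap coverage experiment (200 synthetic datasets,
bands at 400 resamples) checks the interval calibration of the avoidance
band at a representative poison level and lands at the nominal 95% level.

## Numerical and implementation notes

* **Determinism.** Each replicate derives every stochastic decision from a
  single xorshift64* stream seeded from the replicate seed (organism
  placement and founder genomes use a numpy generator with the same seed).
  Replays are bit-identical; treatments use seeds `base_seed + i`.
* **Throughput.** The simulation core is numba-compiled over a handful of
  column-table arrays. Three measured-to-matter choices: per-organism state
  lives in three wide tables rather than ~20 vectors (keeping kernel
  argument counts, and with them register pressure, low); kernels draw
  randomness from the inline xorshift64* generator rather than `np.random`
  (whose calls act as optimization barriers inside the hot loop); and the
  instruction dispatch is written directly inside the scheduler's turn loop
  (a function boundary there costs an order of magnitude — numba-level
  inlining inserts reference-count traffic the pruner cannot remove, and
  real calls are ~100 ns each). A parity test holds the inlined dispatch
  bit-identical to the operation-level entry point used by the unit tests.
  Throughput is roughly 45 million VM instructions per second on one core.
* **Boundaries.** The prey floor blocks attacks strictly below it; the
  pressure classifier is strictly below its cutoff; the minimum-predator
  filter is inclusive at its threshold. All three boundaries are pinned by
  tests.
* **Degenerate inputs.** Harvesting from an empty cell returns zero;
  deletion never empties a genome; a length-1 genome with a skipping
  conditional wraps correctly; trajectory summaries of a single record
  collapse to zero-width bands; display proportions with no mimics alive are
  missing values, not zeros.

## Known limitations

* The instruction set is a minimal stand-in for a full digital-organism
  architecture; absolute rates of evolutionary discovery (e.g. how fast
  targeting arises) are not calibrated to any reference system, and
  generation counts are not calibrated to the original platform's.
* Only mimics' first-order dishonesty is modelled: there is no cost to
  display changes and no perceptual similarity continuum — fidelity is a
  single probability.
* Poisonous kills yield no resource gain by default; the alternative
  (penalty plus gain) is available as `poisonous_kills_yield_gain` but
  untested ecologically.
* Multiple organisms may share a cell; attack targets the most recent
  arrival among prey in the faced cell rather than a random occupant.
* The percentile bootstrap slightly undercovers in very small run groups;
  coverage was checked for the avoidance band at the default design (30
  runs per level), not for arbitrary designs.
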