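# Model and methods

`fragkern` simulates the evolution of seed-dispersal kernels in a
population of sessile, asexually reproducing organisms while their
landscape fragments. This note records the model, the numerical choices
made where the design was genuinely open, and what the package's tests
do and do not demonstrate.

## The model

**Space.** An `L x L` lattice of cells with periodic boundaries (a
torus), `L = 32` by default. Distance between two cells is the Euclidean
distance between their centres under the minimum-image convention,
rounded to the nearest integer ("distance class"). Because squared
lattice distances are integers, a half-integer distance can never occur
and the rounding rule has no ties. The number of cells at class `i` from
any focal cell is the ring size `g_i`; by homogeneity of the torus it is
the same for every focal cell.

**Individuals.** Each habitable cell holds at most one individual. An
individual carries an age, a lifespan drawn once from Normal(100, 5)
time-steps (truncated below at 1), and a dispersal kernel
`d = (d_0, ..., d_14)`: the proportions of its seeds dispersing to each
distance class, `sum_i d_i = 1`, with `d_0` the non-dispersed fraction.
Time is scaled so that 100 steps equal one life expectancy. Genotype and
phenotype are identified (no plasticity, haploid inheritance).

**Dispersal and recruitment.** Every cell at class `i` from an
individual receives the per-cell share `e_i = d_i / g_i` of its seeds.
When a cell falls vacant, each living individual `k` contributes weight
`s_k = d_{i_k} / g_{i_k}` (its kernel at the distance class `i_k` to the
vacancy) to the seed-arrival distribution; one parent is drawn with
probability proportional to these weights (lottery recruitment). The
dying occupant's own offspring compete too (`i = 0`), so a non-dispersed
seed may replace its parent. The recruit starts at age 0 with a fresh
lifespan and a mutated copy of the parent's kernel. Seeds falling on
uninhabitable cells are lost; this emergent dispersal mortality — for an
individual, `sum_i (d_i / g_i) u_i` with `u_i` the uninhabitable count
in ring `i` — is the model's only cost of dispersal.

**Landscape and fragmentation.** Each replicate synthesizes a real-valued
habitat-loss susceptibility surface by random-phase spectral synthesis:
a complex Gaussian spectrum is shaped by the radial power law
`f^-(H+1)` (power-spectrum exponent `2H + 2`, the standard
fractional-Brownian-surface convention for Hurst index `H`), the
zero-frequency component is removed, and the real part of the inverse
FFT yields a periodic surface. `H = 0.2` by default. Gradual
fragmentation removes the most susceptible cells first, at a constant
rate: with `n_total = L^2 - round(phi * L^2)` cells to lose over `T_f`
steps (`phi = 0.10` final habitability), loss event `k` (1-based, cells
in decreasing susceptibility) occurs at step `ceil(k * T_f / n_total)`,
making the cumulative loss at step `t` exactly
`floor(n_total * t / T_f)`. Rate presets: rapid `T_f = 900`,
intermediate `9,000`, slow `90,000` steps; controls: `none` (no loss)
and `instant` (all loss at step 1). Occupants of lost cells die without
replacement.

**Mutation.** Two operators, sharing a per-class mutation probability
`mu = 2/15` (so two classes mutate per reproduction on average) and a
maximal effect size `m = 0.5`, with each realized magnitude `m'` uniform
on `(-m, m)`:

* *Continuous-shifting* (a proxy for polygenic quantitative traits):
  each mutating class `i` exchanges probability mass with a uniformly
  chosen adjacent class `i' = i +/- 1` (trials pointing outside `0..14`
  are consumed without effect). The realized transfer is
  `clip(m', -d_i, d_{i'})` — bounded by the donating entry — so mass can
  only *shift* locally through phenotype space and the kernel's support
  grows by at most one adjacent class per event. An unbounded
  add-then-clip variant would let a mutation conjure mass at an isolated
  empty class, defeating the operator's purpose; the bounded transfer
  also conserves mass exactly, making the final renormalization a no-op
  up to rounding.
* *Unconstrained* (a proxy for large-effect loci): each mutating class
  independently gets `d_i <- clip(d_i + m', 0, 1)`, followed by
  renormalization; mass can therefore appear at any distance class in a
  single generation. If every entry is driven to zero (possible only for
  nearly degenerate kernels) the parent kernel is returned unchanged.

When several classes mutate in one reproduction event, classes are
processed in increasing index order on a working copy; with ~2 events
per call the composition order is a second-order detail.

**One time-step**, in order: (1) scheduled habitat loss; (2) ageing,
with death at the first step where age >= lifespan; (3) the seed pool is
frozen — everyone alive at the start of ageing whose cell is still
habitable, including same-step deaths; (4) every vacant habitable cell
runs its lottery against that common pool (so same-step recruits never
parent each other, and within-step ordering cannot matter); vacancies
with zero total arrival stay empty and are retried every later step;
(5) recording. Extinction halts the replicate with a flag.

## Degenerate geometry on small tori

Kernels always span classes 0–14, but a torus realizes class 14 only
for `L >= 20` (the largest minimum-image distance is `L/sqrt(2)`). On
smaller grids the unrealizable classes have `g_i = 0`: seed mass
assigned to them reaches no cell, contributes nothing to any lottery,
and counts fully toward dispersal mortality — the natural extension of
"seeds landing on unsuitable habitat". Consequence: a pure
long-distance population (`d_14 = 1`) on `L = 16` produces no viable
seeds at all and deterministically goes extinct; desk-scale experiments
that involve the long-distance preset should use `L >= 20`.

## Replication and seeding

Replicate `i` of a scenario derives its generator from
`SeedSequence(master_seed, spawn_key=(i,))`, split once more into a
landscape stream and a dynamics stream. Replicates are therefore
independent of execution order, and a full run is bit-reproducible from
its `config.yaml` provenance file. By default each replicate draws its
own landscape; `share_landscape` reuses replicate 0's surface for
sensitivity checks.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `L` | 32 | torus side (cells) |
| `H` | 0.2 | Hurst index of the susceptibility surface |
| `phi` | 0.10 | final habitable fraction |
| `T_f` | 900 / 9,000 / 90,000 | fragmentation duration presets (steps) |
| `mu` | 2/15 | per-class mutation probability |
| `m` | 0.5 | maximal mutation magnitude |
| lifespan | Normal(100, 5) | steps; 100 steps = 1 life expectancy |
| initial ages | uniform integers 1..125 | demographic heterogeneity at start |
| horizon | 110,000 | steps (1,100 life expectancies) |
| replicates | 200 | per scenario |

The four initial strategies are non-dispersal (`d_0 = 1`), uniform
(`d_i = 1/15`), long-distance (`d_14 = 1`) and bimodal
(`d_0 = d_14 = 1/2`).

## Numerical and design choices

* Susceptibility ties are broken by adding a jitter of magnitude
  `1e-12`, ordered by a seeded random permutation, so the loss ordering
  is total and stable. Only the cell ordering matters downstream, so the
  surface is equivalent up to any monotone transform.
* The surface is standardized (zero mean, unit variance) before jitter;
  this is cosmetic.
* `round(phi * L^2)` (nearest integer) fixes the final habitable count:
  102 cells for the defaults.
* Initial ages are integers; later ages are integer step counts; recruit
  age starts at 0.
* Lifespans are continuous; truncation at 1 step is a formality 20 sigma
  from the mean.
* The instantaneous control applies every loss at step 1.
* The per-offset distance-class table and the per-cell uninhabitable
  ring counts are precomputed/updated incrementally, so seed-arrival is
  a pure function of (pool, cell, habitability).
* Mutation is applied to the recruited seed at establishment rather than
  to every latent seed: only one seed per vacancy is ever realized and
  seeds disperse with the parent's phenotype, so the two schemes are
  distributionally identical and this one is far cheaper.
* Population summaries weight every living individual equally; the
  aggregate across replicates is the unweighted per-step mean, with
  extinct replicates dropped from the step of extinction onward.

## Desk-scale experiment sizes

The shipped test suite and the results-reproduction script run the real
model at reduced sizes chosen to keep a complete run on one CPU in
minutes while staying in the regime the defaults define: rapid-rate
scenarios run at full `L = 32` geometry over the full 110,000-step
horizon with ~10 replicates (cheap, because only ~102 cells remain
occupied after step 900); slow-rate scenarios run at `L = 32` with the
duration and horizon scaled by 1/4 (`T_f = 22,500`, horizon 27,500) and
the post-fragmentation measurement point scaled likewise; qualitative
contrasts use 10 replicates per arm. Aggregates over 10 replicates of
~100–1,000 individuals carry visibly more sampling noise than 200-replicate
means.

## What the generator emulates, and limits

The synthetic landscapes emulate autocorrelated habitat-loss
susceptibility, not any mapped real landscape; there is no density
dependence beyond one-individual-per-cell, no seed bank, dormancy,
sexual reproduction, landscape recovery, or genotype–environment
interaction. Passing tests show the implementation realizes this model
faithfully — they say nothing about organisms whose dispersal biology
violates the model's assumptions.

Two quantitative caveats. First, the spectral-synthesis variant behind
published fractal-landscape generators differs between implementations
(windowing, spectrum normalization); surfaces here follow the canonical
amplitude convention above, and equivalent simulations with another
variant will agree only up to the induced cell ordering. The emergent
equilibrium seed-mortality level is sensitive to exactly this landscape
texture (patch sizes at 10% habitability), so mortality levels should be
compared across landscape generators with care; the evolved
non-dispersed fraction `d_0 ~ 0.3` is, in our experiments, robust to it.
Second, small tori distort the ring structure (see above), so
quantitative kernel summaries from `L < 32` runs are not comparable to
the default geometry.
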