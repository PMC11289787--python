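# Methods

## Model

`diatomsim` advances a closed, panmictic, strictly neutral population of
diploid cells through daily epochs. There is no environment, no spatial
structure, no mortality term and no fitness: the only stochastic forces
are stepwise microsatellite mutation during clonal division, meiotic
crossover during the annual sex event, and the genotype-blind daily
down-sampling to the carrying capacity. Everything the model produces —
bottleneck effects included — emerges from the interaction of those
three forces with the boom–bust calendar.

### Genome

A single linear chromosome of `chrom_len` bp (default 10⁵) carries
`n_loci` = 5 microsatellites. A locus is a motif of 1–6 bp repeated
between 5 and 50 times; its allelic state is the repeat count, so the
heritable state of a cell is a 5 × 2 integer array. Locus positions and
motif lengths are drawn once per experiment from `layout_seed`
(rejection sampling until the five *maximal* tracts — motif length × 50
— are disjoint), and the same layout is shared by every condition and
replicate so that distances along the chromosome, and hence linkage, are
comparable across the whole grid.

Crossover breakpoints are excluded from the maximal tract of each locus,
not the tract realised in a given individual. This makes the exclusion
zone genotype-independent: the recombination machinery never has to
inspect an individual's state, and a breakpoint can never split a repeat
regardless of how many repeats are currently there.

### Mutation

Where the biology does not pin down a mechanism, the field-standard
choice is used: mutation follows the symmetric single-step
stepwise mutation model (±1 repeat with equal probability), applied
independently to each of the 10 (locus, homolog) slots with probability
`mut_rate` at every daughter-producing division. At the bounds the step
reflects (a +1 at 50 yields 49, a −1 at 5 yields 6), which keeps the
allele space exactly [5, 50] without an absorbing edge.

### Recombination and sex

The number of breakpoints per meiosis is Binomial(`chrom_len`,
`rec_rate`) — a per-base Bernoulli formation law — with positions
uniform outside the exclusion tracts (re-drawn until valid) and
duplicates collapsed. A gamete starts from a uniformly chosen homolog
and switches source at each breakpoint; because breakpoints cannot fall
inside a tract, each locus inherits from exactly one homolog. At
`rec_rate` ≤ 10⁻⁶ a meiosis usually draws zero breakpoints and the
gamete is an intact homolog; the implementation fast-paths this case and
runs the full breakpoint machinery otherwise.

On the sex day (bloom day 15 of 30), 2·⌊`sex_rate`·N/2⌋ cells are drawn
without replacement, paired at random, and each pair is replaced by two
zygotes built from two independent gametes per parent. Non-participants
are unaffected (they still divide clonally that day), parents are
consumed, and with two offspring per mating the event is
size-conserving. If rounding leaves an odd participant, one is dropped.

### Demography and regulation

Carrying capacity is 10² cells in the stationary phase and 10⁵ during
the 30-day bloom (day-of-year 1–30 by default; the calendar is
configurable). Cells divide twice per bloom day (×4 before regulation)
and once every fifth absolute day otherwise — a deterministic schedule
rather than a per-cell probability, so replicate trajectories stay
phase-aligned. After all reproduction, `regulate` keeps a uniform random
subset of size K. Extinction is impossible under this scheme (a
non-empty population is never emptied) but guarded with a diagnostic.

### Founders

All conditions and replicates of an experiment start from the same
founder population, drawn from `founder_seed` alone: 100 copies of a
single homozygous genotype whose allele at each locus is uniform in
[5, 50]. Starting clonal and homozygous means every index (A, G, H, R)
grows from its floor during the burn-in and approaches its
mutation–sex–drift balance from below; this is the regime in which
recurrent sex leaves its fingerprint as a slow upward heterozygosity
trend, because recombination keeps assembling heterozygous combinations
faster than the clonal background acquires them. A maximal-diversity
founder mode (`founder_diversity="max"`, every slot independent uniform)
is available and is used in the pure-drift decay tests, where one wants
diversity to start high and only fall.

## Parameters

| name | default | units | notes |
|---|---|---|---|
| `mut_rate` | 10⁻³ | per locus per homolog per division | grid spans 10⁻⁴–10⁻²; the measured mitotic rate for the reference diatom is 3·10⁻³ |
| `rec_rate` | 10⁻⁶ | per base per meiosis | grid {10⁻⁸, 10⁻⁶, 10⁻⁴, 10⁻²} |
| `sex_rate` | 0.35 | fraction of N | grid {0.2, 0.35, 0.5}; 0 = obligate clonality |
| `K_stationary` / `K_bloom` | 10² / 10⁵ | cells | daily regulation targets |
| `year_len` / `bloom_len` | 365 / 30 | days | one bloom per year |
| `sex_day` | 15 | bloom day (1-based) | middle of the bloom |
| `stationary_division_period` | 5 | days | division on absolute days divisible by 5 |
| `bloom_divisions_per_day` | 2 | divisions | ×4 growth per bloom day |
| `burn_in_years` / `sample_years` | 11 / 5 | years | unmonitored / monitored |

The condition grid contains 36 sexual combinations plus 3 clonal
controls. The grid's published recombination regimes list only three
values while announcing four; the fourth is taken to be 10⁻⁶, the value
the dedicated high-resolution runs use, and is flagged here so users can
override it.

Two sampling cadences exist: *standard* (every 60 days outside blooms,
weekly inside) and *high* (every 10 days outside, daily inside); both
always include the last pre-bloom day, the sex day and its neighbours,
and the first post-bloom day, since the signature and bottleneck
analyses need those anchors.

## Reduced-scale profile

`desk_profile()` keeps the full model structure but sets `K_bloom` = 10⁴
and 2 + 2 years, which puts one full condition run in the low seconds on
one core; the test suite and `scripts/acceptance.py` use this profile
(36 runs ≈ one minute). The full-scale configuration is plain
`SimulationConfig()`.

## Analysis layer

* **PCA** — columns of the (A, G, H, R) matrix are centred and scaled
  to unit variance (the indices are incommensurate; scaling is
  switchable), then decomposed by SVD. Constant columns are dropped with
  a warning. Component signs are fixed by making each component's
  largest-magnitude loading positive.
* **nMDS** — SMACOF majorization with isotonic regression of
  configuration distances on the dissimilarities, minimising Kruskal
  stress-1, 20 random starts, 300 iterations, stress tolerance 10⁻⁷,
  fully seeded. Non-convergence returns the best configuration with a
  flag. The per-iteration stress history of the best start is exposed.
* **Binomial deviance distance** — the standard ecological form with
  0·log 0 ≡ 0 and zero contribution from all-absent columns; on binary
  data it equals log 2 × Hamming distance, which the tests exploit as an
  exact oracle.
* **Bloom signature** — operationalised on the daily R series of one
  bloom plus the last pre-bloom day: stage 1 fires if the minimum of the
  first five bloom days falls below the pre-bloom value; stage 2 if the
  least-squares slope from bloom day 5 to the day before sex is
  positive; the sex spike if R rises from the day before to the day
  after the event (forced false when no event occurred, as in clonal
  runs, where any R movement across mid-bloom is mutation noise, not
  sex); stage 3 if the slope from two days after sex to bloom end is
  non-positive. An exactly flat series carries no signature and returns
  all-false. Window widths are arguments.
* **H trend** — least-squares slope of H against day over a run's
  sampling days (≥ 10 required), with its standard error.

## Numerical and degenerate-input choices

* Repeat counts are int16; populations are (N, 5, 2) arrays; MLG
  identity is computed on within-locus-sorted pairs, so it is invariant
  to homolog order.
* Bernoulli-per-slot mutation is realised as a Binomial draw of the
  mutation count followed by a uniform choice of slots — an exact
  equivalence that is much faster at realistic rates.
* R is undefined for N < 2 and reported as missing.
* A sex event that cannot seat two participants is skipped with a
  logged warning rather than raising.
* Every run is reproducible from three seeds (layout, founder, process);
  `run_experiment` derives per-(condition, replicate) process streams
  from a master seed via `SeedSequence` spawn keys.

## What passing tests do and do not show

The simulator is its own data generator; there is no external data
anywhere. The test suite verifies the machinery against independent
oracles (a per-base Bernoulli walk for meiosis, a separately coded
single-locus drift simulator, literal evaluations of the distance
formula, a brute-force eigendecomposition for PCA) and verifies that the
emergent phenomenology at reduced scale matches the modelled biology:
the within-bloom diversity drop, the mutation-driven recovery, the
mid-bloom sex spike, the post-bloom bottleneck collapse with its R
rebound, and the sexual-vs-clonal heterozygosity contrast. None of this
says anything about real plankton beyond what the model structure
encodes: real blooms have environmental forcing, variable phenology,
mortality, size-reduction constraints and mating types, all absent here.

## Known limitations

* **Stage-3 "decay" is plateau-dominated.** After the sex spike, the
  excess of rare recombinant MLGs is eroded within a few days (a
  singleton lineage survives a bloom day's ×4 growth plus ¼ sampling
  with probability ≈ 0.68), while fresh mutant MLGs keep arriving at a
  rate proportional to K·`mut_rate`. At `mut_rate` = 10⁻³ the influx
  dominates for the rest of the bloom, so the R series in the bloom's
  second half is a plateau with a slight upward drift rather than a
  sustained decay, and the stage-3 flag (non-positive late-bloom slope)
  fires only sporadically — at reduced scale and at full K alike. The
  other three stages are detected in essentially every replicate-bloom.
* **Low-mutation heterozygosity contrast is underpowered at reduced
  scale.** At `mut_rate` = 10⁻⁴ the standing diversity after a 2-year
  burn-in is a handful of alleles, and the sexual-vs-clonal slope
  contrast over six replicates is dominated by drift noise; its sign is
  not stable across master seeds. At 10⁻³ and 10⁻² the contrast is
  positive as expected.
* Observed heterozygosity under pure drift is a bounded martingale, not
  a decreasing quantity: culling a homozygous lineage raises the mean.
  Tests therefore check A and G for pathwise monotonicity and H for
  absence of a systematic trend.
* The model has no gene conversion, no multi-step mutation, no
  interference between crossovers, and treats the bloom calendar as
  identical every year.
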