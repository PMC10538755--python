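# Methods

## The model

tortflow simulates a closed population of diploid, sexed individuals on a
rectangular grid of 1 km² cells over discrete, non-overlapping generations.
Each cell carries a movement resistance in [0, 1] (1 = impassable) and an
integer carrying capacity K. A generation consists of dispersal,
reproduction, and complete adult mortality, in that order; individuals are
processed with independent random draws, so no ordering artifacts arise
within a phase.

**Dispersal.** Each individual moves with probability 0.5. The default
kernel (`dispersal_kernel="walk"`) performs 10 sequential Queen's-case
steps, each uniform over the traversable 8-neighbourhood of the current
cell; the endpoint is the new home cell. This gives a short-tailed,
diffusive kernel (per-axis SD ≈ 2.6 cells per event) bounded by a Chebyshev
distance of 10 cells (≈ 14 km), keeps kin spatially associated, and lets
isolation by distance emerge on uniform landscapes. An alternative kernel
(`"ring"`) jumps directly to a uniformly chosen habitable cell at the
largest Chebyshev distance d ≤ 10 reachable by a path of length d; it mixes
far more strongly and is retained for comparison because the verbal
description of "travelling the maximum distance allowed" admits both
readings. Impassable cells block movement entirely. Culvert cells embedded
in a barrier carry a per-generation transit quota equal to their K (3): at
most 3 distinct animals may enter or traverse the cell per generation;
walkers facing an exhausted culvert redraw among their remaining open
moves.

**Reproduction.** In every cell holding at least one female and one male,
the expected number of recruits is the discrete logistic increment

    E = N + r · N · (1 − N/K),    r = 0.48 per generation,

realized as floor(E) plus a Bernoulli(E − floor(E)) extra. Each recruit
draws its mother and father uniformly (with replacement) from the cell's
females and males, inherits one uniformly chosen allele per parent per
locus, and is sexed 1:1. Multi-occupant single-sex cells produce nothing
(mate limitation). A cell occupied by a single individual recruits at the
same logistic rate with the lone occupant as both parents
(`mating_system="fallback"`, the default). This uniparental fallback is a
deliberate engine choice, not tortoise biology: without it, mate limitation
makes the K = 3 configuration demographically subcritical under every
dispersal kernel we tested and the low-density landscape goes extinct
within tens of generations, which contradicts the slow, partial collapse
and the strong heterozygote deficit (Ho far below He) that this model
family is known to produce. The fallback reproduces exactly that
phenomenology: a quasi-stationary low-density population persisting in
small, highly inbred family clusters. The literal rule — no mate, no
offspring — is available as `mating_system="strict"`.

**Mutation.** Each allele copy mutates independently at 5 × 10⁻⁴ per
generation. The default k-allele model replaces the allele with a uniformly
chosen different state from the locus's founder state space; a single-step
(`"smm"`) alternative steps ±1 within the state space. Loci with one state
cannot mutate.

**Growth rate.** r = 0.48 is the annual growth estimate of 1 % compounded
additively over the 48 breeding years between maturity (17 y) and average
lifespan; `growth_rate_from_annual` documents the arithmetic.

## Landscapes and densities

Scenario surfaces are 25 × 25: `no_barrier` (all resistance 0), `barrier`
(the central column impassable, K = 0), `culverts` (the barrier with three
evenly spaced cells of resistance 0.7 and K = 3). Density labels set the
uniform per-cell capacity and the seeding: low 3, moderate 14, high 20
tortoises/km², giving initial populations of 1875, 8750 and 12500. The
high-density value deserves a note: the habitat-capacity table tops out at
24/km², but both the published initial size (12500 = 20 × 625) and the
published near-stable final census (~12 000) pin the effective high-density
capacity at 20/km², so the scenario builder uses 20; the 24/km² ceiling
still applies to habitat-derived surfaces. Heterogeneous surfaces degrade a
habitat raster by disturbance conversion factors
(`habitat × (1 − factor)`, composed multiplicatively over overlapping
layers, order-independent), invert to resistance, and bin habitat into
capacities 0–24. Rasters are read/written as Esri ASCII grids with
`repr`-exact values, so a write–read round trip is bit-identical.

## Synthetic founders

The empirical microsatellite panel this package emulates is not public, so
founders are generated: per locus, an allele count is drawn near the target
richness (13 ± 3; at least 2 when heterozygosity must be positive) and a
symmetric Dirichlet frequency vector is drawn with concentration chosen by
closed-form bisection so the expected heterozygosity matches the target
(0.81). The realized spectra are then tempered (p ∝ p^β, β found by
bisection) so each panel's mean expected heterozygosity hits the target
exactly, not merely in expectation. Genotypes are drawn under
Hardy–Weinberg equilibrium, so panels are panmictic and carry no spatial
signal or linkage disequilibrium by construction. What this does **not**
emulate: the empirical allele-size distribution, the richer allele counts
that deep samples of a burned-in population show (our state space is fixed
at ~13 states/locus, so allelic richness saturates near 13 rather than
rising past 20 in very large samples), and any real departure from HWE.
Passing tests therefore validate the machinery on idealized microsatellite
data, not the fidelity of any one empirical dataset.

## Statistics

* **Diversity**: per-locus observed heterozygosity, Nei's unbiased expected
  heterozygosity (2n/(2n − 1) correction), and raw allele counts
  (no rarefaction — deliberately, since the quantity tracked here rises
  with sample size); means and SDs over loci.
* **F<sub>ST</sub>**: multilocus Weir–Cockerham (1984) θ between the two
  barrier sides, summing the a/b/c variance components over alleles and
  loci. Verified against an independent ANOVA-mean-squares oracle to 1e-12.
* **LD-N<sub>e</sub>**: Burrows composite disequilibrium over all pairs of
  retained alleles (frequency ≥ 0.05; the most common retained allele per
  locus dropped so comparisons are independent), r̂² = Δ̂²/(v₁v₂) with the
  S/(S−1) correction, bias-corrected by E[r²|S] = 1/S + 3.19/S² (S ≥ 30),
  and inverted through the random-mating formula
  N̂e = (1/3 + √(1/9 − 2.76 r²′))/(2 r²′); non-positive r²′ reports ∞.
  The parametric 95 % CI treats the mean r̂² as chi-square with df equal to
  the number of locus pairs — allele-level comparisons within a locus pair
  are far from independent, and using their count produces badly
  anticonservative intervals. With 20 loci this CI covers the true size of
  an ideal Wright–Fisher population (N = 100, S = 100) in ≥ 80 % of
  simulated datasets.
* **HWE**: per-locus Monte-Carlo exact test (alleles permuted and re-paired,
  chi-square distance statistic, ≥ 10⁴ shuffles by default) with a
  Bonferroni threshold of 0.05/20 = 0.0025.
* **sPCA**: eigendecomposition of (1/n) Xᵀ((W + Wᵀ)/2)X where X is the
  column-centered individual allele-frequency matrix (values 0/0.5/1) and W
  a row-standardized symmetric 8-nearest-neighbour network on jittered cell
  centers (k = 8 mirrors the Queen's-case neighbourhood; the network type is
  a package choice). Each axis satisfies λ = var(scores) × I(scores)
  exactly. Global/local structure is tested by permuting individual
  locations (999 permutations by default; p = (1 + #{perm ≥ obs})/(1 + n)).
* **Mantel**: Pearson correlation of off-diagonal distances with joint
  row/column permutation; genetic distance is Euclidean on individual
  allele-frequency vectors.
* **Subsampling**: analyses use n = 750 individuals drawn without
  replacement (the size at which pairwise θ stabilizes in the convergence
  check); smaller snapshots are used whole. Grouping is by side of the
  barrier column, with the (≤ 9) culvert occupants grouped with the western
  side.

## Numerical and design choices

* Recruit rounding is floor-plus-Bernoulli: exact in expectation, minimal
  extra variance.
* Per-replicate RNG streams derive from one master `SeedSequence`; identical
  seeds give bit-identical runs, including GENEPOP/CSV outputs.
* Coordinates are 0-based (row, col); distances Chebyshev; boundaries
  closed (no wraparound).
* Dispersal candidate tables (ring kernel) and neighbour tables (walk
  kernel) are cached per surface and per culvert-quota state.
* The engine stores the population as flat numpy arrays (cells, sexes,
  an (n × 20 × 2) genotype tensor); a replicate of 8750 individuals over
  200 generations runs in a few seconds on one CPU.
* Estimators require complete genotypes and raise on missing data — the
  simulator never generates any.

## Problem sizes used by the test suite and acceptance script

Full 25 × 25 landscapes and the full 200 generations are always used.
Replicate counts are scaled to desk hardware: 5 replicates for low-density
runs, 3 for moderate/high (the published experiments used 30). Cross-
replicate SDs at these counts are small relative to the effects measured
(final-census SDs of tens of individuals against means of hundreds to
thousands).

## Known limitations

* The low-density absolute level is sensitive to the singleton-reproduction
  rule: the engine stabilizes near 310–350 individuals (an ~83 % decline)
  where the reference results report ~460 (75 %); the bracketing behaviours
  (strict mating → extinction; uniparental fallback for all mate-less
  groups → ~1250) confirm the level is set by exactly this rule. Relatedly,
  between-side θ at low density runs several-fold higher than the reference
  value, though still roughly an order of magnitude above the barrier-free
  landscape, as expected.
* No age structure, survival heterogeneity, directed or habitat-weighted
  movement, or burrow/social behaviour; resistance values strictly between
  0 and 1 affect only capacity and culvert quotas, not movement cost.
* Allelic richness cannot exceed the founder state space (mutation is
  k-allele within it).
* The heterogeneous-surface path is exercised on synthetic rasters only; no
  real GIS layers ship with the package.
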