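# tortflow

Agent-based, spatially explicit, forward-in-time simulation of Mojave desert
tortoise (*Gopherus agassizii*) gene flow across roads, railways and culvert
crossings — together with the landscape-genetics analysis pipeline used to
evaluate connectivity: genetic diversity (Ho, He, allelic richness),
pairwise Weir–Cockerham F<sub>ST</sub>, linkage-disequilibrium effective
population size (N<sub>e</sub>), spatial PCA with Moran's *I* permutation
tests, and Mantel tests of isolation by distance.

## Who this is for

Landscape geneticists and conservation modelers asking how linear barriers,
underground crossing structures, and population density interact to shape
demographic and genetic connectivity in low-mobility species. The package
simulates the full causal chain — resistance surface → individual movement →
mating → drift/mutation → measurable genetic pattern — so detection lag,
estimator behaviour, and management scenarios can be explored in silico.

## Model at a glance

A 25 × 25 grid of 1 km² cells carries a movement resistance in [0, 1]
(1 = impassable) and a carrying capacity *K* per cell. Generations are
discrete and non-overlapping. Each generation, every individual:

1. **disperses** with probability 0.5, taking up to 10 Queen's-case steps
   (≤ 14 km) through traversable cells;
2. **reproduces** within its cell: a cell holding *N* individuals of both
   sexes recruits `E[N'] = N + rN(1 − N/K)` offspring (*r* = 0.48 per
   generation, i.e. 1 %/yr × 48 breeding years), parents drawn uniformly from
   the cell's females/males, Mendelian inheritance over 20 unlinked
   microsatellite-like loci with mutation rate 5 × 10⁻⁴;
3. **dies** — the offspring are the next generation's breeding adults.

Scenario surfaces: `no_barrier` (uniform, zero resistance), `barrier`
(a one-cell-wide impassable column bisecting the grid), and `culverts`
(the barrier pierced by 3 low-capacity crossing cells: resistance 0.7,
*K* = 3, at most 3 distinct animals entering or traversing per generation).
Heterogeneous surfaces are built from a habitat-suitability raster plus
disturbance layers via `adjusted = habitat − habitat × factor` (urban/solar
1.00, railway/interstate 0.75, minor roads and rights-of-way ≤ 0.25),
`resistance = 1 − adjusted`, and a step function mapping habitat to
*K* ∈ {0, 1, 3, …, 24}.

Founder genotypes are synthetic: symmetric-Dirichlet allele frequencies
calibrated (by bisection plus spectrum tempering) to the empirical diversity
of the study system — 20 loci, ~13 alleles/locus, expected heterozygosity
0.81, Hardy–Weinberg conformant, no spatial structure.

## Worked example

```python
import numpy as np
from tortflow import (ExperimentSpec, SimulationConfig, run_experiment)

spec = ExperimentSpec(
    scenario="barrier", density="low", master_seed=42,
    config=SimulationConfig(n_generations=200, n_replicates=5,
                            sample_interval=200),
)
result = run_experiment(spec)
final = result.final_census()
print("final census:", final.mean(), "+/-", final.std(ddof=1))
last = result.summary[result.summary.generation == 200]
print("Ho %.2f  He %.2f  FST %.3f" %
      (last.ho.mean(), last.he.mean(), last.fst.mean()))
```

prints

```
final census: 307.0 +/- 19.924858845171276
Ho 0.14  He 0.69  FST 0.394
```

Reading: seeded at 3 tortoises/km² (1875 animals), the population collapses
by ~83 % over 200 generations because dispersers frequently fail to find
mates, and the absolute barrier splits the survivors into two strongly
differentiated, inbred sides (observed heterozygosity far below expected;
F<sub>ST</sub> roughly an order of magnitude above the equivalent
barrier-free landscape). At moderate (14/km²) or high (20/km²) density the
same landscape only loses the barrier's habitat footprint (~4–12 %) and
differentiation stays an order of magnitude lower.

The same experiment from a shell:

```bash
tortflow pipeline run --scenario barrier --density low \
    --replicates 5 --generations 200 --seed 42 --out runs/barrier_low
```

writes `summary.csv`, `fst_timeseries.csv`, `table5_style.csv`, GENEPOP
snapshots and a Ho/F<sub>ST</sub> time-series plot.

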