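# phyloniche

Comparative analysis of bioclimatic-niche evolution for island plant
radiations and their pollinators. The package quantifies species' climatic
niches in a reduced environmental space, measures pairwise niche overlap and
explains it with shared pollination mode and shared island, and then asks the
macroevolutionary question: did niche optima and niche tolerances evolve
under drift-like Brownian motion or under constrained (Ornstein–Uhlenbeck)
dynamics, and do pollination strategy or island isolation define distinct
selective regimes? It is written for evolutionary ecologists working with
herbarium/GBIF-style occurrence data, a climate raster, and a posterior
sample of ultrametric phylogenies — and it ships a synthetic-data generator
that reproduces the statistical shape of such a study end to end, so every
stage is testable without downloads.

## The analysis

**Environmental space.** A correlation-matrix PCA of the background raster
(pixels × standardized climate variables) defines a 2-D environmental space.
Occurrences are filtered (coordinate precision ≤ 10 km; species with ≥ 5
records in ≥ 5 distinct pixels), deduplicated to one record per species per
pixel, and projected with the background loadings. Per species and axis, the
*niche identity* is the mean score and the *niche breadth* the sample SD.

**Overlap.** Species occupancy of the gridded environmental space is a
Gaussian kernel density of its scores, optionally divided by the background
availability density and renormalized. Overlap between species 1 and 2 is
Schoener's statistic

    D = 1 − ½ Σ_cells |z₁ − z₂|  ∈ [0, 1].

Five OLS models (`D ~ 1`, `D ~ pollination`, `D ~ island`, additive, and
with interaction) are ranked by AIC; models within 2 AIC units of the best
are flagged as not rejected.

**Regime histories.** Pollination mode (hummingbird / bat / mixed; 3 states,
all-rates-different) and island (Cuba / Hispaniola / Puerto Rico / Jamaica;
4 states, symmetric rates) evolve under Mk models fitted by maximum
likelihood with Felsenstein pruning. Field-observed modes enter as certain
tips; morphology-inferred specialists get prior (2/3, 1/6, 1/6), inferred
generalists (1/2, 1/4, 1/4), unknowns (1/3, 1/3, 1/3). Full character
histories are drawn by stochastic mapping (exact posterior draws: node
states from the pruning recursion, branch paths by endpoint-conditioned CTMC
sampling).

**Model selection.** On each painted tree, six Gaussian models are fitted to
niche identity and breadth (per axis and bivariate): BM1, BM3/BM4 (one
diffusion rate σ² per pollination mode / island), OU1, and OU3/OU4 (one
optimum θ per regime, shared α and σ²). Models are compared by small-sample
AIC,

    AICc = AIC + 2k(k+1)/(n − k − 1),   n = species × traits,

and Akaike weights `w_i = exp(−Δ_i/2)/Σ_j exp(−Δ_j/2)`. Occurrence and tree
uncertainty are propagated by pairing each of the posterior trees with a 50%
jackknife of every species' records and a fresh stochastic map per
iteration; the headline table reports mean weights with 95% percentile CIs.

## Worked example

Run the whole pipeline on the built-in study-shaped synthetic system
(35 plant species on 4 islands, 22 pollinators, a 3458-pixel / 20-variable
raster, 5 analysis iterations):

```sh
phyloniche full-run --outdir demo --seed 11 --n-iterations 5
```

`demo/table1_plant_overlap.csv` then contains the overlap regression:

```
model,AIC,R2,n,is_best,...,island,island_sig
D ~ 1,-424.89,0.0,595,False,...
D ~ island,-462.57,0.06,595,True,...,0.09,***
D ~ pollination + island,-433.24,0.06,561,False,...,0.08,***
```

Plant pairs sharing an island overlap more (mean D 0.43 same-island vs 0.34
different-island; the island term is +0.09, p < 0.001, and `D ~ island` is
the best model by AIC) — the effect injected by the generator through
island-specific available environments. `demo/table3_mean_aicc_weights.csv`
summarizes the evolutionary-model comparison per trait set, e.g.

```
trait_set,BM1,BM3,BM4,OU1,OU3,OU4
niche identity (PC1),0.0 [0.0-0.01],0.2 [0.0-0.89],0.2 [0.0-0.9],0.48 [0.0-0.92],0.06 [0.0-0.16],0.06 [0.0-0.24]
```

Each cell is the mean AICc weight over iterations with its 95% CI. BM1
collapses to ~0 (tips are far less correlated than unconstrained drift
predicts), the single-optimum OU model carries the largest weight here, and
island-regime models retain some support on identity — which is real in this
synthetic system, because measured identities are partly shaped by what each
island offers. The wide CIs show how much single stochastic maps and
jackknife replicates disagree at 35 species; that spread is the reason the
pipeline replicates instead of reporting one fit.

Every stage is also available separately (`simulate`, `envspace`, `overlap`,
`simmap`, `evofit`, `report`) over declared CSV/JSON/Newick files, with a
manifest of checksums; reruns with the same seed are byte-identical.

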