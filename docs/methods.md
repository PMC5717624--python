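# Methods

This note records the models implemented in `phyloniche`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would otherwise have to
reverse-engineer.

## Environmental space and niche summaries

The background ordination is a PCA of the correlation matrix: variables are
standardized to mean 0 / sample SD 1 (ddof = 1), so each climate variable
enters with equal weight regardless of units. Only the first two components
define the niche space; explained-variance shares are kept for all
components. Two conventions are fixed deliberately:

- **Loading signs.** Eigenvector signs are arbitrary; each loading column is
  flipped so its largest-magnitude element is positive. Outputs are then
  identical across linear-algebra backends.
- **Breadth denominator.** Niche breadth is the per-axis *sample* SD
  (ddof = 1), the conventional unbiased choice.

Occurrences are assigned to the nearest pixel center; records farther than
half a pixel diagonal from every center count as outside the raster. Filter
rules: coordinate precision strictly greater than 10 km is discarded
(a record at exactly 10 km is kept); species need at least 5 records *and*
at least 5 distinct pixels. The minimum-count rule is applied to plants and
is configurable for pollinators, whose sampling regimes differ. Projection
always uses the background standardization constants and loadings — species
records never refit the PCA.

## Occupancy grids and Schoener's D

Occupancy is a product-Gaussian kernel density of the species' deduplicated
scores evaluated at the centers of an R × R grid (default R = 100) spanning
the background scores. Bandwidths follow Silverman's rule per axis,
`h = 0.9 min(sd, IQR/1.34) n^{-1/5}`, floored at half a cell width so
degenerate point sets remain well-defined. With availability correction
(default on), the occurrence density is divided cellwise by the background
density, floored at its 1st positive percentile to prevent division
blow-ups where almost no environment exists; the grid is renormalized to
sum to 1 afterwards. `D = 1 − ½Σ|z₁ − z₂|`.

The overlap regression is ordinary least squares. AIC uses the Gaussian
log-likelihood at the ML variance and counts k = coefficients + 1 (the
variance is a fitted parameter). Pairs with an unknown pollination mode are
excluded only from models that use the pollination term (listwise deletion
per predictor), so island-only models keep the full pair set. Two caveats
are accepted knowingly: species pairs are not independent (each species
appears in many pairs) and no phylogenetic correction is applied — D is a
distance between pairs, not a species-level trait.

## Mk models and stochastic mapping

The discrete-character likelihood is Felsenstein pruning with per-branch
transition matrices exp(Qt); tip data are probability vectors, which is how
observed/inferred/unknown pollination information is weighted. Transition
matrices are computed by eigendecomposition of Q (vectorized over branches),
falling back to `scipy.linalg.expm` when the eigenvector matrix is
ill-conditioned (condition number > 1e8). Root handling defaults to
FitzJohn-style weighting (each root state weighted by its share of the root
partial likelihood); uniform and stationary treatments are selectable and
are used by the oracle tests because their weights do not depend on the
data. Rates are estimated by L-BFGS-B on log rates, bounds [1e-6, 1e3],
from a heuristic start (states / total tree length) plus uniform ±2 log-unit
restarts.

Stochastic maps are exact joint draws: the root state is sampled from its
posterior, node states from `P(parent→child) × partial(child)` in preorder,
and each branch's internal history conditional on its endpoints — by
rejection-sampling forward CTMC paths (cap 1000 attempts) with an exact
uniformization bridge as fallback, so improbable endpoint pairs terminate.
Multi-island species are collapsed to a single island uniformly at random
per iteration, because the regime models require exclusive states.

## Evolutionary models

All six models are Gaussian processes on the painted tree; means and
covariances are built in closed form (Hansen-type construction) and the same
moment code feeds the likelihood, the fitting routines and the trait
simulator, which keeps simulator and inference consistent by construction.

- **BM.** Covariance accumulates σ²(regime) × duration over the shared
  root-to-MRCA path; the root state is the (shared) mean. Multi-regime BM
  varies only σ² across regimes.
- **OU.** Non-stationary root fixed at the optimum of the root regime (a
  stationary-root variant is selectable): tip expectation decays from the
  root optimum and accumulates `(1 − e^{−α·dur}) e^{−α·remaining} θ(regime)`
  along the path; covariance is
  `σ²/(2α) · e^{−α d_ij} (1 − e^{−2α s_ij})` with s the shared time and d
  the patristic distance. Multi-regime OU varies only θ; α and σ² are
  shared, which is the literal reading of "a different selective optimum per
  regime".
- **Bivariate traits** use a symmetric 2×2 rate matrix per regime (BM) or a
  shared 2×2 rate matrix with a diagonal α (OU); the full-α variant is
  deliberately omitted to keep k small at n = 35 × 2.

Parameter counts entering AICc: univariate BM m+1, OU m+2; bivariate BM
3m+2, OU 2m+5 (m = number of regimes). n = species × traits. These counts
are part of the model definition here and are reported with every fit.

**Fitting.** Everything that can be profiled is profiled: the mean (root
state or regime optima) by GLS at each covariance evaluation, and the scalar
σ² of univariate OU analytically, leaving a 1-D problem in α solved by a
log-spaced grid (default 16 points across α ∈ [1e-4, 50]/tree-depth) plus
bounded Brent refinement — deterministic and strictly more reliable than
multi-start quasi-Newton in one dimension. Multi-parameter fits (multi-rate
BM, bivariate models) use L-BFGS-B on log-variances, atanh-correlations and
log-α with analytic gradients (verified against central differences to
~1e-6); the envelope theorem justifies differentiating at the profiled GLS
mean. Restarts default to 5 in `fit_model`; the replicated pipeline uses 2
with the smart initialization (closed-form single-rate and univariate
profiles), which is where the speed to run 50 iterations × 8 trait sets ×
6 models comes from. Degenerate situations are floored, not hidden: ML
variance estimates are bounded below at machine scale, and a regime absent
from a painting yields a least-squares (minimum-norm) optimum with its θ
effectively unidentified.

**Replication.** Iteration i pairs tree i (cycling), a 50% jackknife of each
species' deduplicated records (at least 2 kept), one island assignment, and
one stochastic map per character — propagating occurrence, tree and mapping
uncertainty jointly rather than crossing them. The summary reports the mean
weight and the 2.5/97.5 empirical percentiles over iterations. Failed
iterations are logged and skipped; more than 10% failures aborts the run.
The pipeline derives every random stream from the root seed via
`SeedSequence`-style keyed generators, so reruns are byte-identical.

## What the synthetic generator emulates

`generate_dataset` produces the full study shape: a 3458-pixel raster of 20
variables that are noisy mixtures of two latent climatic gradients (so two
PCs dominate, ~65–75% of variance at the default noise SD 0.8); four
contiguous islands of unequal size placed at *fixed* offsets in latent space
(so every island pair is environmentally distinct and "same island → more
similar available environments" is a stable, injectable property); a
birth–death tree (birth 1.0, death 0.5 per unit depth) rescaled to depth 1
with a pseudo-posterior of lognormally branch-jittered, re-ultrametricized
copies; Mk histories for island (symmetric) and pollination (ARD) with a
20 : 14 : 1 observed/inferred/unknown mode mix and four two-island species;
and niche centers and log-breadths evolving under a single-optimum OU
process (half-life 0.2 × depth; breadth optimum 1.2 PC units, chosen so
niches span an appreciable part of an island's environmental envelope —
with much narrower niches the island-availability effect on realized niches
vanishes). Occurrences (6–116 per species; pollinators 8–120) are drawn
with probability proportional to an isotropic Gaussian at each pixel's
scores, restricted to the species' islands, and centers are clipped into
their islands' score box — the realized-niche analogue of being limited by
what the island offers, and necessary for narrow-niche species to survive
the 5-pixel filter.

Trait values are drawn from the exact model-implied multivariate normal
(Cholesky of the closed-form covariance), never from discretized SDE paths.

What it does *not* emulate: spatial autocorrelation or collector bias
beyond per-pixel duplication (pixels are exchangeable within the niche
density), georeferencing error structure, climate-variable semantics,
observation-driven pollinator effort, or a genuine MCMC tree posterior (the
pseudo-posterior is branch noise around one true tree). Passing tests
therefore demonstrate the statistical machinery, not robustness to these
real-data pathologies.

An important and intended consequence of the island construction: *measured*
niche identity is shaped both by the heritable niche center and by island
availability. Island-regime models (BM4/OU4) can therefore legitimately
attract weight on identity traits in the synthetic pipeline even though the
generating process for the underlying centers is single-optimum OU; breadth
traits are less island-bound and tend to select OU1.

## Known limitations

- **BM/OU selection at small n.** With 35 tips and α allowed up to
  50/tree-depth, AICc-based selection spuriously prefers OU over BM-generated
  data in a substantial minority of datasets (~30% in our recovery
  experiments): a weak-signal BM realization is well mimicked by a
  near-white-noise OU, and regime-mean OU (and huge-rate regime BM) models
  can absorb clade effects produced by drift. This is a property of the
  model set and sample size, not of the optimizer — on offending datasets
  the profile fits match independent derivative-free ML to 4 decimals, and
  all likelihoods match brute-force path-enumeration oracles to 1e-8. At
  this n, weights for constrained models should be read as evidence
  *ratios*, not as error-free selections.
- Multi-regime BM with freely varying rates can fit a near-degenerate
  covariance (one regime rate → very large on deep shared branches, acting
  as a free clade offset). The fits are genuine ML; interpret BM3/BM4 wins
  with that pathology in mind.
- The overlap regression treats pairs as independent observations; p-values
  are anti-conservative to an unquantified degree.
- The 1st-percentile availability floor, R = 100 and Silverman bandwidths
  are conventional defaults, all configurable; D values shift slightly with
  these choices, their comparison across pairs much less.
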