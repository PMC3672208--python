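# Methods

## Data model

The analysis unit is a replicated point-referenced chamber dataset: `Q`
chambers at planar metre coordinates inside a small field, each measured
for `M` replicates (months), giving fluxes `y_ir` (µg N₂O-N m⁻² hr⁻¹) and
seven covariates in the fixed order moisture, temperature, NO₃⁻, pH, sand,
silt, clay. Fluxes are right-skewed and are analysed as `log(y + c)`;
`c = 0` when all fluxes are positive, otherwise half the smallest positive
flux (recorded in the dataset metadata and configurable). Replicates are
treated as exchangeable given the site: the site effect is indexed by site
only, and residuals are i.i.d. across sites and replicates. No temporal
autocorrelation is modelled.

## Spatial structures

Two derived structures feed the models:

* **Distance matrix** — Euclidean pairwise distances; its distinct-pair
  minimum and maximum also set the decay-rate prior (below).
* **Thiessen adjacency** — Voronoi cells of the chamber locations, clipped
  to the field rectangle expanded by 10% per side, with `w_ij = 1` iff two
  clipped cells share an edge longer than 1 nm. The margin is configurable;
  adjacency among interior sites is insensitive to it, and the expansion
  only prevents the field edge from truncating boundary-cell contacts.
  Cells that touch at a single point (the four-corner degeneracy) are not
  neighbours. All-collinear layouts degrade to a 1-D chain with a warning.
  Implementation uses `scipy.spatial.Voronoi` with distant ghost sites (so
  every real cell is finite) and `shapely` clipping; the test suite checks
  it against an exhaustive bisector-interval oracle.

## The three regression models

All models share `y_ir = β₀ + x_irᵀβ + z_i + ε_ir`, `ε ~ N(0, σ²)`, with
diffuse `N(0, 10⁶)` priors on all coefficients and `σ ~ U(0,5)`.

* **independent**: `z = 0`.
* **exp**: `z = s ~ N(0, σ_s² Φ(θ))`, `Φ_ij = exp[−(θ d_ij)^δ]`, `δ = 1`
  (the exponential member of the decay family; other shapes are out of
  scope). `θ ~ U(θ_lo, θ_hi)` with `θ_lo = −ln(ρ)/d_max`,
  `θ_hi = −ln(ρ)/d_min`, `ρ = 0.05`: the prior spans decay rates for which
  spatial correlation has fallen to 0.05 somewhere between the closest and
  the farthest chamber pair.
* **icar**: `z = u` with the intrinsic CAR prior
  `u_i | u_−i ~ N(Σ_j w_ij u_j / w_i+, σ_u²/w_i+)` on binary first-order
  weights, `σ_u ~ U(0,10)`. The intrinsic prior is improper; draws are
  identified by recentring `u` to sum to zero after every sweep, and the
  intercept carries the level.

The prior for the GP standard deviation σ_s is not pinned down by the
conventions the other two scale priors follow; we use `U(0,10)`, matching
σ_u, since both play the same role as spatial-effect scales. All priors are
configurable through `Priors`.

## Samplers

Each model has a bespoke sampler with Gaussian full conditionals for `β`,
`s` (jointly) and `u` (single-site sweeps), exposed as standalone functions
so tests can verify them against closed forms:

* `β | ·` — ridge/GLS form `(XᵀX/σ² + I/10⁶)⁻¹ Xᵀr/σ²`.
* `s | ·` — precision `Φ⁻¹/σ_s² + (M/σ²)I`, mean precision-weighted from
  per-site residual sums.
* `u_i | ·` — normal-normal blend of the neighbour average (precision
  `w_i+/σ_u²`) with the site likelihood (precision `M/σ²`).

Standard deviations (σ, σ_s, σ_u) are sampled on the SD scale by shrinkage
slice sampling on their bounded uniform supports — no Jacobian bookkeeping
against the stated priors. θ uses random-walk Metropolis restricted to its
support, with the step size adapted every 100 iterations during burn-in
toward ≈35% acceptance and frozen afterwards to preserve detailed balance.
Correlation matrices get a 1e-8 diagonal jitter on Cholesky failure.

The design matrix check rejects only exact singularities (identical or
all-zero columns). The compositional texture triplet sums to exactly 100
and is therefore exactly collinear with the intercept; the diffuse normal
prior keeps that posterior proper, and erroring on numerical rank would
reject the very design this analysis targets. The texture coefficients are
correspondingly only jointly identified — their individual posteriors are
prior-dominated in one direction, which is visible as very wide credible
intervals.

Defaults follow the emulated study: 150,000 iterations, 50,000 burn-in,
single chain; thinning 10 bounds memory. The test and acceptance
simulations use 15,000/5,000 (recovery) and 6,000/2,000 (model-selection)
chains with Q=17, M=13 — chosen as the smallest runs at which the
diagnostics of interest are stable.

### Deviance convention

The DIC deviance is computed **conditional on the latent site effects**:
`D = −2 Σ log N(y_ir | μ_ir, σ²)` with `μ_ir` including `s_i`/`u_i`. This
is the random-effects-focused deviance conventional for these hierarchical
models; marginalising the site effects would change pD and hence DIC, so
DIC values are only comparable across models computed under the same focus
(as all three here are).

## Model averaging

`p(M_l | D) ∝ p(M_l) exp(−DIC_l/2)` with equal 1/3 priors by default,
computed with min-subtraction in log space. Averaged posterior quantities
are **mixtures**, not moment averages: each averaged draw picks a model
with probability equal to its weight, then one of that model's retained
draws. The mixture mean equals the weighted mean, while the mixture
variance adds the between-model spread (law of total variance) — averaging
means alone would understate uncertainty.

## Prediction and kriging

Posterior predictive draws are `μ_ir + N(0, σ²)` per retained draw;
site-level summaries aggregate the replicate dimension. Fit diagnostics
are the fraction of observations outside their 95% predictive intervals
and the sum of squared residuals on the log scale.

Surfaces are produced by kriging the per-site posterior summaries (the
predicted log-flux, and the posterior-mean spatial effect for the
variation maps) rather than kriging every posterior draw; per-draw kriging
is available (`krige_per_draw`) for uncertainty propagation. The
variogram is an exponential model `γ(h) = c₀ + c₁(1 − e^{−h/a})` fitted by
pair-count-weighted least squares to a binned method-of-moments
semivariogram over lags up to half the maximum pair distance (the
conventional window; beyond it bins hold too few pairs). Effective range
is `3a`. A constant field short-circuits to a degenerate pure-nugget
model. Ordinary kriging solves the standard system with the Σλ = 1
unbiasedness constraint (asserted at every node); with a zero nugget the
surface interpolates the site values exactly and has zero kriging variance
there. Covariate-based prediction at unsampled locations is out of scope —
off-site covariate values are by construction unavailable — which is
precisely why interpolation falls back to kriging.

## Synthetic-data generator

The generator emulates the study design the models were built for:

* **Layout** — Q=17 points uniform in a 16.5 × 16.5 m field (≈272 m²),
  rejection-sampled to a 0.75 m minimum separation (chamber diameter
  scale), deterministic given the seed.
* **Covariates** — site-static pH and texture; replicate-varying moisture,
  temperature and NO₃⁻ built from a site offset (15% of variance), one
  shared sinusoidal 12-month seasonal wave (35%) and independent noise
  (50%), all scaled to published means/SDs and clipped to published
  ranges; texture renormalised to sum to 100. The variance split is a
  design choice: monthly sampling over a year implies seasonality, and
  recovery tests need within-site covariate variation; the exact fractions
  are not identified by any published summary.
* **Fluxes** — generated on the log scale from any of the three models and
  exponentiated. Default generative parameters are the fitted values of
  the emulated study (moisture 0.055, temperature 0.16, NO₃⁻ −0.018, pH
  0.4, small texture effects, σ² = 1.6, σ_s² = 0.76, θ = 1.0, σ_u² = 1.78),
  with β₀ = −7.5 putting the mean natural-scale flux near the observed
  ≈27 µg N₂O-N m⁻² hr⁻¹. ICAR truth is drawn on the sum-to-zero subspace
  via the eigendecomposition pseudo-inverse of the intrinsic precision. A
  configurable back-shift produces occasional exact zeros to exercise the
  log-shift path.

What the generator does **not** emulate: temporal autocorrelation of
fluxes between months, measurement error in covariates, anisotropy, and
non-Gaussian log-flux tails. Passing recovery tests therefore demonstrate
correctness of the samplers under the assumed model, not robustness to
real-data misspecification.

## Numerical choices

* Shared Voronoi edges shorter than 1e-9 m are point contacts, not
  boundaries (deterministic tie-break of the four-corner degeneracy).
* Coincident chamber coordinates are an error (they break the θ prior).
* All randomness descends from one seed per operation via
  `numpy.random.SeedSequence` spawning; identical seed + configuration
  reproduce byte-identical samples CSVs.
* Slice sampling falls back to the current value after 200 shrinkage steps
  (only reachable in pathological flat-likelihood corners).
* Kriging variances are floored at zero against roundoff; singular kriging
  systems get a 1e-10 jitter before erroring.

## Known limitations

* Single-chain convergence checking (traces, autocorrelation, split-chain
  z) as in the emulated workflow; no multi-chain R-hat.
* DIC is convention-dependent (see deviance focus above); comparisons with
  DIC values computed under a marginal focus are not meaningful.
* The ICAR variance σ_u² is weakly identified at Q ≈ 17; its posterior is
  prior-influenced and recovery is only reliable to within a factor of ~2.
* The field boundary used to clip Thiessen polygons is a construction of
  this package (the physical field edge), and boundary-cell adjacency
  depends mildly on it.
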