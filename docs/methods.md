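# Methods

## Model

The observation model is a latent-Gaussian count regression.  Counts
`y(s,t)` (one per trawl set) are Poisson or negative binomial; for the NB
the size parameter is `n = exp(φ)` and the variance is `μ(1 + μ/n)`.
Both families use a log link (the identity-link Gaussian family exists as
a conjugate test harness only).  The linear predictor is

    η(s,t) = β₀ + ξ(s,t) + Σⱼ fⱼ(cⱼ(s,t)).

An explicit intercept β₀ is included; without it the log-mean would be
pinned to the field's zero mean.  Covariate smooths are piecewise linear
on equal-quantile knots (default 25, reduced when the covariate has few
distinct values) with a second-order random-walk penalty and a soft
sum-to-zero constraint so they remain identifiable next to the intercept.
Covariate pairs with |Pearson r| ≥ 0.9 are refused in the same model, and
`collinearity_screen` enumerates the maximal admissible subsets.

The latent field `ξ` is an AR(1) chain of Matérn fields.  σ is defined as
the **stationary** marginal SD of the chain, so the innovation SD is
σ√(1−a²); this makes σ comparable between the joint AR(1) fit and the
per-year fits, which have no persistence term.  Smoothness is fixed at
ν = 1 in d = 2 (SPDE order α = 2).  The reported range is ρ = √(8ν)/κ,
the distance at which the correlation has fallen to √8·K₁(√8) = 0.1397 —
the conventional "approximately 0.1".  C(0) := 1 by continuity.

## Discretisation

The domain triangulation is built from the data locations: positions
within `cutoff` of each other merge to their centroid (greedy, input
order; merging is aggressive by default when fitting, `cutoff =
max_edge/3`, because observations are projected onto the mesh and need
not sit on vertices).  The convex hull is buffered outward by
`offset_factor · max_edge` (default factor 1) to push the Neumann
boundary away from the data; straight stretches of the buffered boundary
are subdivided with a slight outward bulge because qhull silently drops
exactly-collinear hull points, which would otherwise leave unsplittable
long edges.  The interior is seeded with a hexagonal lattice at
0.8·max_edge and long edges are bisected (with a deterministic jitter off
the edge, for the same qhull reason) until every edge of the
sliver-filtered triangulation is ≤ max_edge.  Triangles with interior
angle < 0.5° — hairline slivers that only ever occur along the curved
hull — are dropped, so 0.5° is the effective mesh-quality floor.

Mass lumping keeps `G C⁻¹ G` sparse, giving the standard precision
`Q_s = τ²(κ⁴C + 2κ²G + GC⁻¹G)` with `τ = 1/(σκ√(4π))` so the stationary
marginal SD is σ.  On a ≤600-vertex unit-square mesh with edge ≈ 0.17ρ
the implied correlations track the closed-form Matérn within 0.05
(discretisation error concentrates at lags of one to two edge lengths).
The space-time precision is `Q = Q_ar1(a) ⊗ Q_s` with the AR(1) factor
scaled to unit stationary marginal variance, so every vertex-year has
marginal SD σ and the innovation variance is σ²(1−a²) by construction.

## Priors

Penalised-complexity priors shrink toward the base model ρ = ∞, σ = 0:
π(ρ) = λ_ρ ρ⁻² exp(−λ_ρ/ρ) with λ_ρ = −log(α_ρ)·ρ₀ (d = 2), and an
exponential on σ with rate λ_σ = −log(α_σ)/σ₀.  Defaults are the
reference calibration ρ₀ = 0.5, α_ρ = 0.5, σ₀ = 0.75, α_σ = 0.5.  The
remaining priors are declared defaults, not estimates from any earlier
analysis: Normal(0, 2²) on the Fisher transform z = log((1+a)/(1−a)),
Normal(0, 5²) on φ, and Gamma(1, 10⁻³) on each smoothing precision.

## Inference

Inner step: Newton ascent on the latent vector (field weights, smooth
coefficients, intercept) with step halving; the gradient tolerance is
scaled by ‖y‖ so convergence is meaningful for counts in the thousands.
The curvature at the mode gives the Gaussian (Laplace) approximation with
precision `Q_prior + XᵀWX`.  Factorisations use a banded Cholesky under a
reverse-Cuthill-McKee permutation computed once per model structure:
unlike a general sparse LU with numerical pivoting, its cost and memory
are deterministic functions of the sparsity pattern, which matters when
an optimizer wanders into badly scaled corners of the hyperparameter
space.  The prior log-determinant is assembled in closed form
(Kronecker identity, AR(1) determinant (1−a²)^−(T−1), and
`log det Q_s = 2n log τ + 2 log det(κ²C+G) − log det C`).

Outer step: the approximate hyperparameter posterior (Laplace evidence
plus priors) is maximised by two Nelder-Mead stages with explicit initial
simplices (0.6 then 0.2 steps on the transformed scale; the default
simplex steps are far too small for a log-scale space, and the restart
recovers from premature simplex collapse).  Around the mode an axial grid
(±0.5 per coordinate) is evaluated and softmax-weighted; hyper summaries
and DIC average over this grid.  Latent marginal variances are taken from
the mode-θ Gaussian with the between-grid spread of the conditional modes
added — a deliberate simplification of full nested-Laplace integration,
adequate for point estimates and interval coverage at desk scale (the
test suite checks ≥90% empirical coverage of nominal 95% intervals).
A persistence estimate with |a| > 0.995 sets a boundary warning on the
result instead of being clamped.

Degenerate inputs: fewer than three distinct (post-merge) locations or
collinear locations are rejected; zero-area triangles raise; locations
outside the mesh raise in fitting but are returned masked (NaN) in
prediction; a hyperparameter evaluation that fails to converge or to
factorise is treated as −∞ posterior during optimisation.

## Assessment

DIC: expected deviance by Monte Carlo over the grid-mixture Gaussian
(seeded), p_D = E[D] − D(posterior mean), DIC = E[D] + p_D; negative p_D
(possible under the Laplace approximation) warns, never errors.  CPO:
observations are partitioned into W seeded equal folds; the model
(hyperparameters and latent field) is refit without each fold and each
held-out observation's predictive density is evaluated under its own
fold's fit, integrating the count likelihood over the η marginal by
Gauss-Hermite quadrature (analytic for the Gaussian harness).  With
W = n this is exact leave-one-out, which the tests verify against the
conjugate closed form.  The default W corresponds to 5% folds (W = 20).
LPML = Σ log CPO.  RMSEE compares counts with fitted response-scale means
`exp(η_mean + η_var/2)` (plug-in `exp(η_mean)` by flag).  Densities that
underflow are floored at 1e-300 with a warning count.

## Stock-structure diagnostics

Relative exploitation RE(i,t) divides a sub-zone's landings share by its
survey-abundance share; a zone with positive landings but zero survey
abundance is flagged undefined (NaN, never infinity) and years with zero
totals are excluded with a warning.  Annual `(ρ_t, σ_t)` come from
per-year refits with a single spatial field and no persistence; years
with fewer than `min_sets` (default 30) sets or failed fits are marked
missing, and ρ_t larger than the domain diameter is flagged, never
clamped.  Core-range masks threshold predicted abundance at the pooled
(across-years) quantile — default 0.75 — so contraction is visible;
per-year thresholds are available by flag.  Patches are 8-connected
components; separations are centroid distances, also in multiples of a
supplied ρ̂.

The erosion classifier works on log-scale movements (Δlog ρ, Δlog σ)
with thresholds δ = log 1.5 by default (a 50% change counts as "large").
A movement is **erosion** when at least one axis moves beyond its
threshold toward the flattened-field corner (ρ up, σ down) and the other
axis does not oppose it; **recovery** is the exact mirror, so reversing
time swaps the labels; movements inside both thresholds are
**fluctuation**; large opposing movements are reported as **stable**.
Requiring *both* axes to exceed log 1.5 was rejected because documented
erosion episodes (e.g. ρ rising 2.9× while σ falls only 1.27×) would be
missed; the one-large-axis rule captures them while time-reversal
symmetry is preserved.

## Synthetic data

`simulate_survey` draws the latent chain sequentially (one spatial
Cholesky, reused), places sets stratified-randomly over three vertical
sub-zones with effort proportional to zone area, and samples counts by a
gamma-Poisson mixture (valid for non-integer NB size).  Defaults emulate
the target survey: 200 sets/year over 40 years on an irregular ~3°×1°
shelf polygon, ρ = 0.3, σ = 1.5, a = 0.6, φ = 1, intercept 2 (typical
sets of tens of fish), and an optional west-east bottom-temperature
gradient whose effect declines with warming.  Counts up to the
ten-thousands per set are reachable with intercept ≈ 7, σ ≈ 3.

`simulate_collapse` builds the deterministic surface from three
flat-topped bumps (quartic profile, so the plateau maximum is exactly the
configured height for any width) over a smooth large-scale background
field (range 1.2°, SD 0.5).  Through the collapse window every bump
width contracts by the configured factor (default 0.4) per year and the
middle bump is removed at the window midpoint.  The attached truth
records the per-year maximum (constant by construction) and the analytic
occupied area — the half-maximum cross-section Σ πw²√(ln 2), which
decreases strictly through the window; a grid-based fraction above the
pooled 75th percentile is stored alongside.  The half-maximum definition
is used for the exact truth because any grid-quantile version quantises
once the bumps shrink below cell size.  Bump and background scales were
chosen once so that pre-collapse annual fits see moderate ρ (set by bump
diameter) and post-collapse fits see the smooth background (large ρ,
small σ): the erosion signature then emerges from the fits rather than
being injected.

`simulate_landings` allocates annual landings across zones proportionally
to (zone abundance)^targeting: targeting 0 spreads evenly, 1 yields
RE ≈ 1 everywhere, > 1 concentrates effort on dense zones.

### What the generator does not emulate

Vessel and catchability effects, within-year movement, swept-area
offsets, zero-inflation beyond the NB, and measurement error in
positions.  Passing tests therefore demonstrate internal consistency of
the method under its own assumptions and the detectability of engineered
erosion — not performance on any real survey.

## Problem sizes and study settings

The simulation studies in the test suite use desk-scale versions of the
study conditions: parameter recovery at 150 sites × 10 years on a unit
square (20 seeds; mesh edge 0.16, merge cutoff 0.08, 100 evidence
evaluations per fit), zero-persistence recovery at 100 sites × 6 years,
and the collapse study at 150 sets × 6 years with a 4-year window.
Annual refits use 60 evidence evaluations.  These sizes were chosen so
the full suite runs on a single CPU in well under half an hour while
leaving the acceptance margins (30% relative on ρ and σ, ±0.15 on a)
comfortably met.

## Known limitations

* Hyperparameter uncertainty is summarised by an axial grid, not a full
  integration; skewed posteriors (notably for ρ with few years) are
  under-represented.
* The annual ρ_t is weakly identified once the field is nearly flat; the
  series is reported with convergence status rather than smoothed, and
  values beyond the domain diameter are only flagged.
* Coordinates are treated as planar degrees (no great-circle correction),
  matching how shelf-scale ranges are conventionally reported; at high
  latitudes the implied anisotropy is not corrected.
* The Laplace approximation can produce negative DIC p_D on small counts;
  this is warned about and left visible.
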