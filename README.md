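# spatstock

Bayesian spatio-temporal modelling of fish survey abundance, with the
spatial stock-structure diagnostics needed to detect *local overfishing* —
the serial depletion of high-density patches that can hide behind stable
catch rates until a stock collapses.

`spatstock` is written for quantitative fisheries scientists working with
annual trawl-survey count data (one count per trawl set, with coordinates,
year and optional covariates such as bottom temperature or bathymetry) and
annual landings by management sub-zone.

## The model

Counts `y(s,t)` at location `s` in year `t` follow a Poisson or negative
binomial distribution (NB variance `μ(1 + μ/n)` with size `n`) whose log
mean is

```
log μ(s,t) = β₀ + ξ(s,t) + Σⱼ fⱼ(cⱼ(s,t))
```

where the `fⱼ` are penalised piecewise-linear smooths of covariates and
`ξ(s,t)` is a latent Gaussian field with AR(1) persistence across years,

```
ξ(s,t) = a·ξ(s,t−1) + ω(s,t),     |a| < 1,
```

whose spatial innovations have a Matérn (ν = 1) correlation
`C(h) = (κh)·K₁(κh)`.  The field is discretised on a triangulation by the
SPDE/finite-element approach, giving a sparse precision matrix
`Q = τ²(κ⁴C + 2κ²G + GC⁻¹G)` over the vertex weights.  Three
hyperparameters summarise stock structure:

* **connectivity ρ = √8/κ** — the distance (degrees) at which spatial
  correlation drops to ≈ 0.1; large ρ means a flat, structureless field;
* **spatial variance σ** — the stationary marginal SD of `ξ`; the contrast
  between high- and low-density areas;
* **persistence a** — how strongly this year's spatial pattern repeats
  last year's.

Penalised-complexity priors shrink toward the structureless base model
(ρ = ∞, σ = 0), calibrated by `P(ρ < 0.5) = 0.5` and
`P(σ > 0.75) = 0.5`.  Fitting is a nested-Laplace scheme: a Newton inner
loop gives the Gaussian approximation of the latent field, and the
hyperparameter posterior is explored by empirical-Bayes optimisation plus
a small axial grid.  Models are compared with DIC, W-fold CPO/LPML and
RMSEE.

The diagnostics layer turns the model into a monitoring tool: relative
exploitation `RE(i,t)` (a sub-zone's landings share over its survey-
abundance share), per-year refits giving an annual `(ρ_t, σ_t)` series,
75th-percentile core-range masks with patch areas and separations, and a
classifier that labels each year-to-year movement of `(ρ_t, σ_t)` as
*erosion* (ρ up, σ down — structure being fished flat), *recovery* (the
mirror image), *fluctuation* or *stable*.

A synthetic-survey generator emulates the target data (≈200 trawl sets
per year on an irregular shelf domain, counts from zero to thousands per
set), including collapse scenarios in which core aggregations keep their
peak density but lose extent — hyperstability by construction — so every
claim the package makes is testable without any survey download.

## Worked example

```python
from shapely.geometry import box
from spatstock import ModelSpec, fit_model
from spatstock.simulate import ScenarioConfig, simulate_survey

config = ScenarioConfig(domain=box(0, 0, 1, 1), n_years=6, sets_per_year=120,
                        rho=0.3, sigma=1.5, a=0.6, phi=1.0, intercept=2.0,
                        temperature=False, seed=7, mesh_max_edge=0.1)
data = simulate_survey(config)
fit = fit_model(data, ModelSpec(spatial_structure="ar1"),
                max_edge=0.16, cutoff=0.08, maxfev=100, grid=False,
                compute_marginals=False)
print(fit.hyper_mode.as_dict())
```

Running this (it is `examples/02_simulate_and_fit.py`) prints

```
simulated 720 sets over 6 years; counts 0..1237
                true   fitted
rho            0.300    0.361
sigma          1.500    1.548
a              0.600    0.626
phi            1.000    0.615
```

— the connectivity, spatial variance and persistence of the generating
process are recovered from six years of survey counts alone.  The other
scripts in `examples/` demonstrate the prior calibration, DIC/RMSEE model
comparison, and the erosion diagnostics on a simulated collapse (where
the annual series shows ρ_t rising and σ_t falling through the collapse
window, and the classifier prints `erosion` labels).

A thin CLI mirrors the library:
`spatstock simulate|fit|assess|annual|diagnose|predict` (see `--help`).

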