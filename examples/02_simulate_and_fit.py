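"""Simulate a small survey and refit the generating model.

Draws a six-year negative-binomial trawl survey from the AR(1)-Matérn
generative model on a unit-square domain, fits the full spatio-temporal
model, and prints the estimated hyperparameters next to the truth: rho is
the correlation range (degrees), sigma the marginal SD of the latent
log-density, a the year-to-year persistence and phi the log NB size.
"""

from shapely.geometry import box

from spatstock import ModelSpec, fit_model
from spatstock.simulate import ScenarioConfig, simulate_survey

config = ScenarioConfig(
    domain=box(0, 0, 1, 1),
    n_years=6,
    sets_per_year=120,
    rho=0.3,
    sigma=1.5,
    a=0.6,
    phi=1.0,
    intercept=2.0,
    temperature=False,
    seed=7,
    mesh_max_edge=0.1,
)
data = simulate_survey(config)
print(f"simulated {len(data)} sets over {config.n_years} years; "
      f"counts {int(data.counts.min())}..{int(data.counts.max())}")

spec = ModelSpec(spatial_structure="ar1", family="negative_binomial")
fit = fit_model(data, spec, max_edge=0.16, cutoff=0.08, maxfev=100, grid=False,
                compute_marginals=False)

h = fit.hyper_mode
print(f"{'':12s}{'true':>8s}{'fitted':>9s}")
print(f"{'rho':12s}{config.rho:8.3f}{h.rho:9.3f}")
print(f"{'sigma':12s}{config.sigma:8.3f}{h.sigma:9.3f}")
print(f"{'a':12s}{config.a:8.3f}{h.a:9.3f}")
print(f"{'phi':12s}{config.phi:8.3f}{h.phi:9.3f}")
print("(estimates are empirical-Bayes modes; agreement improves with effort/years)")
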