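"""Shared fixtures.

The expensive simulation studies (parameter recovery, zero-persistence
recovery, collapse-erosion) are session-scoped so that module tests and
the acceptance suite measure the same runs instead of re-simulating.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import settings

from shapely.geometry import box

from spatstock import ModelSpec, build_mesh, fem_matrices, fit_model
from spatstock.diagnostics import annual_parameter_series, erosion_classify
from spatstock.simulate import ScenarioConfig, simulate_collapse, simulate_survey

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

N_STUDY_SEEDS = 20


def unit_square_lattice(spacing: float) -> np.ndarray:
    """Triangular lattice covering the unit square (mesh test scaffold)."""
    xs = np.arange(0, 1 + spacing, spacing)
    ys = np.arange(0, 1 + spacing * np.sqrt(3) / 2, spacing * np.sqrt(3) / 2)
    pts = []
    for i, y in enumerate(ys):
        off = spacing / 2 if i % 2 else 0.0
        for x in xs:
            pts.append((min(x + off, 1.0), y))
    return np.unique(np.array(pts), axis=0)


@pytest.fixture(scope="session")
def small_mesh():
    rng = np.random.default_rng(11)
    return build_mesh(rng.uniform(0, 1, (60, 2)), max_edge=0.25, cutoff=0.02)


@pytest.fixture(scope="session")
def small_fem(small_mesh):
    return fem_matrices(small_mesh)


@pytest.fixture(scope="session")
def small_survey():
    """Ten-year unit-square survey at reduced effort, NB counts."""
    cfg = ScenarioConfig(
        domain=box(0, 0, 1, 1),
        n_years=6,
        sets_per_year=40,
        temperature=True,
        seed=5,
        start_year=1990,
        mesh_max_edge=0.12,
    )
    return simulate_survey(cfg)


def _recovery_conditions(seed: int) -> ScenarioConfig:
    """The recovery-study conditions: 150 sites x 10 years, rho 0.3,
    sigma 1.5, a 0.6, phi 1.0, on a unit-square domain."""
    return ScenarioConfig(
        domain=box(0, 0, 1, 1),
        n_years=10,
        sets_per_year=150,
        rho=0.3,
        sigma=1.5,
        a=0.6,
        phi=1.0,
        intercept=2.0,
        temperature=False,
        seed=seed,
        start_year=1990,
        mesh_max_edge=0.1,
    )


def _vertex_year_coverage(fit, data) -> float:
    """Fraction of vertex-years whose nominal 95% interval for the latent
    eta (field + intercept) covers the true simulated value."""
    from spatstock import projection_matrix

    mats = fit.matrices
    n, T = mats.n_vert, mats.n_years
    proj = projection_matrix(data.truth["mesh"], fit.mesh.vertices, allow_outside=True)
    intercept_true = data.truth["config"].intercept
    cov = fit.latent_covariance()
    hits = []
    for t in range(T):
        true_eta = intercept_true + proj.matrix @ data.truth["vertex_fields"][t]
        sl = slice(t * n, (t + 1) * n)
        mean = fit.latent_mean[sl] + fit.latent_mean[-1]
        var = np.diag(cov)[sl] + cov[-1, -1] + 2 * cov[sl, -1]
        sd = np.sqrt(np.maximum(var, 0.0))
        ok = (true_eta >= mean - 1.96 * sd) & (true_eta <= mean + 1.96 * sd)
        hits.append(ok[proj.inside])
    return float(np.mean(np.concatenate(hits)))


@pytest.fixture(scope="session")
def recovery_study():
    """Fit the AR(1) model to 20 of its own simulations; collect estimates,
    true values and latent-interval coverage of the true field at the
    mesh vertex-years."""
    rows = []
    spec = ModelSpec(spatial_structure="ar1", family="negative_binomial")
    for seed in range(N_STUDY_SEEDS):
        data = simulate_survey(_recovery_conditions(seed))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_model(
                data,
                spec,
                max_edge=0.16,
                cutoff=0.08,
                grid=False,
                compute_marginals=True,
                maxfev=100,
            )
        h = fit.hyper_mode
        rows.append(
            {
                "seed": seed,
                "rho": h.rho,
                "sigma": h.sigma,
                "a": h.a,
                "phi": h.phi,
                "coverage": _vertex_year_coverage(fit, data),
            }
        )
    return rows


@pytest.fixture(scope="session")
def zero_persistence_study():
    """Same harness with a* = 0 at reduced size: the persistence estimate
    should stay near zero."""
    rows = []
    spec = ModelSpec(spatial_structure="ar1", family="negative_binomial")
    for seed in range(N_STUDY_SEEDS):
        cfg = ScenarioConfig(
            domain=box(0, 0, 1, 1),
            n_years=6,
            sets_per_year=100,
            rho=0.3,
            sigma=1.5,
            a=0.0,
            phi=1.0,
            intercept=2.0,
            temperature=False,
            seed=100 + seed,
            start_year=1990,
            mesh_max_edge=0.1,
        )
        data = simulate_survey(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_model(
                data,
                spec,
                max_edge=0.16,
                cutoff=0.08,
                grid=False,
                compute_marginals=False,
                maxfev=80,
            )
        rows.append({"seed": seed, "a": fit.hyper_mode.a})
    return rows


def collapse_conditions(seed: int) -> ScenarioConfig:
    """Desk-scale collapse study: 2 stable years then a 4-year window in
    which bump extent contracts by 0.4/year and the middle bump is fished
    out, over a smooth large-scale background."""
    return ScenarioConfig(
        n_years=6,
        sets_per_year=150,
        collapse_window=(3, 6),
        intercept=1.0,
        temperature=False,
        seed=seed,
    )


@pytest.fixture(scope="session")
def collapse_study():
    """Simulate -> annual fits -> classify, for 20 seeds."""
    rows = []
    for seed in range(N_STUDY_SEEDS):
        data = simulate_collapse(collapse_conditions(seed))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traj = annual_parameter_series(data, max_edge=0.3, maxfev=60)
            labelled = erosion_classify(traj)
        rows.append(
            {
                "seed": seed,
                "series": traj.series,
                "transitions": labelled.transitions,
                "truth": data.truth,
            }
        )
    return rows
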