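"""Matérn correlation, SPDE precision, AR(1) coupling and PC priors."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad
from scipy.spatial import distance_matrix

from spatstock import (
    PcPrior,
    SpdeParams,
    TemporalParams,
    ar1_precision,
    build_mesh,
    fem_matrices,
    kappa_from_range,
    matern_correlation,
    pc_prior_log_density,
    range_from_kappa,
    sample_field,
    spacetime_precision,
    spatial_precision,
    tau_from_sigma,
)
from spatstock.errors import StationarityError
from spatstock.field import ar1_logdet, sigma_from_tau, spatial_precision_logdet


class TestMaternCorrelation:
    def test_zero_lag_is_one(self):
        assert matern_correlation(0.0, kappa=2.0) == 1.0

    def test_huge_lag_vanishes(self):
        assert matern_correlation(1e6, kappa=1.0) < 1e-12

    def test_value_at_empirical_range(self):
        """At h = sqrt(8 nu)/kappa the nu=1 correlation is 0.1397 (the
        conventional 'approximately 0.1' range definition)."""
        for kappa in (0.5, 1.0, 8.812):
            h = math.sqrt(8.0) / kappa
            assert matern_correlation(h, kappa) == pytest.approx(0.1397, abs=5e-5)

    @given(st.floats(0.01, 50.0), st.floats(0.1, 10.0))
    def test_monotone_decreasing(self, h, kappa):
        assert matern_correlation(h, kappa) >= matern_correlation(h * 1.3, kappa)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            matern_correlation(-1.0, kappa=1.0)


class TestRangeScaleIdentities:
    def test_kappa_at_sqrt8_range(self):
        assert kappa_from_range(math.sqrt(8.0)) == pytest.approx(1.0, abs=1e-12)

    def test_kappa_for_reported_range(self):
        # rho = 0.321 degrees -> kappa = sqrt(8)/0.321
        assert kappa_from_range(0.321) == pytest.approx(8.812, abs=5e-3)

    @given(st.floats(1e-3, 1e3))
    def test_round_trip(self, rho):
        assert range_from_kappa(kappa_from_range(rho)) == pytest.approx(rho, rel=1e-12)

    def test_tau_for_unit_sigma_unit_kappa(self):
        assert tau_from_sigma(1.0, 1.0) == pytest.approx(1.0 / math.sqrt(4 * math.pi), abs=1e-5)

    def test_tau_inversely_proportional_to_sigma(self):
        assert tau_from_sigma(2.0, 1.3) == pytest.approx(tau_from_sigma(1.0, 1.3) / 2, rel=1e-12)
        assert sigma_from_tau(tau_from_sigma(1.7, 2.2), 2.2) == pytest.approx(1.7, rel=1e-12)

    def test_domain_errors(self):
        for bad in (0.0, -1.0):
            with pytest.raises(ValueError):
                kappa_from_range(bad)
            with pytest.raises(ValueError):
                tau_from_sigma(bad, 1.0)


@pytest.fixture(scope="module")
def fine_unit_mesh():
    rng = np.random.default_rng(2)
    return build_mesh(rng.uniform(0, 1, (250, 2)), max_edge=0.06, cutoff=0.006)


class TestSpatialPrecision:
    def test_large_kappa_mass_dominates(self, small_fem):
        kappa, tau = 1e5, 0.37
        Q = spatial_precision(kappa, tau, small_fem).toarray()
        lead = (tau**2 * kappa**4) * small_fem.mass.toarray()
        rel = np.linalg.norm(Q - lead) / np.linalg.norm(lead)
        assert rel < 1e-6

    def test_positive_definite(self, small_fem):
        spde = SpdeParams(rho=0.4, sigma=1.0)
        Q = spatial_precision(spde.kappa, spde.tau, small_fem).toarray()
        assert np.linalg.eigvalsh(Q).min() > 0

    def test_matches_matern_in_interior(self, fine_unit_mesh):
        """Correlations implied by Q_s^-1 track the closed-form Matérn."""
        fem = fem_matrices(fine_unit_mesh)
        spde = SpdeParams(rho=0.4, sigma=1.0)
        S = np.linalg.inv(spatial_precision(spde.kappa, spde.tau, fem).toarray())
        v = fine_unit_mesh.vertices
        idx = np.where((v[:, 0] > 0.3) & (v[:, 0] < 0.7) & (v[:, 1] > 0.3) & (v[:, 1] < 0.7))[0]
        D = distance_matrix(v[idx], v[idx])
        C = S[np.ix_(idx, idx)]
        corr = C / np.sqrt(np.outer(np.diag(C), np.diag(C)))
        sel = (D >= 0.06) & (D <= 0.6)
        err = np.abs(corr[sel] - matern_correlation(D[sel], spde.kappa))
        assert err.max() < 0.05

    def test_logdet_identity(self, small_fem):
        spde = SpdeParams(rho=0.5, sigma=1.3)
        Q = spatial_precision(spde.kappa, spde.tau, small_fem).toarray()
        sign, direct = np.linalg.slogdet(Q)
        assert sign > 0
        assert spatial_precision_logdet(spde.kappa, spde.tau, small_fem) == pytest.approx(
            direct, rel=1e-10
        )


class TestAr1Precision:
    def test_independence_is_identity(self):
        assert np.allclose(ar1_precision(0.0, 3).toarray(), np.eye(3))

    def test_half_persistence_hand_values(self):
        Q = ar1_precision(0.5, 3).toarray()
        expected = np.array(
            [[4 / 3, -2 / 3, 0.0], [-2 / 3, 5 / 3, -2 / 3], [0.0, -2 / 3, 4 / 3]]
        )
        assert np.allclose(Q, expected, atol=1e-12)

    def test_inverse_has_geometric_correlations(self):
        a, T = 0.627, 5
        cov = np.linalg.inv(ar1_precision(a, T).toarray())
        assert cov[0, T - 1] == pytest.approx(a ** (T - 1), abs=1e-10)
        for k in range(T):
            assert cov[k, k] == pytest.approx(1.0, abs=1e-10)

    def test_logdet_closed_form(self):
        a, T = 0.72, 7
        sign, ld = np.linalg.slogdet(ar1_precision(a, T).toarray())
        assert ar1_logdet(a, T) == pytest.approx(ld, rel=1e-12)

    @pytest.mark.parametrize("a", [1.0, -1.0, 1.5])
    def test_nonstationary_rejected(self, a):
        with pytest.raises(StationarityError):
            ar1_precision(a, 4)
        with pytest.raises(StationarityError):
            TemporalParams(a=a, n_years=4)

    def test_innovation_sd(self):
        tp = TemporalParams(a=0.627, n_years=18)
        assert tp.innovation_sd(3.39) == pytest.approx(3.39 * math.sqrt(1 - 0.627**2))


class TestSpacetimePrecision:
    def test_zero_persistence_is_block_diagonal(self, small_fem):
        spde = SpdeParams(rho=0.4, sigma=1.2)
        Q = spacetime_precision(spde, TemporalParams(a=0.0, n_years=3), small_fem).toarray()
        n = small_fem.n_vertices
        block = Q[:n, :n]
        for t in range(1, 3):
            assert np.allclose(Q[t * n : (t + 1) * n, t * n : (t + 1) * n], block)
            assert np.abs(Q[:n, t * n : (t + 1) * n]).max() == 0.0

    def test_marginal_variance_constant_over_time(self):
        mesh = build_mesh(np.random.default_rng(4).uniform(0, 1, (40, 2)), 0.35, 0.02)
        fem = fem_matrices(mesh)
        spde = SpdeParams(rho=0.5, sigma=1.0)
        Q = spacetime_precision(spde, TemporalParams(a=0.6, n_years=4), fem)
        S = np.linalg.inv(Q.toarray())
        n = fem.n_vertices
        interior = ~mesh.boundary_flags
        per_year = np.array(
            [np.diag(S)[t * n : (t + 1) * n][interior] for t in range(4)]
        )
        spread = per_year.max(axis=0) / per_year.min(axis=0) - 1.0
        assert spread.max() < 0.02

    def test_lag1_correlation_matches_persistence(self, small_fem):
        spde = SpdeParams(rho=0.4, sigma=1.0)
        a, T = 0.627, 2
        Q = spacetime_precision(spde, TemporalParams(a=a, n_years=T), small_fem)
        draws = sample_field(Q, seed=0, size=2000)
        n = small_fem.n_vertices
        x0, x1 = draws[:, :n], draws[:, n:]
        v = 10  # an arbitrary vertex
        r = np.corrcoef(x0[:, v], x1[:, v])[0, 1]
        se = (1 - a**2) / math.sqrt(2000)
        assert abs(r - a) < 3 * max(se, 0.02)


class TestSampleField:
    def test_seed_determinism(self, small_fem):
        spde = SpdeParams(rho=0.4, sigma=1.0)
        Q = spatial_precision(spde.kappa, spde.tau, small_fem)
        assert np.array_equal(sample_field(Q, seed=42), sample_field(Q, seed=42))

    def test_mean_and_covariance_match_inverse(self):
        mesh = build_mesh(np.random.default_rng(6).uniform(0, 1, (30, 2)), 0.4, 0.02)
        fem = fem_matrices(mesh)
        spde = SpdeParams(rho=0.5, sigma=1.0)
        Q = spacetime_precision(spde, TemporalParams(a=0.5, n_years=2), fem)
        S = np.linalg.inv(Q.toarray())
        draws = sample_field(Q, seed=1, size=5000)
        emp = np.cov(draws.T)
        sd_pair = np.sqrt(np.outer(np.diag(S), np.diag(S)))
        assert np.abs(emp - S).max() < 5 * sd_pair.max() / math.sqrt(5000) * 3
        mean_se = np.sqrt(np.diag(S) / 5000)
        assert np.all(np.abs(draws.mean(axis=0)) < 4.5 * mean_se)

    def test_empirical_sigma_matches_parameter(self):
        """Fields simulated with tau from tau_from_sigma have marginal SD
        close to the requested sigma in the mesh interior."""
        rng = np.random.default_rng(7)
        mesh = build_mesh(rng.uniform(0, 1, (200, 2)), max_edge=0.07, cutoff=0.007)
        fem = fem_matrices(mesh)
        sigma, rho = 1.5, 0.25
        kappa = kappa_from_range(rho)
        Q = spatial_precision(kappa, tau_from_sigma(sigma, kappa), fem)
        draws = sample_field(Q, seed=2, size=500)
        v = mesh.vertices
        interior = (
            (v[:, 0] > 0.25) & (v[:, 0] < 0.75) & (v[:, 1] > 0.25) & (v[:, 1] < 0.75)
        )
        emp = draws[:, interior].std(axis=0).mean()
        mc_se = sigma / math.sqrt(2 * 499)
        assert abs(emp - sigma) < max(3 * mc_se, 0.12 * sigma)


class TestPcPrior:
    def test_calibration_statements(self):
        """P(rho < 0.5) = 0.5 and P(sigma > 0.75) = 0.5 by numerical
        integration of the implemented densities."""
        prior = PcPrior(rho0=0.5, alpha_rho=0.5, sigma0=0.75, alpha_sigma=0.5)
        mass_rho, _ = quad(lambda r: np.exp(prior.log_density_rho(r)), 0, 0.5)
        assert mass_rho == pytest.approx(0.5, abs=1e-6)
        mass_sigma, _ = quad(lambda s: np.exp(prior.log_density_sigma(s)), 0.75, np.inf)
        assert mass_sigma == pytest.approx(0.5, abs=1e-6)

    def test_densities_normalise(self):
        prior = PcPrior()
        total_rho, _ = quad(lambda r: np.exp(prior.log_density_rho(r)), 0, np.inf)
        total_sigma, _ = quad(lambda s: np.exp(prior.log_density_sigma(s)), 0, np.inf)
        assert total_rho == pytest.approx(1.0, abs=1e-4)
        assert total_sigma == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("rho0,alpha", [(0.2, 0.3), (0.5, 0.5), (2.0, 0.8), (5.0, 0.05)])
    def test_quantile_calibration_grid(self, rho0, alpha):
        prior = PcPrior(rho0=rho0, alpha_rho=alpha)
        mass, _ = quad(lambda r: np.exp(prior.log_density_rho(r)), 0, rho0)
        assert mass == pytest.approx(alpha, abs=1e-6)
        assert prior.cdf_rho(rho0) == pytest.approx(alpha, abs=1e-12)

    def test_joint_log_density(self):
        prior = PcPrior()
        val = pc_prior_log_density(0.4, 1.1, prior)
        assert val == pytest.approx(
            float(prior.log_density_rho(0.4) + prior.log_density_sigma(1.1)), rel=1e-12
        )
        with pytest.raises(ValueError):
            pc_prior_log_density(-0.1, 1.0, prior)

    def test_correlation_at_range_in_paper_band(self):
        """The exact correlation at h = rho sits between the two rounded
        values (0.10 and 0.13) used informally for the range definition."""
        val = matern_correlation(math.sqrt(8) / 3.0, 3.0)
        assert 0.10 <= val <= 0.15


def test_precision_coo_text_round_trip(small_fem):
    from spatstock.field import precision_from_coo_text, precision_to_coo_text

    spde = SpdeParams(rho=0.4, sigma=1.0)
    Q = spatial_precision(spde.kappa, spde.tau, small_fem)
    again = precision_from_coo_text(precision_to_coo_text(Q))
    assert (Q != again).nnz == 0
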