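"""Matérn field, SPDE precision, AR(1) persistence and PC priors.

The latent spatio-temporal effect xi(s, t) is an AR(1) chain of spatially
correlated innovations,

    xi(s, t) = a * xi(s, t-1) + omega(s, t),      |a| < 1,

where each innovation omega(., t) is a zero-mean Gaussian field with
Matérn correlation C(h; nu, kappa) and the chain is stationary with
marginal standard deviation sigma, so the innovation SD is
sigma * sqrt(1 - a^2).  The field is discretised on a triangulation via
the SPDE representation: for smoothness nu = 1 in two dimensions the
precision of the vertex weights is

    Q_s = tau^2 (kappa^4 C + 2 kappa^2 G + G C^{-1} G)

with C, G the finite-element mass and stiffness matrices.  The reported
range rho = sqrt(8 nu) / kappa is the distance at which the correlation
has dropped to about 0.1 (exactly 0.1397 for nu = 1).

Penalised-complexity priors shrink towards the structureless base model
(rho = infinity, sigma = 0) and are calibrated by two tail statements:
P(rho < rho0) = alpha_rho and P(sigma > sigma0) = alpha_sigma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import sparse
from scipy.linalg import cholesky, solve_triangular
from scipy.special import gamma as gamma_fn, kv

from .errors import ConditioningError, StationarityError
from .mesh import FemMatrices

__all__ = [
    "SpdeParams",
    "TemporalParams",
    "PcPrior",
    "matern_correlation",
    "kappa_from_range",
    "range_from_kappa",
    "tau_from_sigma",
    "spatial_precision",
    "ar1_precision",
    "spacetime_precision",
    "pc_prior_log_density",
    "sample_field",
]

#: Matérn correlation at lag h = rho for nu = 1: sqrt(8) * K_1(sqrt(8))
CORRELATION_AT_RANGE = float(math.sqrt(8.0) * kv(1, math.sqrt(8.0)))


def matern_correlation(h, kappa: float, nu: float = 1.0):
    """Matérn correlation C(h; nu, kappa) = (kappa h)^nu K_nu(kappa h) / (Gamma(nu) 2^(nu-1)).

    Defined by continuity as 1 at h = 0.  Vectorised over ``h``.
    """
    if kappa <= 0 or nu <= 0:
        raise ValueError("kappa and nu must be positive")
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("distances must be non-negative")
    x = kappa * h
    with np.errstate(invalid="ignore", over="ignore"):
        val = np.where(
            x > 0, x**nu * kv(nu, np.where(x > 0, x, 1.0)) / (gamma_fn(nu) * 2 ** (nu - 1)), 1.0
        )
    val = np.nan_to_num(val, nan=0.0)  # kv underflows to nan*0 for huge x
    out = np.clip(val, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def kappa_from_range(rho: float, nu: float = 1.0) -> float:
    """Scale parameter kappa = sqrt(8 nu) / rho."""
    if rho <= 0:
        raise ValueError("range rho must be positive")
    return math.sqrt(8.0 * nu) / rho


def range_from_kappa(kappa: float, nu: float = 1.0) -> float:
    """Empirical range rho = sqrt(8 nu) / kappa (correlation ~0.1 at rho)."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    return math.sqrt(8.0 * nu) / kappa


def tau_from_sigma(sigma: float, kappa: float) -> float:
    """Precision scaling giving the stationary field marginal SD ``sigma``.

    For nu = 1 in d = 2 the marginal variance of the SPDE solution is
    1 / (4 pi kappa^2 tau^2), hence tau = 1 / (sigma kappa sqrt(4 pi)).
    """
    if sigma <= 0 or kappa <= 0:
        raise ValueError("sigma and kappa must be positive")
    return 1.0 / (sigma * kappa * math.sqrt(4.0 * math.pi))


def sigma_from_tau(tau: float, kappa: float) -> float:
    if tau <= 0 or kappa <= 0:
        raise ValueError("tau and kappa must be positive")
    return 1.0 / (tau * kappa * math.sqrt(4.0 * math.pi))


@dataclass
class SpdeParams:
    """Matérn/SPDE parameters (nu fixed at 1, d = 2).

    ``rho`` is the correlation range (degrees), ``sigma`` the stationary
    marginal SD of the field; ``kappa`` and ``tau`` are derived.
    """

    rho: float
    sigma: float
    nu: float = 1.0

    def __post_init__(self):
        if self.rho <= 0 or self.sigma <= 0:
            raise ValueError("rho and sigma must be positive")

    @property
    def kappa(self) -> float:
        return kappa_from_range(self.rho, self.nu)

    @property
    def tau(self) -> float:
        return tau_from_sigma(self.sigma, self.kappa)


@dataclass
class TemporalParams:
    """AR(1) persistence ``a`` over ``n_years`` annual fields."""

    a: float
    n_years: int

    def __post_init__(self):
        if not abs(self.a) < 1:
            raise StationarityError(f"|a| must be < 1, got {self.a}")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")

    def innovation_sd(self, sigma: float) -> float:
        """Innovation SD sigma_omega = sigma * sqrt(1 - a^2)."""
        return sigma * math.sqrt(1.0 - self.a**2)


@dataclass
class PcPrior:
    """Penalised-complexity prior on (rho, sigma), calibrated by tail masses.

    The density is the product of the Fuglstad-type range prior
    pi(rho) = (d/2) lambda_r rho^(-d/2-1) exp(-lambda_r rho^(-d/2)), d = 2,
    and an exponential on sigma, pi(sigma) = lambda_s exp(-lambda_s sigma),
    with rates solved from P(rho < rho0) = alpha_rho and
    P(sigma > sigma0) = alpha_sigma.
    """

    rho0: float = 0.5
    alpha_rho: float = 0.5
    sigma0: float = 0.75
    alpha_sigma: float = 0.5
    d: int = 2
    lambda_rho: float = dc_field(init=False)
    lambda_sigma: float = dc_field(init=False)

    def __post_init__(self):
        if not (0 < self.alpha_rho < 1 and 0 < self.alpha_sigma < 1):
            raise ValueError("tail probabilities must lie in (0, 1)")
        if self.rho0 <= 0 or self.sigma0 <= 0:
            raise ValueError("reference values must be positive")
        self.lambda_rho = -math.log(self.alpha_rho) * self.rho0 ** (self.d / 2.0)
        self.lambda_sigma = -math.log(self.alpha_sigma) / self.sigma0

    def log_density_rho(self, rho):
        rho = np.asarray(rho, dtype=float)
        d2 = self.d / 2.0
        return (
            math.log(d2 * self.lambda_rho)
            + (-d2 - 1.0) * np.log(rho)
            - self.lambda_rho * rho ** (-d2)
        )

    def log_density_sigma(self, sigma):
        sigma = np.asarray(sigma, dtype=float)
        return math.log(self.lambda_sigma) - self.lambda_sigma * sigma

    def cdf_rho(self, rho: float) -> float:
        """P(rho < r) = exp(-lambda_r r^(-d/2))."""
        return math.exp(-self.lambda_rho * rho ** (-self.d / 2.0))

    def survival_sigma(self, sigma: float) -> float:
        """P(sigma > s) = exp(-lambda_s s)."""
        return math.exp(-self.lambda_sigma * sigma)


def pc_prior_log_density(rho: float, sigma: float, prior: PcPrior) -> float:
    """Joint log-density log pi(rho, sigma) under independent PC priors."""
    if rho <= 0 or sigma <= 0:
        raise ValueError("rho and sigma must be positive")
    if prior.lambda_rho <= 0 or prior.lambda_sigma <= 0:  # pragma: no cover
        raise ValueError("prior is not calibrated")
    return float(prior.log_density_rho(rho) + prior.log_density_sigma(sigma))


def spatial_precision(kappa: float, tau: float, fem: FemMatrices) -> sparse.csc_matrix:
    """SPDE precision Q_s = tau^2 (kappa^4 C + 2 kappa^2 G + G C^{-1} G)."""
    if kappa <= 0 or tau <= 0:
        raise ValueError("kappa and tau must be positive")
    C = fem.mass
    G = fem.stiffness
    c_inv = sparse.diags(1.0 / C.diagonal(), format="csc")
    Q = tau**2 * (kappa**4 * C + 2.0 * kappa**2 * G + G @ c_inv @ G)
    Q = 0.5 * (Q + Q.T)
    return Q.tocsc()


def spatial_precision_logdet(kappa: float, tau: float, fem: FemMatrices) -> float:
    """log det Q_s without factorizing Q_s itself.

    Q_s factorises as tau^2 (kappa^2 C + G) C^{-1} (kappa^2 C + G), so
    log det Q_s = 2n log tau + 2 log det(kappa^2 C + G) - log det C, and
    only the (much better conditioned) n x n Helmholtz matrix needs an LU.
    """
    from scipy.sparse.linalg import splu as _splu

    n = fem.n_vertices
    H = (kappa**2 * fem.mass + fem.stiffness).tocsc()
    lu = _splu(H, permc_spec="MMD_AT_PLUS_A")
    logdet_H = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
    logdet_C = float(np.sum(np.log(fem.mass.diagonal())))
    return 2.0 * n * math.log(tau) + 2.0 * logdet_H - logdet_C


def ar1_logdet(a: float, T: int) -> float:
    """log det of the unit-marginal AR(1) precision: -(T-1) log(1 - a^2)."""
    if not abs(a) < 1:
        raise StationarityError(f"|a| must be < 1, got {a}")
    return -(T - 1) * math.log(1.0 - a**2)


def ar1_precision(a: float, T: int) -> sparse.csc_matrix:
    """Tridiagonal AR(1) precision with unit stationary marginal variance.

    The inverse has entries a^|i-j|; for T = 1 the matrix is [[1]].
    """
    if not abs(a) < 1:
        raise StationarityError(f"|a| must be < 1, got {a}")
    if T < 1:
        raise ValueError("T must be >= 1")
    if T == 1:
        return sparse.eye(1, format="csc")
    scale = 1.0 / (1.0 - a**2)
    diag = np.full(T, (1.0 + a**2) * scale)
    diag[0] = diag[-1] = scale
    off = np.full(T - 1, -a * scale)
    return sparse.diags([off, diag, off], offsets=[-1, 0, 1], format="csc")


def spacetime_precision(
    spde: SpdeParams, temporal: TemporalParams, fem: FemMatrices
) -> sparse.csc_matrix:
    """Joint precision over vertex-years, stacked year-major.

    Kronecker product of the unit-marginal AR(1) precision and the spatial
    precision scaled so every vertex has stationary marginal SD ``sigma``;
    the innovation variance is sigma^2 (1 - a^2) by construction.
    """
    Qs = spatial_precision(spde.kappa, spde.tau, fem)
    Qt = ar1_precision(temporal.a, temporal.n_years)
    return sparse.kron(Qt, Qs, format="csc")


def precision_to_coo_text(Q: sparse.spmatrix) -> str:
    """Serialise a sparse precision to coordinate-triplet text (debugging).

    One "row col value" line per stored entry, preceded by a header line
    with the matrix shape.
    """
    coo = sparse.coo_matrix(Q)
    lines = [f"# {coo.shape[0]} {coo.shape[1]}"]
    for i, j, v in zip(coo.row, coo.col, coo.data):
        lines.append(f"{i} {j} {float(v)!r}")
    return "\n".join(lines) + "\n"


def precision_from_coo_text(text: str) -> sparse.csc_matrix:
    """Inverse of :func:`precision_to_coo_text`."""
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("#"):
        raise ValueError("missing shape header line")
    n, m = (int(x) for x in lines[0][1:].split())
    rows, cols, vals = [], [], []
    for ln in lines[1:]:
        i, j, v = ln.split()
        rows.append(int(i))
        cols.append(int(j))
        vals.append(float(v))
    return sparse.csc_matrix((vals, (rows, cols)), shape=(n, m))


def sample_field(Q: sparse.spmatrix, seed, size: int = 1) -> np.ndarray:
    """Draw zero-mean Gaussian vectors with precision ``Q``.

    Uses a dense Cholesky factor Q = R'R and solves R x = z; intended for
    desk-scale systems (a few thousand dimensions).  ``seed`` may be an
    integer or a ``numpy.random.Generator``.

    Returns an array of shape (size, n); squeezed to (n,) when size == 1.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Qd = np.asarray(Q.todense()) if sparse.issparse(Q) else np.asarray(Q, float)
    try:
        R = cholesky(Qd, lower=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise ConditioningError(f"precision not positive definite: {exc}") from exc
    z = rng.standard_normal((Qd.shape[0], size))
    x = solve_triangular(R, z, lower=False)
    return x.T[0] if size == 1 else x.T
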