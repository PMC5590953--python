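"""Latent-Gaussian model fitting.

The posterior of the latent vector u (field weights, smooth coefficients,
intercept) given hyperparameters theta is approximated by a Gaussian
centred at the posterior mode (Laplace approximation); the hyperparameter
posterior is explored by maximising the approximate marginal posterior
(empirical-Bayes mode) and evaluating a small axial grid around the mode
whose normalised weights approximate the hyperparameter posterior.  This
is a deliberately simplified variant of the nested-Laplace strategy:
latent marginal variances are taken from the mode-theta Gaussian, with the
between-grid spread of the conditional modes added, rather than from a
full mixture of per-grid marginals.

Hyperparameters and their transforms:

* ``log_rho``, ``log_sigma`` — Matérn range and marginal SD, PC priors;
* ``z_a`` — Fisher transform of the AR(1) persistence, Normal(0, 2^2);
* ``phi`` — log size of the negative binomial, Normal(0, 5^2);
* ``log_lambda_<name>`` — log smoothing precision per covariate smooth,
  Gamma(1, 1e-3) on the precision scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import sparse
from scipy.optimize import minimize

from .errors import ConditioningError, ConvergenceError, SchemaError
from .field import (
    PcPrior,
    SpdeParams,
    ar1_logdet,
    ar1_precision,
    pc_prior_log_density,
    spatial_precision,
    spatial_precision_logdet,
)
from .mesh import TriangulationMesh, build_mesh, fem_matrices, projection_matrix
from .observation import (
    CovariateSmooth,
    ObservationParams,
    SurveyDataset,
    build_covariate_smooth,
    observation_loglik,
)

__all__ = [
    "ModelSpec",
    "Hyperparameters",
    "FitResult",
    "gaussian_approximation",
    "fit_model",
    "predict_surface",
]

SPATIAL_STRUCTURES = ("none", "constant", "replicated_by_year", "ar1")

# soft sum-to-zero weight and properness ridge for intrinsic RW2 blocks
_SUM_TO_ZERO_WEIGHT = 1e4
_RW2_RIDGE = 1e-8
_INTERCEPT_PRECISION = 1e-6


@dataclass
class ModelSpec:
    """What to fit: spatial structure, covariates, count family, priors."""

    spatial_structure: str = "ar1"
    covariates: tuple = ()
    family: str = "negative_binomial"
    n_knots: int = 25
    pc_prior: PcPrior = dc_field(default_factory=PcPrior)
    prior_a_sd: float = 2.0
    prior_phi_sd: float = 5.0
    smoothing_gamma_rate: float = 1e-3
    gaussian_sd: float = 1.0
    collinearity_threshold: float = 0.9

    def __post_init__(self):
        if self.spatial_structure not in SPATIAL_STRUCTURES:
            raise ValueError(f"unknown spatial structure {self.spatial_structure!r}")
        self.covariates = tuple(self.covariates)

    def hyper_names(self) -> list[str]:
        names = []
        if self.spatial_structure != "none":
            names += ["log_rho", "log_sigma"]
        if self.spatial_structure == "ar1":
            names.append("z_a")
        if self.family == "negative_binomial":
            names.append("phi")
        names += [f"log_lambda_{c}" for c in self.covariates]
        return names


@dataclass
class Hyperparameters:
    """Named hyperparameter vector with back-transformed accessors."""

    names: list
    values: np.ndarray

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def get(self, name, default=None):
        return self[name] if name in self.names else default

    @property
    def rho(self):
        v = self.get("log_rho")
        return math.exp(v) if v is not None else None

    @property
    def sigma(self):
        v = self.get("log_sigma")
        return math.exp(v) if v is not None else None

    @property
    def a(self):
        v = self.get("z_a")
        return math.tanh(v / 2.0) if v is not None else None

    @property
    def phi(self):
        return self.get("phi")

    def as_dict(self) -> dict:
        out = dict(zip(self.names, map(float, self.values)))
        for k in ("rho", "sigma", "a", "phi"):
            val = getattr(self, k)
            if val is not None:
                out[k] = val
        return out


@dataclass
class LaplaceFit:
    """Gaussian approximation of the latent posterior at fixed theta."""

    mode: np.ndarray
    Q_post: sparse.csc_matrix
    lu: object
    loglik: float
    quad: float  # u' Q_prior u at the mode
    logdet_post: float
    n_iter: int
    converged: bool

    @property
    def conditional_logdensity(self) -> float:
        """log p(u_hat | y, theta) up to the Gaussian normalising constant."""
        return self.loglik - 0.5 * self.quad


class SpdFactor:
    """Banded Cholesky of a sparse SPD matrix under an RCM permutation.

    A bandwidth-reducing (reverse Cuthill-McKee) permutation is computed
    once from the sparsity pattern and can be reused across refactorizations
    with identical structure.  Unlike a general sparse LU with numerical
    pivoting, the banded factorization has deterministic, bounded cost and
    memory — no value-dependent fill-in explosions.
    """

    def __init__(self, Q: sparse.spmatrix, perm: np.ndarray | None = None):
        from scipy.linalg import cholesky_banded

        Q = Q.tocsr()
        n = Q.shape[0]
        if perm is None:
            perm = _rcm_permutation(Q)
        self.perm = perm
        self.iperm = np.empty(n, dtype=np.intp)
        self.iperm[perm] = np.arange(n)
        Qp = Q[perm][:, perm].tocoo()
        lower = Qp.row >= Qp.col
        rows, cols, vals = Qp.row[lower], Qp.col[lower], Qp.data[lower]
        bw = int((rows - cols).max()) if len(rows) else 0
        self.bandwidth = bw
        ab = np.zeros((bw + 1, n))
        np.add.at(ab, (rows - cols, cols), vals)
        try:
            self.cb = cholesky_banded(ab, lower=True, check_finite=False)
        except np.linalg.LinAlgError as exc:
            raise ConditioningError(f"banded Cholesky failed: {exc}") from exc
        self.n = n

    @property
    def logdet(self) -> float:
        return float(2.0 * np.sum(np.log(self.cb[0])))

    def solve(self, b: np.ndarray) -> np.ndarray:
        from scipy.linalg import cho_solve_banded

        b = np.asarray(b, float)
        bp = b[self.perm] if b.ndim == 1 else b[self.perm, :]
        xp = cho_solve_banded((self.cb, True), bp, check_finite=False)
        return xp[self.iperm] if b.ndim == 1 else xp[self.iperm, :]

    def solve_Lt(self, z: np.ndarray) -> np.ndarray:
        """Solve L' x = z (permuted space in, original space out): a draw
        x has covariance Q^{-1} when z is standard normal."""
        from scipy.linalg import solve_banded

        # upper-banded storage of L' from the lower-banded factor of L
        bw = self.bandwidth
        n = self.n
        ub = np.zeros((bw + 1, n))
        for k in range(bw + 1):
            # L'[j-k.., j] row offset: U = L', U[i, j] = L[j, i]
            ub[bw - k, k:] = self.cb[k, : n - k]
        xp = solve_banded((0, bw), ub, np.asarray(z, float), check_finite=False)
        return xp[self.iperm] if xp.ndim == 1 else xp[self.iperm, :]


def _rcm_permutation(Q: sparse.spmatrix) -> np.ndarray:
    from scipy.sparse.csgraph import reverse_cuthill_mckee

    return np.asarray(reverse_cuthill_mckee(Q.tocsr(), symmetric_mode=True), dtype=np.intp)


def gaussian_approximation(
    Q_prior: sparse.spmatrix,
    X: sparse.spmatrix,
    y: np.ndarray,
    obs_params: ObservationParams,
    u0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
    perm: np.ndarray | None = None,
) -> LaplaceFit:
    """Newton optimisation of the latent field at fixed hyperparameters.

    Maximises loglik(y | X u) - u' Q_prior u / 2; the returned Gaussian
    approximation has precision Q_prior + X' W X with W the negative
    log-likelihood Hessian at the mode.  The gradient tolerance is scaled
    by the data magnitude so convergence is meaningful for counts in the
    thousands.
    """
    Q_prior = Q_prior.tocsc()
    X = X.tocsr()
    y = np.asarray(y, float)
    n_lat = Q_prior.shape[0]
    u = np.zeros(n_lat) if u0 is None else np.array(u0, float)
    scale = max(1.0, float(np.linalg.norm(y)))
    if perm is None:
        # permutation depends only on the sparsity pattern; reusable
        perm = _rcm_permutation((Q_prior + X.T @ X).tocsr())

    def objective(u):
        eta = X @ u
        ll, g, w = observation_loglik(y, eta, obs_params)
        return ll - 0.5 * float(u @ (Q_prior @ u)), g, w

    obj, g, w = objective(u)
    lu = None
    Q_post = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad = X.T @ g - Q_prior @ u
        gnorm = float(np.linalg.norm(grad))
        if gnorm < tol * scale:
            converged = True
            break
        W = sparse.diags(np.maximum(w, 0.0))
        Q_post = (Q_prior + X.T @ W @ X).tocsc()
        lu = SpdFactor(Q_post, perm=perm)
        step = lu.solve(grad)
        # step halving to guarantee ascent of the log-concave objective
        alpha = 1.0
        for _ in range(30):
            u_new = u + alpha * step
            try:
                obj_new, g_new, w_new = objective(u_new)
            except FloatingPointError:  # pragma: no cover
                obj_new = -np.inf
            if np.isfinite(obj_new) and obj_new >= obj - 1e-12:
                break
            alpha *= 0.5
        else:
            raise ConvergenceError(
                f"step halving failed at iteration {it}; last step norm "
                f"{float(np.linalg.norm(step)):.3e}"
            )
        if np.linalg.norm(alpha * step) < 1e-12 * max(1.0, np.linalg.norm(u)):
            u, obj, g, w = u_new, obj_new, g_new, w_new
            converged = True
            break
        u, obj, g, w = u_new, obj_new, g_new, w_new
    else:
        raise ConvergenceError(
            f"Newton did not converge in {max_iter} iterations; "
            f"gradient norm {gnorm:.3e}"
        )

    # final curvature at the mode
    _, g, w = objective(u)
    W = sparse.diags(np.maximum(w, 0.0))
    Q_post = (Q_prior + X.T @ W @ X).tocsc()
    lu = SpdFactor(Q_post, perm=perm)
    ll, _, _ = observation_loglik(y, X @ u, obs_params)
    return LaplaceFit(
        mode=u,
        Q_post=Q_post,
        lu=lu,
        loglik=ll,
        quad=float(u @ (Q_prior @ u)),
        logdet_post=lu.logdet,
        n_iter=it,
        converged=converged,
    )


class ModelMatrices:
    """Design and prior-precision assembly for a (spec, data, mesh) triple."""

    def __init__(self, spec: ModelSpec, data: SurveyDataset, mesh: TriangulationMesh):
        self.spec = spec
        self.data = data
        self.mesh = mesh
        self.fem = fem_matrices(mesh)
        self.years = data.years
        self.n_years = len(self.years)
        if spec.spatial_structure == "ar1" and self.n_years < 2:
            raise SchemaError("AR(1) structure requires at least 2 years of data")
        for c in spec.covariates:
            if c not in data.df.columns:
                raise SchemaError(f"covariate {c!r} not in dataset")
        self._check_collinearity()

        self.n_vert = mesh.n_vertices
        self.T_field = {
            "none": 0,
            "constant": 1,
            "replicated_by_year": self.n_years,
            "ar1": self.n_years,
        }[spec.spatial_structure]

        # covariate smooths (knots from the data)
        self.smooths: list[CovariateSmooth] = []
        for c in spec.covariates:
            vals = data.df[c].to_numpy(float)
            n_knots = min(spec.n_knots, max(4, len(np.unique(vals[np.isfinite(vals)]))))
            self.smooths.append(build_covariate_smooth(vals, n_knots=n_knots, name=c))

        self.X = self._design()
        self.n_latent = self.X.shape[1]

    def _check_collinearity(self):
        cov = list(self.spec.covariates)
        if len(cov) < 2:
            return
        sub = self.data.df[cov].dropna()
        corr = sub.corr().abs().to_numpy()
        for i in range(len(cov)):
            for j in range(i + 1, len(cov)):
                if corr[i, j] >= self.spec.collinearity_threshold:
                    raise SchemaError(
                        f"covariates {cov[i]!r} and {cov[j]!r} have |r| = "
                        f"{corr[i, j]:.3f} >= {self.spec.collinearity_threshold}; "
                        "enter only one of them"
                    )

    def _design(self) -> sparse.csr_matrix:
        blocks = []
        n_obs = len(self.data)
        if self.T_field > 0:
            A = projection_matrix(self.mesh, self.data.coords).matrix
            if self.T_field == 1:
                blocks.append(A)
            else:
                yr_idx = np.searchsorted(self.years, self.data.df["year"].to_numpy())
                rows, cols, vals = [], [], []
                Acoo = A.tocoo()
                for r, c, v in zip(Acoo.row, Acoo.col, Acoo.data):
                    rows.append(r)
                    cols.append(yr_idx[r] * self.n_vert + c)
                    vals.append(v)
                blocks.append(
                    sparse.csr_matrix(
                        (vals, (rows, cols)), shape=(n_obs, self.n_vert * self.T_field)
                    )
                )
        for sm in self.smooths:
            blocks.append(sparse.csr_matrix(sm.design(self.data.df[sm.name].to_numpy(float))))
        blocks.append(sparse.csr_matrix(np.ones((n_obs, 1))))
        return sparse.hstack(blocks, format="csr")

    def obs_params(self, theta: Hyperparameters) -> ObservationParams:
        if self.spec.family == "negative_binomial":
            return ObservationParams(family="negative_binomial", phi=theta["phi"])
        if self.spec.family == "gaussian":
            return ObservationParams(family="gaussian", sd=self.spec.gaussian_sd)
        return ObservationParams(family="poisson")

    def prior_precision(self, theta: Hyperparameters) -> sparse.csc_matrix:
        blocks = []
        if self.T_field > 0:
            spde = SpdeParams(rho=theta.rho, sigma=theta.sigma)
            Qs = spatial_precision(spde.kappa, spde.tau, self.fem)
            if self.T_field == 1:
                blocks.append(Qs)
            else:
                a = theta.a if self.spec.spatial_structure == "ar1" else 0.0
                blocks.append(sparse.kron(ar1_precision(a, self.T_field), Qs, format="csc"))
        for sm in self.smooths:
            lam = math.exp(theta[f"log_lambda_{sm.name}"])
            k = sm.n_knots
            J = np.full((k, k), _SUM_TO_ZERO_WEIGHT / k)
            block = lam * sm.penalty_precision + J + _RW2_RIDGE * np.eye(k)
            blocks.append(sparse.csc_matrix(block))
        blocks.append(sparse.csc_matrix(np.array([[_INTERCEPT_PRECISION]])))
        return sparse.block_diag(blocks, format="csc")

    def prior_logdet(self, theta: Hyperparameters) -> float:
        """log det of the prior precision, block by block.

        The space-time block uses log det(A kron B) = n_B log det A +
        n_A log det B with the AR(1) determinant in closed form, so only
        an n_vertices-sized Helmholtz factorization is needed; smooth
        blocks are small and dense.
        """
        total = math.log(_INTERCEPT_PRECISION)
        if self.T_field > 0:
            spde = SpdeParams(rho=theta.rho, sigma=theta.sigma)
            logdet_qs = spatial_precision_logdet(spde.kappa, spde.tau, self.fem)
            a = theta.a if self.spec.spatial_structure == "ar1" else 0.0
            total += self.T_field * logdet_qs + self.n_vert * ar1_logdet(a, self.T_field)
        for sm in self.smooths:
            lam = math.exp(theta[f"log_lambda_{sm.name}"])
            k = sm.n_knots
            J = np.full((k, k), _SUM_TO_ZERO_WEIGHT / k)
            block = lam * sm.penalty_precision + J + _RW2_RIDGE * np.eye(k)
            sign, ld = np.linalg.slogdet(block)
            total += ld
        return total

    def log_prior_theta(self, theta: Hyperparameters) -> float:
        lp = 0.0
        spec = self.spec
        if self.T_field > 0:
            # PC prior with log-transform Jacobians d rho/d log rho = rho
            lp += pc_prior_log_density(theta.rho, theta.sigma, spec.pc_prior)
            lp += theta["log_rho"] + theta["log_sigma"]
        if spec.spatial_structure == "ar1":
            z = theta["z_a"]
            lp += -0.5 * (z / spec.prior_a_sd) ** 2
        if spec.family == "negative_binomial":
            lp += -0.5 * (theta["phi"] / spec.prior_phi_sd) ** 2
        for sm in self.smooths:
            loglam = theta[f"log_lambda_{sm.name}"]
            lam = math.exp(loglam)
            # Gamma(1, rate) on the precision, with Jacobian lam
            lp += loglam - spec.smoothing_gamma_rate * lam
        return lp

    def theta(self, values) -> Hyperparameters:
        return Hyperparameters(self.spec.hyper_names(), np.asarray(values, float))

    def initial_theta(self) -> Hyperparameters:
        names = self.spec.hyper_names()
        vals = []
        coords = self.data.coords
        extent = float(
            np.hypot(*(coords.max(axis=0) - coords.min(axis=0)))
        ) or 1.0
        y = self.data.counts
        for n in names:
            if n == "log_rho":
                vals.append(math.log(max(0.25 * extent, 1e-3)))
            elif n == "log_sigma":
                vals.append(0.0)
            elif n == "z_a":
                vals.append(1.0)
            elif n == "phi":
                m, v = float(np.mean(y)), float(np.var(y))
                n_mom = m**2 / max(v - m, 1e-3)
                vals.append(math.log(min(max(n_mom, 0.1), 20.0)))
            else:
                vals.append(0.0)
        return Hyperparameters(names, np.array(vals))


@dataclass
class GridPoint:
    theta: Hyperparameters
    log_post: float
    weight: float
    mode: np.ndarray


@dataclass
class FitResult:
    """Fitted model: hyperparameter mode, grid, latent summaries, scores."""

    spec: ModelSpec
    matrices: ModelMatrices
    hyper_mode: Hyperparameters
    hyper_grid: list  # of GridPoint
    log_marginal: float
    latent_mean: np.ndarray
    latent_sd: np.ndarray | None
    eta_mean: np.ndarray
    eta_sd: np.ndarray | None
    fitted_mu: np.ndarray
    mode_fit: LaplaceFit
    boundary_warning: bool = False
    assessment: dict = dc_field(default_factory=dict)
    _cov_cache: np.ndarray | None = None

    @property
    def mesh(self) -> TriangulationMesh:
        return self.matrices.mesh

    @property
    def data(self) -> SurveyDataset:
        return self.matrices.data

    def hyper_summary(self) -> dict:
        """Mode and grid-weighted posterior mean/sd per hyperparameter."""
        out = {"mode": self.hyper_mode.as_dict()}
        vals = np.array([gp.theta.values for gp in self.hyper_grid])
        w = np.array([gp.weight for gp in self.hyper_grid])
        mean = w @ vals
        sd = np.sqrt(np.maximum(w @ vals**2 - mean**2, 0.0))
        out["grid_mean"] = dict(zip(self.hyper_mode.names, map(float, mean)))
        out["grid_sd"] = dict(zip(self.hyper_mode.names, map(float, sd)))
        return out

    def latent_covariance(self) -> np.ndarray:
        """Dense covariance of the latent Gaussian at the hyper mode (cached)."""
        if self._cov_cache is None:
            n = self.mode_fit.Q_post.shape[0]
            self._cov_cache = self.mode_fit.lu.solve(np.eye(n))
            self._cov_cache = 0.5 * (self._cov_cache + self._cov_cache.T)
        return self._cov_cache

    def sample_latent(self, size: int, rng) -> tuple[np.ndarray, list]:
        """Draw latent vectors from the grid-mixture Gaussian approximation.

        Returns (draws of shape (size, n_latent), grid point index per draw).
        """
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        cov = self.latent_covariance()
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
        w = np.array([gp.weight for gp in self.hyper_grid])
        which = rng.choice(len(w), size=size, p=w)
        z = rng.standard_normal((size, cov.shape[0]))
        draws = np.empty((size, cov.shape[0]))
        for i, k in enumerate(which):
            draws[i] = self.hyper_grid[k].mode + L @ z[i]
        return draws, list(which)

    def eta_at(self, X_new: sparse.spmatrix, with_sd: bool = True):
        """Posterior mean (and SD) of eta for new design rows."""
        X_new = sparse.csr_matrix(X_new)
        mean = X_new @ self.latent_mean
        if not with_sd:
            return mean, None
        cov = self.latent_covariance()
        S = X_new @ cov
        var = np.asarray(X_new.multiply(S).sum(axis=1)).ravel()
        return mean, np.sqrt(np.maximum(var, 0.0))


def _evaluate_theta(mats: ModelMatrices, theta_vals, warm: dict, tol: float = 1e-8):
    """Laplace evidence + hyper prior at one theta; warm-starts the Newton."""
    theta = mats.theta(theta_vals)
    Q_prior = mats.prior_precision(theta)
    logdet_prior = mats.prior_logdet(theta)
    if "perm" not in warm:
        warm["perm"] = _rcm_permutation((Q_prior + mats.X.T @ mats.X).tocsr())
    lf = gaussian_approximation(
        Q_prior,
        mats.X,
        mats.data.counts,
        mats.obs_params(theta),
        u0=warm.get("u"),
        tol=tol,
        perm=warm["perm"],
    )
    warm["u"] = lf.mode
    log_evidence = (
        lf.loglik - 0.5 * lf.quad + 0.5 * logdet_prior - 0.5 * lf.logdet_post
    )
    return theta, lf, log_evidence, log_evidence + mats.log_prior_theta(theta)


def fit_model(
    data: SurveyDataset,
    spec: ModelSpec,
    mesh: TriangulationMesh | None = None,
    max_edge: float | None = None,
    cutoff: float | None = None,
    maxfev: int = 150,
    grid_step: float = 0.5,
    grid: bool = True,
    compute_marginals: bool = True,
    inner_tol: float = 1e-6,
) -> FitResult:
    """Fit the full model: empirical-Bayes hyper mode + axial grid.

    If no mesh is given one is built from the data locations with
    ``max_edge`` defaulting to 1/8 of the coordinate extent and ``cutoff``
    to ``max_edge / 10``.  ``grid=False`` (with ``compute_marginals`` off)
    gives a fast point-estimate fit for simulation loops.
    """
    if mesh is None:
        coords = data.coords
        extent = float(np.hypot(*(coords.max(axis=0) - coords.min(axis=0))))
        if max_edge is None:
            max_edge = extent / 8.0
        if cutoff is None:
            # aggressive merging: observations are projected onto the mesh,
            # so vertices need not sit on every trawl location
            cutoff = max_edge / 3.0
        mesh = build_mesh(coords, max_edge=max_edge, cutoff=cutoff)
    mats = ModelMatrices(spec, data, mesh)
    warm: dict = {}
    cache: dict = {}

    theta_init = mats.initial_theta()

    def negpost(vals):
        # reject wild excursions before they hit the factorization: far
        # corners of the transform scale produce hopelessly ill-conditioned
        # precisions (sigma -> 0/inf, |a| -> 1)
        if np.any(np.abs(np.asarray(vals) - theta_init.values) > 8.0):
            return 1e10
        key = tuple(np.round(vals, 10))
        if key not in cache:
            try:
                cache[key] = _evaluate_theta(mats, vals, warm, tol=inner_tol)
            except (ConvergenceError, ConditioningError, MemoryError):
                return 1e10
        return -cache[key][3]

    theta0 = mats.initial_theta()
    if len(theta0.values) == 0:
        theta_mode_vals = theta0.values
        theta, lf, log_ev, log_post = _evaluate_theta(mats, theta_mode_vals, warm, tol=1e-8)
    else:
        # two Nelder-Mead stages with explicit simplices: the default
        # initial simplex takes 5e-2|x| (2.5e-4 at zero) steps, far too
        # small for a log-scale hyper space, and a restart with a fresh
        # smaller simplex recovers from premature simplex collapse
        n_h = len(theta0.values)
        x_best = theta0.values
        for step, frac in ((0.6, 0.55), (0.2, 0.45)):
            simplex = np.vstack([x_best, x_best + step * np.eye(n_h)])
            res = minimize(
                negpost,
                x_best,
                method="Nelder-Mead",
                options={
                    "maxfev": max(int(maxfev * frac), 10),
                    "xatol": 0.02,
                    "fatol": 0.05,
                    "initial_simplex": simplex,
                    "adaptive": n_h > 3,
                },
            )
            x_best = res.x
        theta_mode_vals = x_best
        try:
            theta, lf, log_ev, log_post = _evaluate_theta(mats, theta_mode_vals, warm, tol=1e-8)
        except (ConvergenceError, ConditioningError, MemoryError):
            # optimizer terminated in a penalized region: fall back to the
            # best cached evaluation
            good = [v for v in cache.values() if np.isfinite(v[3])]
            if not good:
                raise
            theta, lf, log_ev, log_post = max(good, key=lambda v: v[3])

    boundary_warning = False
    if "z_a" in theta.names and abs(theta.a) > 0.995:
        boundary_warning = True
        warnings.warn("persistence estimate at the stationarity boundary (|a| ~ 1)")

    grid_points = [GridPoint(theta, log_post, 1.0, lf.mode)]
    if grid and len(theta.values) > 0:
        for i in range(len(theta.values)):
            for s in (-grid_step, grid_step):
                vals = theta.values.copy()
                vals[i] += s
                try:
                    th_g, lf_g, _, lp_g = _evaluate_theta(mats, vals, warm, tol=inner_tol)
                except (ConvergenceError, ConditioningError, MemoryError):
                    continue
                grid_points.append(GridPoint(th_g, lp_g, 0.0, lf_g.mode))
    logps = np.array([gp.log_post for gp in grid_points])
    w = np.exp(logps - logps.max())
    w /= w.sum()
    for gp, wi in zip(grid_points, w):
        gp.weight = float(wi)

    latent_mean = np.sum([gp.weight * gp.mode for gp in grid_points], axis=0)
    latent_sd = None
    eta_sd = None
    fit = FitResult(
        spec=spec,
        matrices=mats,
        hyper_mode=theta,
        hyper_grid=grid_points,
        log_marginal=log_ev,
        latent_mean=latent_mean,
        latent_sd=None,
        eta_mean=np.asarray(mats.X @ latent_mean),
        eta_sd=None,
        fitted_mu=np.empty(0),
        mode_fit=lf,
        boundary_warning=boundary_warning,
    )
    if compute_marginals:
        cov = fit.latent_covariance()
        within = np.diag(cov)
        between = np.sum(
            [gp.weight * (gp.mode - latent_mean) ** 2 for gp in grid_points], axis=0
        )
        latent_sd = np.sqrt(np.maximum(within + between, 0.0))
        fit.latent_sd = latent_sd
        mean_eta, sd_eta = fit.eta_at(mats.X, with_sd=True)
        fit.eta_mean = mean_eta
        fit.eta_sd = sd_eta
    if spec.family == "gaussian":
        fit.fitted_mu = fit.eta_mean.copy()
    else:
        var_term = 0.5 * fit.eta_sd**2 if fit.eta_sd is not None else 0.0
        fit.fitted_mu = np.exp(fit.eta_mean + var_term)
    if fit.latent_sd is not None and np.any(fit.latent_sd <= 0):
        # strictly positive by construction; guard against round-off zeros
        fit.latent_sd = np.maximum(fit.latent_sd, 1e-12)
    return fit


def predict_surface(
    fit: FitResult,
    points,
    year=None,
    covariate_values: dict | None = None,
    with_sd: bool = True,
):
    """Posterior mean (and SD) of eta on arbitrary points for one year.

    Points outside the mesh are returned as NaN with ``inside`` False.
    Covariate smooth terms are added only when values are supplied for
    every covariate in the spec; otherwise the surface is field +
    intercept (useful for mapping the random field itself).

    Returns dict with ``mean``, ``sd``, ``inside``.
    """
    mats = fit.matrices
    pts = np.atleast_2d(np.asarray(points, float))
    proj = projection_matrix(mats.mesh, pts, allow_outside=True)
    n_pts = pts.shape[0]
    blocks = []
    if mats.T_field > 0:
        if mats.T_field == 1:
            blocks.append(proj.matrix)
        else:
            if year is None:
                raise ValueError("year is required for a year-indexed field")
            t_idx = int(np.searchsorted(mats.years, year))
            if t_idx >= mats.n_years or mats.years[t_idx] != year:
                raise ValueError(f"year {year} not in fitted years")
            pad_left = sparse.csr_matrix((n_pts, t_idx * mats.n_vert))
            pad_right = sparse.csr_matrix(
                (n_pts, (mats.T_field - t_idx - 1) * mats.n_vert)
            )
            blocks.append(sparse.hstack([pad_left, proj.matrix, pad_right]))
    for sm in mats.smooths:
        if covariate_values is not None and sm.name in covariate_values:
            blocks.append(sparse.csr_matrix(sm.design(covariate_values[sm.name])))
        else:
            blocks.append(sparse.csr_matrix((n_pts, sm.n_knots)))
    blocks.append(sparse.csr_matrix(np.ones((n_pts, 1))))
    X_pred = sparse.hstack(blocks, format="csr")
    mean, sd = fit.eta_at(X_pred, with_sd=with_sd)
    mean = np.where(proj.inside, mean, np.nan)
    if sd is not None:
        sd = np.where(proj.inside, sd, np.nan)
    return {"mean": mean, "sd": sd, "inside": proj.inside}
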