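"""Observation model: survey data container, covariate smooths, likelihoods.

Counts y(s, t) from individual trawl sets are modelled with a log link,

    log mu(s, t) = eta(s, t) = beta0 + xi(s, t) + sum_j f_j(c_j(s, t)),

where xi is the latent spatio-temporal field and each f_j is a smoothed
(piecewise-linear, second-order random-walk penalised) function of a
covariate such as bottom temperature, bathymetry or relative exploitation.
Candidate count families are the Poisson and the negative binomial with
size parameter n (variance mu (1 + mu / n)); a Gaussian family with
identity link is provided as a test/conjugate harness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import MissingDataError, SchemaError

__all__ = [
    "SurveyDataset",
    "CovariateSmooth",
    "ObservationParams",
    "collinearity_screen",
    "build_covariate_smooth",
    "smooth_design",
    "assemble_linear_predictor",
    "observation_loglik",
]

RESERVED_COLUMNS = ("lon", "lat", "year", "count", "subzone", "distance_towed")


@dataclass
class SurveyDataset:
    """Trawl survey records with coordinates, year, count and covariates.

    Any column beyond the reserved schema columns is treated as a
    covariate.  ``truth`` optionally carries the generating parameters and
    latent field when the dataset is synthetic.
    """

    df: pd.DataFrame
    truth: dict | None = None

    def __post_init__(self):
        missing = [c for c in ("lon", "lat", "year", "count") if c not in self.df.columns]
        if missing:
            raise SchemaError(f"survey table missing required columns: {missing}")
        counts = self.df["count"]
        if (counts < 0).any():
            rows = self.df.index[counts < 0].tolist()
            raise SchemaError(f"negative counts at rows {rows[:5]}")
        if not np.all(np.isfinite(self.df[["lon", "lat"]].to_numpy(float))):
            raise SchemaError("non-finite coordinates")

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.df.columns if c not in RESERVED_COLUMNS]

    @property
    def coords(self) -> np.ndarray:
        return self.df[["lon", "lat"]].to_numpy(float)

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.df["year"].unique())

    @property
    def counts(self) -> np.ndarray:
        return self.df["count"].to_numpy(float)

    def subset(self, mask) -> "SurveyDataset":
        return SurveyDataset(self.df.loc[mask].reset_index(drop=True), truth=self.truth)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class ObservationParams:
    """Count family and its dispersion.

    For the negative binomial, ``phi = log(n)`` with size parameter n and
    variance mu (1 + mu / n).  For the Gaussian harness ``sd`` is the
    (known) observation SD and the link is the identity.
    """

    family: str = "negative_binomial"
    phi: float = 0.0
    sd: float = 1.0

    def __post_init__(self):
        if self.family not in ("poisson", "negative_binomial", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def n(self) -> float:
        return math.exp(self.phi)


@dataclass
class CovariateSmooth:
    """Piecewise-linear covariate effect with an RW2 penalty.

    ``coefficients`` hold the effect at the knots; observations map to a
    convex combination of the two bracketing knots.  The second-difference
    penalty matrix has null space {constant, linear}; a sum-to-zero
    constraint keeps the effect identifiable next to the intercept.
    """

    name: str
    knots: np.ndarray
    coefficients: np.ndarray = dc_field(default=None)
    penalty_precision: np.ndarray = dc_field(default=None)
    smoothing_precision: float = 1.0

    def __post_init__(self):
        self.knots = np.asarray(self.knots, float)
        if self.coefficients is None:
            self.coefficients = np.zeros(len(self.knots))
        if self.penalty_precision is None:
            k = len(self.knots)
            D = np.diff(np.eye(k), n=2, axis=0)
            self.penalty_precision = D.T @ D

    @property
    def n_knots(self) -> int:
        return len(self.knots)

    def design(self, values) -> np.ndarray:
        return smooth_design(np.asarray(values, float), self.knots)

    def evaluate(self, values) -> np.ndarray:
        return self.design(values) @ self.coefficients

    def penalty_quadform(self, coefficients=None) -> float:
        c = self.coefficients if coefficients is None else np.asarray(coefficients, float)
        return float(c @ self.penalty_precision @ c)


def smooth_design(values: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Rows of linear-interpolation weights onto ordered knots.

    Values outside the knot span are clamped to the end knots, so the
    fitted effect is constant beyond the observed covariate range.
    """
    if np.any(~np.isfinite(values)):
        raise MissingDataError("covariate contains missing/non-finite values")
    k = len(knots)
    x = np.clip(values, knots[0], knots[-1])
    idx = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, k - 2)
    left = knots[idx]
    width = knots[idx + 1] - left
    w = np.where(width > 0, (x - left) / np.where(width > 0, width, 1.0), 0.0)
    B = np.zeros((len(values), k))
    B[np.arange(len(values)), idx] = 1.0 - w
    B[np.arange(len(values)), idx + 1] += w
    return B


def build_covariate_smooth(values, n_knots: int = 25, name: str = "covariate") -> CovariateSmooth:
    """Place ``n_knots`` equal-quantile knots over the covariate values."""
    if n_knots < 4:
        raise ValueError("n_knots must be at least 4")
    vals = np.asarray(values, float)
    vals = vals[np.isfinite(vals)]
    distinct = np.unique(vals)
    if distinct.size < n_knots:
        raise ValueError(
            f"need at least n_knots={n_knots} distinct values, got {distinct.size}"
        )
    knots = np.unique(np.quantile(vals, np.linspace(0, 1, n_knots)))
    return CovariateSmooth(name=name, knots=knots)


def collinearity_screen(dataset, threshold: float = 0.9) -> list[frozenset]:
    """Maximal covariate subsets with all pairwise |Pearson r| < threshold.

    Mirrors the modelling rule that covariates correlated at or above 0.9
    (e.g. nitrate and silicate) are never entered together.
    """
    df = dataset.df if isinstance(dataset, SurveyDataset) else pd.DataFrame(dataset)
    names = (
        dataset.covariates
        if isinstance(dataset, SurveyDataset)
        else [c for c in df.columns if c not in RESERVED_COLUMNS]
    )
    if len(names) < 2:
        return [frozenset(names)]
    sub = df[names].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 complete observations")
    for c in names:
        if np.std(sub[c].to_numpy(float)) == 0:
            raise ValueError(f"covariate {c!r} is constant")
    corr = sub.corr().abs().to_numpy()
    ok = corr < threshold  # compatibility graph
    np.fill_diagonal(ok, True)

    # Bron-Kerbosch maximal cliques on the compatibility graph
    cliques: list[frozenset] = []

    def expand(r: set, p: set, x: set):
        if not p and not x:
            cliques.append(frozenset(names[i] for i in r))
            return
        for v in list(p):
            nv = {u for u in range(len(names)) if u != v and ok[v, u]}
            expand(r | {v}, p & nv, x & nv)
            p.remove(v)
            x.add(v)

    expand(set(), set(range(len(names))), set())
    return cliques


def assemble_linear_predictor(field_at_obs, smooth_terms=(), intercept: float = 0.0):
    """eta = intercept + projected field + sum of evaluated covariate smooths.

    ``smooth_terms`` is an iterable of (CovariateSmooth, covariate values)
    pairs; missing covariate values raise :class:`MissingDataError`.
    Returns (eta, mu) with mu = exp(eta).
    """
    eta = np.asarray(field_at_obs, float) + intercept
    for smooth, values in smooth_terms:
        vals = np.asarray(values, float)
        if len(vals) != len(eta):
            raise ValueError("covariate length does not match field length")
        eta = eta + smooth.evaluate(vals)
    return eta, np.exp(eta)


def observation_loglik(counts, eta, params: ObservationParams):
    """Log-likelihood and derivatives with respect to the linear predictor.

    Returns (value, gradient, negative Hessian diagonal), all in eta.
    For count families mu = exp(eta); the Gaussian harness uses the
    identity link (mu = eta).
    """
    y = np.asarray(counts, float)
    eta = np.asarray(eta, float)
    if params.family in ("poisson", "negative_binomial"):
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("counts must be non-negative integers")
        mu = np.exp(eta)
    if params.family == "poisson":
        value = float(np.sum(y * eta - mu - gammaln(y + 1.0)))
        grad = y - mu
        neg_hess = mu
    elif params.family == "negative_binomial":
        n = params.n
        if n > 1e8:
            # gammaln(y+n) - gammaln(n) cancels catastrophically for huge
            # size parameters; sum log(n+k) directly (counts are integers)
            kmax = int(y.max())
            cums = np.concatenate([[0.0], np.cumsum(np.log(n + np.arange(kmax)))])
            rising = cums[y.astype(int)]
        else:
            rising = gammaln(y + n) - gammaln(n)
        value = float(
            np.sum(
                rising
                - gammaln(y + 1.0)
                - n * np.log1p(mu / n)
                + y * (np.log(mu) - np.log(n + mu))
            )
        )
        grad = n * (y - mu) / (n + mu)
        neg_hess = n * mu * (n + y) / (n + mu) ** 2
    else:  # gaussian, identity link
        s2 = params.sd**2
        resid = y - eta
        value = float(-0.5 * np.sum(resid**2) / s2 - 0.5 * len(y) * math.log(2 * math.pi * s2))
        grad = resid / s2
        neg_hess = np.full_like(eta, 1.0 / s2)
    return value, grad, neg_hess
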