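"""Model comparison: DIC, cross-validated CPO/LPML, RMSEE.

Three criteria with the field's usual directions: DIC (expected deviance
plus effective parameters p_D, lower is better), LPML (sum of log
conditional predictive ordinates from W-fold cross-validation, higher is
better), and RMSEE (root mean squared difference between observed counts
and fitted means, lower is better).  The criteria can and do disagree;
``model_comparison_table`` records the disagreements rather than hiding
them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .errors import ComparabilityError
from .inference import FitResult, fit_model
from .observation import ObservationParams, observation_loglik

__all__ = [
    "AssessmentScores",
    "dic",
    "cpo_lpml",
    "rmsee",
    "model_comparison_table",
]

_CPO_FLOOR = 1e-300


@dataclass
class AssessmentScores:
    dic: float = math.nan
    p_d: float = math.nan
    mean_deviance: float = math.nan
    cpo: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    lpml: float = math.nan
    rmsee: float = math.nan
    n_obs: int = 0

    def as_dict(self) -> dict:
        return {
            "dic": self.dic,
            "p_d": self.p_d,
            "mean_deviance": self.mean_deviance,
            "lpml": self.lpml,
            "rmsee": self.rmsee,
            "n_obs": self.n_obs,
        }


def _deviance(y, eta, params: ObservationParams) -> float:
    return -2.0 * observation_loglik(y, eta, params)[0]


def dic(fit: FitResult, n_samples: int = 200, seed: int = 0):
    """Deviance information criterion from the fitted posterior.

    The expected deviance is a Monte Carlo average over latent draws from
    the grid-mixture Gaussian approximation (hyperparameters sampled by
    grid weight); p_D is the expected deviance minus the deviance at the
    posterior mean (plugin at the hyper mode); DIC = E[D] + p_D.  Negative
    p_D is possible under the Laplace approximation and triggers a warning
    rather than an error.

    Returns (dic, p_d, mean_deviance).
    """
    if not fit.hyper_grid:
        raise ValueError("fit has no hyperparameter grid")
    mats = fit.matrices
    y = mats.data.counts
    rng = np.random.default_rng(seed)
    draws, which = fit.sample_latent(n_samples, rng)
    devs = np.empty(n_samples)
    for i, (u, k) in enumerate(zip(draws, which)):
        params = mats.obs_params(fit.hyper_grid[k].theta)
        devs[i] = _deviance(y, mats.X @ u, params)
    mean_dev = float(np.mean(devs))
    dev_at_mean = _deviance(y, mats.X @ fit.latent_mean, mats.obs_params(fit.hyper_mode))
    p_d = mean_dev - dev_at_mean
    if p_d < 0:
        warnings.warn(f"negative effective parameter count p_D = {p_d:.3f}")
    return mean_dev + p_d, p_d, mean_dev


def _predictive_density(y, eta_mean, eta_sd, params: ObservationParams, gh_order: int = 31):
    """Per-observation predictive density integrating over eta ~ N(m, s^2).

    Gaussian family is integrated analytically; count families use
    Gauss-Hermite quadrature on the eta marginal.
    """
    y = np.asarray(y, float)
    m = np.asarray(eta_mean, float)
    s = np.asarray(eta_sd, float)
    if params.family == "gaussian":
        var = params.sd**2 + s**2
        return np.exp(-0.5 * (y - m) ** 2 / var) / np.sqrt(2 * np.pi * var)
    nodes, weights = np.polynomial.hermite_e.hermegauss(gh_order)
    # eta = m + s * node, weights sum to sqrt(2 pi)
    dens = np.zeros_like(y)
    for x, w in zip(nodes, weights):
        eta = m + s * x
        ll = np.array(
            [observation_loglik([yi], [ei], params)[0] for yi, ei in zip(y, eta)]
        )
        dens += w * np.exp(ll)
    return dens / math.sqrt(2 * math.pi)


def cpo_lpml(data, spec, W: int = 20, seed: int = 0, mesh=None, **fit_kwargs):
    """W-fold cross-validated CPO per observation and LPML.

    Observations are partitioned into W equal-sized random folds (seeded);
    the model is refit without each fold (hyperparameter mode and latent
    field both refit on the retained data) and each held-out observation's
    predictive density is evaluated under its own fold's fit.  With W = n
    the folds are singletons and CPO is exact leave-one-out.  LPML is the
    sum of log CPO; larger is better.

    Returns (cpo array aligned with ``data``, lpml).  Densities that
    underflow are floored at 1e-300 (counted in a warning).
    """
    n = len(data)
    if W < 2:
        raise ValueError("W must be at least 2")
    if W > n:
        raise ValueError("more folds than observations")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = [perm[i::W] for i in range(W)]

    if mesh is None:
        from .mesh import build_mesh

        coords = data.coords
        extent = float(np.hypot(*(coords.max(axis=0) - coords.min(axis=0))))
        max_edge = fit_kwargs.pop("max_edge", extent / 8.0)
        cutoff = fit_kwargs.pop("cutoff", max_edge / 10.0)
        mesh = build_mesh(coords, max_edge=max_edge, cutoff=cutoff)

    from .inference import predict_surface  # local import to avoid cycle noise

    cpo = np.empty(n)
    n_floored = 0
    for fold in folds:
        keep = np.setdiff1d(np.arange(n), fold)
        fit = fit_model(data.subset(keep), spec, mesh=mesh, **fit_kwargs)
        mats = fit.matrices
        held = data.subset(fold)
        # design rows for held-out observations against the fold's fit
        cov_vals = {c: held.df[c].to_numpy(float) for c in spec.covariates}
        if mats.T_field > 1:
            m_list, s_list = [], []
            for yr in np.unique(held.df["year"]):
                sel = held.df["year"].to_numpy() == yr
                res = predict_surface(
                    fit,
                    held.coords[sel],
                    year=yr,
                    covariate_values={c: v[sel] for c, v in cov_vals.items()},
                )
                m_list.append((sel, res["mean"], res["sd"]))
            m = np.empty(len(held))
            s = np.empty(len(held))
            for sel, mm, ss in m_list:
                m[sel] = mm
                s[sel] = ss
        else:
            res = predict_surface(fit, held.coords, covariate_values=cov_vals)
            m, s = res["mean"], res["sd"]
        params = mats.obs_params(fit.hyper_mode)
        dens = _predictive_density(held.counts, m, s, params)
        low = dens < _CPO_FLOOR
        n_floored += int(low.sum())
        cpo[fold] = np.maximum(dens, _CPO_FLOOR)
    if n_floored:
        warnings.warn(f"{n_floored} predictive densities floored at {_CPO_FLOOR}")
    lpml = float(np.sum(np.log(cpo)))
    return cpo, lpml


def rmsee(fit: FitResult, data=None, plugin: bool = False) -> float:
    """Root mean squared estimation error between counts and fitted means.

    By default the fitted mean on the response scale includes the
    lognormal half-variance correction exp(eta_mean + eta_var / 2); with
    ``plugin=True`` the plain exp(eta_mean) is used.
    """
    y = (data.counts if data is not None else fit.data.counts).astype(float)
    if fit.spec.family == "gaussian":
        mu = fit.eta_mean
    elif plugin or fit.eta_sd is None:
        mu = np.exp(fit.eta_mean)
    else:
        mu = np.exp(fit.eta_mean + 0.5 * fit.eta_sd**2)
    if len(y) != len(mu):
        raise ValueError("counts and fitted means have different lengths")
    return float(np.sqrt(np.mean((y - mu) ** 2)))


def assess(fit: FitResult, W: int | None = None, seed: int = 0, **cv_kwargs) -> AssessmentScores:
    """All-in-one scores for a fit; CPO/LPML only when ``W`` is given."""
    d, p_d, mean_dev = dic(fit, seed=seed)
    scores = AssessmentScores(
        dic=d, p_d=p_d, mean_deviance=mean_dev, rmsee=rmsee(fit), n_obs=len(fit.data)
    )
    if W is not None:
        scores.cpo, scores.lpml = cpo_lpml(
            fit.data, fit.spec, W=W, seed=seed, mesh=fit.mesh, **cv_kwargs
        )
    fit.assessment = scores.as_dict()
    return scores


def model_comparison_table(fits: list[FitResult], labels=None, seed: int = 0) -> pd.DataFrame:
    """Rank candidate fits on identical data by DIC (↓), LPML (↑), RMSEE (↓).

    Requires at least two fits on the same observations; flags the best
    fit under each criterion and whether the criteria disagree.  LPML
    columns are filled only for fits whose assessment already contains
    them (cross-validation is expensive and must be requested explicitly
    via :func:`assess`).
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    y0 = fits[0].data.counts
    for f in fits[1:]:
        if len(f.data) != len(y0) or not np.array_equal(f.data.counts, y0):
            raise ComparabilityError("fits were not computed on identical data")
    if labels is None:
        labels = []
        for f in fits:
            cov = "+".join(f.spec.covariates) or "none"
            labels.append(f"{f.spec.spatial_structure}|{cov}")
    for f in fits:
        if not f.assessment:
            d, p_d, mean_dev = dic(f, seed=seed)
            f.assessment = {
                "dic": d,
                "p_d": p_d,
                "mean_deviance": mean_dev,
                "lpml": math.nan,
                "rmsee": rmsee(f),
                "n_obs": len(f.data),
            }
    table = pd.DataFrame(
        {
            "model": labels,
            "dic": [f.assessment["dic"] for f in fits],
            "lpml": [f.assessment.get("lpml", math.nan) for f in fits],
            "rmsee": [f.assessment["rmsee"] for f in fits],
        }
    )
    table["best_dic"] = table["dic"] == table["dic"].min()
    table["best_lpml"] = (
        table["lpml"] == table["lpml"].max() if table["lpml"].notna().any() else False
    )
    table["best_rmsee"] = table["rmsee"] == table["rmsee"].min()
    winners = set()
    winners.add(table.loc[table["dic"].idxmin(), "model"])
    if table["lpml"].notna().any():
        winners.add(table.loc[table["lpml"].idxmax(), "model"])
    winners.add(table.loc[table["rmsee"].idxmin(), "model"])
    table.attrs["criteria_disagree"] = len(winners) > 1
    table.attrs["ties"] = {
        "dic": int(table["best_dic"].sum()) > 1,
        "rmsee": int(table["best_rmsee"].sum()) > 1,
    }
    return table.sort_values("dic").reset_index(drop=True)
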