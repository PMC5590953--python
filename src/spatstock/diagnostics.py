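"""Spatial stock-structure diagnostics.

Four tools for reading stock structure off the fitted model:

* relative exploitation — a sub-zone's share of landings divided by its
  share of survey abundance; values above 1 mean the zone is harvested
  out of proportion to the fish it holds;
* annual parameter series — the model refit to each year alone (no
  persistence term) giving per-year connectivity rho_t and spatial
  variance sigma_t;
* core-range masks — the part of the prediction grid at or above the
  75th percentile of predicted abundance, with connected patches, areas
  and separations (also in multiples of the fitted range);
* erosion classification — labelling of consecutive-year (rho_t,
  sigma_t) movements: a large move to larger rho with falling sigma is
  erosion of structure (local overfishing signature), the mirror move is
  recovery, small moves are normal fluctuation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConvergenceError, SchemaError
from .inference import ModelSpec, fit_model
from .observation import SurveyDataset

__all__ = [
    "RelativeExploitationTable",
    "ErosionTrajectory",
    "CoreRangeMask",
    "relative_exploitation",
    "annual_parameter_series",
    "core_range_mask",
    "erosion_classify",
    "DEFAULT_DELTA",
]

DEFAULT_DELTA = math.log(1.5)


@dataclass
class RelativeExploitationTable:
    """Per (sub-zone, year) landings share over survey-abundance share."""

    df: pd.DataFrame
    excluded_years: list = dc_field(default_factory=list)

    def attach_to_survey(self, survey: SurveyDataset, column: str = "re") -> SurveyDataset:
        """Join RE back onto survey records as a covariate column.

        Records in (zone, year) cells with undefined RE receive NaN; the
        number of such records is reported in a warning so downstream
        smooths can drop them explicitly.
        """
        merged = survey.df.merge(
            self.df[["subzone", "year", "re"]], on=["subzone", "year"], how="left"
        )
        merged = merged.rename(columns={"re": column})
        n_missing = int(merged[column].isna().sum())
        if n_missing:
            warnings.warn(f"{n_missing} survey records have undefined relative exploitation")
        return SurveyDataset(merged, truth=survey.truth)


def relative_exploitation(landings: pd.DataFrame, survey: SurveyDataset) -> RelativeExploitationTable:
    """RE(i, t) = (landings share of zone i in year t) / (survey share).

    Zones with zero survey abundance but positive landings get RE = NaN
    (flagged undefined, never infinity); years with zero total survey
    count are excluded with a warning.
    """
    for col in ("subzone", "year", "landings"):
        if col not in landings.columns:
            raise SchemaError(f"landings table missing column {col!r}")
    if "subzone" not in survey.df.columns:
        raise SchemaError("survey has no subzone labels")
    obis = (
        survey.df.groupby(["subzone", "year"])["count"].sum().rename("obis").reset_index()
    )
    land = landings.groupby(["subzone", "year"])["landings"].sum().reset_index()
    merged = land.merge(obis, on=["subzone", "year"], how="outer").fillna({"landings": 0.0, "obis": 0.0})

    rows = []
    excluded = []
    for year, grp in merged.groupby("year"):
        landings_t = grp["landings"].sum()
        obis_t = grp["obis"].sum()
        if obis_t <= 0:
            excluded.append(int(year))
            continue
        if landings_t <= 0:
            excluded.append(int(year))
            continue
        for _, r in grp.iterrows():
            share_land = r["landings"] / landings_t
            share_obis = r["obis"] / obis_t
            if share_obis > 0:
                re_val = share_land / share_obis
            else:
                re_val = math.nan if r["landings"] > 0 else 0.0
            rows.append(
                (r["subzone"], int(year), r["landings"], landings_t, r["obis"], obis_t, re_val)
            )
    if excluded:
        warnings.warn(f"years excluded from RE (zero totals): {excluded}")
    df = pd.DataFrame(
        rows,
        columns=["subzone", "year", "landings", "landings_total", "obis", "obis_total", "re"],
    )
    if (df["re"].dropna() < 0).any():  # pragma: no cover - shares are non-negative
        raise ValueError("negative relative exploitation")
    return RelativeExploitationTable(df, excluded_years=excluded)


@dataclass
class ErosionTrajectory:
    """Per-year (rho_t, sigma_t) estimates with transition labels.

    ``series`` has one row per year with columns year, rho, sigma,
    n_sets, status ('ok' | 'too_few_sets' | 'failed') and
    rho_exceeds_domain; ``transitions`` is filled by
    :func:`erosion_classify`.
    """

    series: pd.DataFrame
    transitions: pd.DataFrame | None = None
    domain_diameter: float | None = None

    def valid(self) -> pd.DataFrame:
        return self.series[self.series["status"] == "ok"]


def annual_parameter_series(
    data: SurveyDataset,
    spec: ModelSpec | None = None,
    mesh=None,
    min_sets: int = 30,
    **fit_kwargs,
) -> ErosionTrajectory:
    """Refit the spatial model to each year alone and record (rho_t, sigma_t).

    The per-year model has a single spatial field (no persistence).  Years
    with fewer than ``min_sets`` sets, or whose fit fails, are marked
    missing rather than dropped silently.  Estimated ranges larger than
    the domain diameter are flagged, never clamped.
    """
    if spec is None:
        spec = ModelSpec(spatial_structure="constant")
    else:
        spec = ModelSpec(
            spatial_structure="constant",
            covariates=spec.covariates,
            family=spec.family,
            n_knots=spec.n_knots,
            pc_prior=spec.pc_prior,
        )
    coords = data.coords
    diam = float(np.hypot(*(coords.max(axis=0) - coords.min(axis=0))))
    if mesh is None:
        from .mesh import build_mesh

        max_edge = fit_kwargs.pop("max_edge", diam / 10.0)
        cutoff = fit_kwargs.pop("cutoff", max_edge / 3.0)
        mesh = build_mesh(coords, max_edge=max_edge, cutoff=cutoff)
    fit_kwargs.setdefault("grid", False)
    fit_kwargs.setdefault("compute_marginals", False)
    fit_kwargs.setdefault("maxfev", 60)

    rows = []
    any_ok = False
    for year in data.years:
        sub = data.subset(data.df["year"].to_numpy() == year)
        if len(sub) < min_sets:
            rows.append((int(year), math.nan, math.nan, len(sub), "too_few_sets", False))
            continue
        try:
            fit = fit_model(sub, spec, mesh=mesh, **fit_kwargs)
        except ConvergenceError:
            rows.append((int(year), math.nan, math.nan, len(sub), "failed", False))
            continue
        rho_t = fit.hyper_mode.rho
        sigma_t = fit.hyper_mode.sigma
        rows.append((int(year), rho_t, sigma_t, len(sub), "ok", rho_t > diam))
        any_ok = True
    if not any_ok:
        raise ConvergenceError("every annual fit failed or had too few sets")
    series = pd.DataFrame(
        rows, columns=["year", "rho", "sigma", "n_sets", "status", "rho_exceeds_domain"]
    )
    return ErosionTrajectory(series=series, domain_diameter=diam)


@dataclass
class CoreRangeMask:
    """Thresholded abundance surface with its connected patches."""

    year: object
    threshold: float
    mask: np.ndarray  # 2-D bool
    patches: list  # dicts: label, n_cells, area, centroid, max_value
    separations: pd.DataFrame
    degenerate: bool = False
    n_finite_cells: int = 0

    @property
    def masked_fraction(self) -> float:
        """Fraction of in-domain (finite) cells at or above the threshold."""
        denom = self.n_finite_cells or self.mask.size
        return float(self.mask.sum()) / denom


def _mask_one(surface, threshold, x, y, rho):
    finite = np.isfinite(surface)
    mask = np.zeros_like(surface, dtype=bool)
    mask[finite] = surface[finite] >= threshold
    labels, n_patch = ndimage.label(mask, structure=np.ones((3, 3)))
    dx = float(x[1] - x[0]) if len(x) > 1 else 1.0
    dy = float(y[1] - y[0]) if len(y) > 1 else 1.0
    patches = []
    for lab in range(1, n_patch + 1):
        sel = labels == lab
        ii, jj = np.nonzero(sel)
        patches.append(
            {
                "label": lab,
                "n_cells": int(sel.sum()),
                "area": float(sel.sum() * dx * dy),
                "centroid": (float(np.mean(x[jj])), float(np.mean(y[ii]))),
                "max_value": float(np.nanmax(surface[sel])),
            }
        )
    sep_rows = []
    for i in range(len(patches)):
        for j in range(i + 1, len(patches)):
            ci, cj = patches[i]["centroid"], patches[j]["centroid"]
            d = math.hypot(ci[0] - cj[0], ci[1] - cj[1])
            sep_rows.append(
                {
                    "patch_a": patches[i]["label"],
                    "patch_b": patches[j]["label"],
                    "separation": d,
                    "separation_over_rho": d / rho if rho else math.nan,
                }
            )
    separations = pd.DataFrame(
        sep_rows, columns=["patch_a", "patch_b", "separation", "separation_over_rho"]
    )
    return mask, patches, separations


def core_range_mask(
    surfaces,
    quantile: float = 0.75,
    x=None,
    y=None,
    pooled: bool = True,
    rho: float | None = None,
):
    """Mask the cells where predicted abundance meets or exceeds a quantile.

    ``surfaces`` is a 2-D array (one year) or a mapping year -> 2-D array.
    By default the threshold is the pooled quantile across all supplied
    years so that a contraction of the core range is visible as shrinking
    masks; ``pooled=False`` thresholds each year on its own values.  NaN
    cells (outside the domain) never enter the quantile or the mask.
    Patches are 8-connected components; separations are centroid
    distances, also reported in multiples of ``rho`` when given.
    """
    single = not isinstance(surfaces, dict)
    surf_map = {None: np.asarray(surfaces, float)} if single else {
        k: np.asarray(v, float) for k, v in surfaces.items()
    }
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    shapes = {v.shape for v in surf_map.values()}
    if len(shapes) != 1:
        raise ValueError("all surfaces must share one grid shape")
    shape = shapes.pop()
    if x is None:
        x = np.arange(shape[1], dtype=float)
    if y is None:
        y = np.arange(shape[0], dtype=float)

    all_vals = np.concatenate([v[np.isfinite(v)].ravel() for v in surf_map.values()])
    if all_vals.size == 0:
        raise ValueError("no finite surface values")
    pooled_thr = float(np.quantile(all_vals, quantile))

    out = []
    for year, surf in surf_map.items():
        finite_vals = surf[np.isfinite(surf)]
        thr = pooled_thr if pooled else float(np.quantile(finite_vals, quantile))
        degenerate = bool(np.all(finite_vals == finite_vals.flat[0]))
        mask, patches, seps = _mask_one(surf, thr, np.asarray(x, float), np.asarray(y, float), rho)
        out.append(
            CoreRangeMask(
                year=year,
                threshold=thr,
                mask=mask,
                patches=patches,
                separations=seps,
                degenerate=degenerate,
                n_finite_cells=int(np.isfinite(surf).sum()),
            )
        )
    return out[0] if single else out


def _label_transition(d_log_rho: float, d_log_sigma: float, delta_rho: float, delta_sigma: float) -> str:
    """Quadrant label for one year-to-year movement of (rho, sigma).

    A movement is erosion when at least one axis moves beyond its
    threshold toward the flattened-field corner (rho up, sigma down) and
    the other axis does not oppose it; recovery is the exact mirror, so
    reversing time swaps the two labels.  Movements inside the thresholds
    on both axes are ordinary fluctuation; anything else (large opposing
    moves) is reported as stable.
    """
    big_rho_up = d_log_rho > delta_rho
    big_rho_down = d_log_rho < -delta_rho
    big_sig_up = d_log_sigma > delta_sigma
    big_sig_down = d_log_sigma < -delta_sigma
    if not (big_rho_up or big_rho_down or big_sig_up or big_sig_down):
        return "fluctuation"
    if (big_rho_up and d_log_sigma <= 0) or (big_sig_down and d_log_rho >= 0):
        return "erosion"
    if (big_rho_down and d_log_sigma >= 0) or (big_sig_up and d_log_rho <= 0):
        return "recovery"
    return "stable"


def erosion_classify(
    trajectory: ErosionTrajectory,
    delta_rho: float = DEFAULT_DELTA,
    delta_sigma: float = DEFAULT_DELTA,
) -> ErosionTrajectory:
    """Label every consecutive-year transition of the (rho, sigma) series.

    Transitions involving a missing year are skipped and reported with
    label 'skipped'.  Thresholds are on the log scale (default log 1.5:
    a 50% change counts as large).
    """
    ser = trajectory.series
    if len(ser) < 2:
        raise ValueError("need at least 2 years to classify transitions")
    rows = []
    years = ser["year"].to_numpy()
    for k in range(len(ser) - 1):
        r0, r1 = ser.iloc[k], ser.iloc[k + 1]
        if r0["status"] != "ok" or r1["status"] != "ok":
            rows.append((int(years[k]), int(years[k + 1]), math.nan, math.nan, "skipped"))
            continue
        dlr = math.log(r1["rho"] / r0["rho"])
        dls = math.log(r1["sigma"] / r0["sigma"])
        rows.append(
            (int(years[k]), int(years[k + 1]), dlr, dls, _label_transition(dlr, dls, delta_rho, delta_sigma))
        )
    trans = pd.DataFrame(
        rows, columns=["year_from", "year_to", "d_log_rho", "d_log_sigma", "label"]
    )
    return ErosionTrajectory(
        series=ser, transitions=trans, domain_diameter=trajectory.domain_diameter
    )
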