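"""Readers, writers and run configuration.

CSV is the canonical tabular format (survey and landings tables), GeoJSON
carries sub-zone polygons, JSON carries artifacts (mesh, fit summaries,
scores).  Survey CSV schema: required columns ``lon``, ``lat``, ``year``,
``count``; optional ``subzone`` and ``distance_towed``; every other
column is preserved as a covariate.  Landings CSV schema: ``subzone``,
``year``, ``landings``.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import shape

from .errors import ConfigError, SchemaError
from .field import PcPrior
from .observation import SurveyDataset

__all__ = [
    "read_survey_csv",
    "write_survey_csv",
    "read_landings_csv",
    "write_landings_csv",
    "read_zones_geojson",
    "assign_subzones",
    "RunConfig",
    "fit_artifact",
    "write_json",
]

SURVEY_REQUIRED = ("lon", "lat", "year", "count")
LANDINGS_REQUIRED = ("subzone", "year", "landings")


def _require_columns(df: pd.DataFrame, required, what: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {missing}")


def read_survey_csv(path) -> SurveyDataset:
    """Read a trawl survey table; unknown columns become covariates."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"survey file not found: {path}")
    df = pd.read_csv(path)
    _require_columns(df, SURVEY_REQUIRED, f"survey table {path}")
    for col, kind in (("lon", float), ("lat", float), ("year", int), ("count", int)):
        try:
            df[col] = df[col].astype(kind)
        except (ValueError, TypeError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
            raise SchemaError(
                f"column {col!r} unparsable as {kind.__name__} at row(s) {bad[:5]}"
            ) from exc
    return SurveyDataset(df)


def write_survey_csv(data: SurveyDataset, path) -> None:
    data.df.to_csv(path, index=False)


def read_landings_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"landings file not found: {path}")
    df = pd.read_csv(path)
    _require_columns(df, LANDINGS_REQUIRED, f"landings table {path}")
    try:
        df["landings"] = df["landings"].astype(float)
        df["year"] = df["year"].astype(int)
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"unparsable landings/year values in {path}") from exc
    if (df["landings"] < 0).any():
        rows = df.index[df["landings"] < 0].tolist()
        raise SchemaError(f"negative landings at row(s) {rows[:5]}")
    return df


def write_landings_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_zones_geojson(path) -> dict:
    """Sub-zone polygons keyed by their 'name' (or 'id') property."""
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    zones = {}
    for i, feat in enumerate(feats):
        props = feat.get("properties") or {}
        name = props.get("name") or props.get("id") or f"zone_{i}"
        zones[str(name)] = shape(feat["geometry"])
    if not zones:
        raise SchemaError(f"no polygon features in {path}")
    return zones


def write_zones_geojson(zones: dict, path) -> None:
    feats = []
    for name in sorted(zones):
        geom = zones[name]
        feats.append(
            {
                "type": "Feature",
                "properties": {"name": name},
                "geometry": json.loads(json.dumps(geom.__geo_interface__)),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def assign_subzones(data: SurveyDataset, zones: dict) -> SurveyDataset:
    """Point-in-polygon sub-zone assignment.

    Zones are tried in alphabetical label order and boundary points go to
    the first (lowest-label) zone that covers them; records outside every
    zone get a missing label.
    """
    labels = np.full(len(data), None, dtype=object)
    coords = data.coords
    for name in sorted(zones):
        geom = zones[name]
        unset = np.array([lab is None for lab in labels])
        if not unset.any():
            break
        import shapely

        hit = shapely.intersects_xy(geom, coords[unset, 0], coords[unset, 1])
        idx = np.where(unset)[0][hit]
        labels[idx] = name
    df = data.df.copy()
    df["subzone"] = labels
    return SurveyDataset(df, truth=data.truth)


@dataclass
class RunConfig:
    """Validated run settings with the model's default prior calibration.

    Prior defaults: reference range 0.5 with P(rho < 0.5) = 0.5, reference
    SD 0.75 with P(sigma > 0.75) = 0.5; core-range quantile 0.75;
    smoothness nu fixed at 1.
    """

    survey: str | None = None
    landings: str | None = None
    zones: str | None = None
    spatial_structure: str = "ar1"
    covariates: list = dc_field(default_factory=list)
    family: str = "negative_binomial"
    rho0: float = 0.5
    alpha_rho: float = 0.5
    sigma0: float = 0.75
    alpha_sigma: float = 0.5
    max_edge: float | None = None
    cutoff: float | None = None
    folds: int = 20
    seed: int = 0
    quantile: float = 0.75
    delta_rho: float = math.log(1.5)
    delta_sigma: float = math.log(1.5)
    min_sets: int = 30

    _NUMERIC = {
        "rho0": (0, None),
        "alpha_rho": (0, 1),
        "sigma0": (0, None),
        "alpha_sigma": (0, 1),
        "quantile": (0, 1),
        "delta_rho": (0, None),
        "delta_sigma": (0, None),
    }

    def __post_init__(self):
        if self.spatial_structure not in ("none", "constant", "replicated_by_year", "ar1"):
            raise ConfigError(f"unknown spatial_structure {self.spatial_structure!r}")
        if self.family not in ("poisson", "negative_binomial"):
            raise ConfigError(f"unknown family {self.family!r}")
        for name, (lo, hi) in self._NUMERIC.items():
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ConfigError(f"{name} must be a finite number, got {v!r}")
            if v <= lo or (hi is not None and v >= hi):
                hi_txt = f", {hi}" if hi is not None else ", inf"
                raise ConfigError(f"{name} must lie in ({lo}{hi_txt}), got {v}")
        if self.folds < 2:
            raise ConfigError("folds must be at least 2")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def pc_prior(self) -> PcPrior:
        return PcPrior(
            rho0=self.rho0,
            alpha_rho=self.alpha_rho,
            sigma0=self.sigma0,
            alpha_sigma=self.alpha_sigma,
        )

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def fit_artifact(fit, config: RunConfig | None = None) -> dict:
    """JSON-ready summary of a fit: hyper mode/grid and latent summaries."""
    spec_payload = {
        "spatial_structure": fit.spec.spatial_structure,
        "covariates": list(fit.spec.covariates),
        "family": fit.spec.family,
        "n_knots": fit.spec.n_knots,
    }
    art = {
        "spec": spec_payload,
        "spec_hash": hashlib.sha256(
            json.dumps(spec_payload, sort_keys=True).encode()
        ).hexdigest()[:12],
        "hyper": fit.hyper_summary(),
        "hyper_grid": [
            {"theta": gp.theta.as_dict(), "weight": gp.weight, "log_post": gp.log_post}
            for gp in fit.hyper_grid
        ],
        "log_marginal": fit.log_marginal,
        "n_obs": len(fit.data),
        "n_vertices": fit.mesh.n_vertices,
        "eta_mean": np.asarray(fit.eta_mean).tolist(),
        "eta_sd": None if fit.eta_sd is None else np.asarray(fit.eta_sd).tolist(),
        "fitted_mu": np.asarray(fit.fitted_mu).tolist(),
        "assessment": fit.assessment,
        "boundary_warning": fit.boundary_warning,
    }
    if config is not None:
        art["config_hash"] = config.hash()
    return art


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=default, allow_nan=True)
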