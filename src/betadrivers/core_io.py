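"""Shared data containers, file I/O and pairwise distance operations.

The pipeline studies river macroinvertebrate metacommunities sampled at
georeferenced sites across regions and months.  Its inputs are a
site-by-taxon count matrix, a site table (coordinates, altitude, region),
a physicochemical table and a categorical land-use raster; this module
holds the containers those files load into and the three pairwise
distances every downstream stage consumes:

* great-circle (haversine) geographic distance in metres,
* absolute altitude difference in metres,
* normalised environmental dissimilarity
  ``Ed = Euc / Euc_max + 0.001``,
  where ``Euc`` is the Euclidean distance between the (optionally
  z-scored) environmental vectors of two sites and ``Euc_max`` the
  largest such distance in the set.  The 0.001 offset keeps identical
  sites from registering null dissimilarity, so Ed lives in
  [0.001, 1.001].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.distance import pdist, squareform

#: Mean Earth radius in metres, used by the haversine distance.
EARTH_RADIUS_M = 6371008.8


class ValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CommunityMatrix:
    """Non-negative integer abundance table, sites x taxa.

    Abundances are individual counts (field surveys report density in
    individuals per square metre; any constant area factor is irrelevant
    to every dissimilarity computed here).
    """

    site_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.site_ids), len(self.taxon_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.taxon_ids)} taxa"
            )
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValidationError("duplicate site ids in community matrix")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValidationError("duplicate taxon ids in community matrix")
        if len(self.site_ids) < 2 or len(self.taxon_ids) < 1:
            raise ValidationError("need at least 2 sites and 1 taxon")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded, atol=1e-9):
                raise ValidationError("community counts must be integers")
            self.counts = rounded.astype(np.int64)
        if (self.counts < 0).any():
            raise ValidationError("community counts must be non-negative")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def empty_sites(self) -> list[str]:
        """Ids of sites with zero total abundance."""
        totals = self.counts.sum(axis=1)
        return [s for s, t in zip(self.site_ids, totals) if t == 0]

    def require_no_empty_sites(self) -> None:
        empty = self.empty_sites()
        if empty:
            raise ValidationError(
                f"sites with zero total abundance: {empty}; drop them or "
                "pass allow_empty_sites=True where supported"
            )

    def subset_sites(self, ids: Sequence[str]) -> "CommunityMatrix":
        idx = [self.site_ids.index(s) for s in ids]
        return CommunityMatrix(list(ids), list(self.taxon_ids), self.counts[idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.site_ids, columns=self.taxon_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CommunityMatrix":
        return cls(
            [str(s) for s in df.index],
            [str(t) for t in df.columns],
            df.to_numpy(),
        )

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "site_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path, allow_empty_sites: bool = False) -> "CommunityMatrix":
        df = pd.read_csv(path, index_col=0)
        cm = cls.from_dataframe(df)
        if not allow_empty_sites:
            cm.require_no_empty_sites()
        return cm


@dataclass
class SiteRecord:
    """One sampling site: position, altitude and design labels.

    ``x``/``y`` are optional projected (metric) coordinates used for
    raster buffer extraction; longitude/latitude drive the geographic
    distance matrix.
    """

    site_id: str
    longitude: float
    latitude: float
    altitude: float
    region: str = ""
    month: str = ""
    x: float = float("nan")
    y: float = float("nan")

    def __post_init__(self) -> None:
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(f"{self.site_id}: longitude {self.longitude} out of range")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(f"{self.site_id}: latitude {self.latitude} out of range")


def sites_to_dataframe(sites: Sequence[SiteRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "longitude": [s.longitude for s in sites],
            "latitude": [s.latitude for s in sites],
            "altitude": [s.altitude for s in sites],
            "region": [s.region for s in sites],
            "x": [s.x for s in sites],
            "y": [s.y for s in sites],
        }
    )


def sites_from_dataframe(df: pd.DataFrame) -> list[SiteRecord]:
    records = []
    for _, row in df.iterrows():
        records.append(
            SiteRecord(
                site_id=str(row["site_id"]),
                longitude=float(row["longitude"]),
                latitude=float(row["latitude"]),
                altitude=float(row["altitude"]),
                region=str(row.get("region", "")),
                x=float(row["x"]) if "x" in row else float("nan"),
                y=float(row["y"]) if "y" in row else float("nan"),
            )
        )
    if len({r.site_id for r in records}) != len(records):
        raise ValidationError("duplicate site ids in site table")
    return records


def sites_from_csv(path) -> list[SiteRecord]:
    return sites_from_dataframe(pd.read_csv(path))


def sites_to_csv(sites: Sequence[SiteRecord], path) -> None:
    sites_to_dataframe(sites).to_csv(path, index=False)


@dataclass
class EnvMatrix:
    """Per-site environmental (physicochemical) variables, one row per site."""

    site_ids: list[str]
    variable_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.site_ids), len(self.variable_names)):
            raise ValidationError("env values shape mismatch")
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValidationError("duplicate site ids in env matrix")

    def validate(self, impute_median: bool = False) -> "EnvMatrix":
        """Refuse missing values, or optionally impute per-variable medians."""
        if np.isnan(self.values).any():
            if not impute_median:
                bad = [
                    v
                    for j, v in enumerate(self.variable_names)
                    if np.isnan(self.values[:, j]).any()
                ]
                raise ValidationError(f"missing env values in variables: {bad}")
            for j in range(self.values.shape[1]):
                col = self.values[:, j]
                if np.isnan(col).any():
                    med = np.nanmedian(col)
                    warnings.warn(
                        f"imputed median {med:g} for variable "
                        f"{self.variable_names[j]}"
                    )
                    col[np.isnan(col)] = med
        return self

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.variable_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "EnvMatrix":
        return cls([str(s) for s in df.index], [str(v) for v in df.columns], df.to_numpy(float))

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "site_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "EnvMatrix":
        return cls.from_dataframe(pd.read_csv(path, index_col=0))

    def subset(self, variables: Sequence[str]) -> "EnvMatrix":
        idx = [self.variable_names.index(v) for v in variables]
        return EnvMatrix(list(self.site_ids), list(variables), self.values[:, idx])


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise matrix with a metric label and optional components.

    ``components`` holds same-shaped matrices for additive partitions
    (keys ``"turnover"`` and ``"nestedness"``); ``meta`` records
    provenance flags such as whether variables were standardised.
    """

    site_ids: list[str]
    metric: str
    values: np.ndarray
    components: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.site_ids)
        if self.values.shape != (n, n):
            raise ValidationError("dissimilarity matrix must be square over site ids")
        if not np.isfinite(self.values).all():
            # NaNs are allowed only where explicitly flagged (empty-site pairs)
            if not self.meta.get("allow_nan", False):
                raise ValidationError(f"{self.metric}: non-finite dissimilarities")
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(self.values - self.values.T)) > 1e-10:
                raise ValidationError(f"{self.metric}: matrix not symmetric")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def condensed(self, component: str | None = None) -> np.ndarray:
        """Upper-triangle values in scipy ``pdist`` order."""
        mat = self.values if component is None else self.components[component]
        iu = np.triu_indices(self.n_sites, k=1)
        return mat[iu]

    def pair_index(self) -> pd.MultiIndex:
        iu = np.triu_indices(self.n_sites, k=1)
        ids = np.asarray(self.site_ids)
        return pd.MultiIndex.from_arrays([ids[iu[0]], ids[iu[1]]], names=["site_i", "site_j"])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.site_ids)

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "site_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path, metric: str = "") -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls([str(s) for s in df.index], metric, df.to_numpy(float))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: Land-use class codes used throughout (raster codes 1..7).
DEFAULT_CLASS_NAMES: dict[int, str] = {
    1: "cultivated",
    2: "forest",
    3: "grass",
    4: "construction",
    5: "water",
    6: "wetland",
    7: "bare",
}

# Construction-land-equivalent conversion coefficients for the human
# activity intensity index (HAILS).  SYNTHETIC placeholder table for
# testing: the authoritative per-class coefficients live in the source
# supplement and must be transcribed by the user for real analyses.
DEFAULT_HAILS_CI: dict[str, float] = {
    "cultivated": 0.2,
    "forest": 0.067,
    "grass": 0.067,
    "construction": 1.0,
    "water": 0.1,
    "wetland": 0.067,
    "bare": 0.05,
}


def _default_wqi_params() -> list[dict]:
    """SYNTHETIC placeholder WQI parameter table (weights 1-4, piecewise
    linear normalisation curves mapping measured values to scores in
    [0, 100]).  Real analyses must transcribe the published parameter
    settings; these curves only match the synthetic generator's ranges.
    """

    def down(lo, hi):
        # score 100 at/below lo, 0 at/above hi
        return [[lo, 100.0], [hi, 0.0]]

    def up(lo, hi):
        return [[lo, 0.0], [hi, 100.0]]

    return [
        {"name": "pH", "weight": 1, "curve": [[5.5, 0.0], [7.5, 100.0], [9.5, 0.0]]},
        {"name": "WT", "weight": 1, "curve": down(0.0, 35.0)},
        {"name": "EC", "weight": 2, "curve": down(0.0, 2500.0)},
        {"name": "TUR", "weight": 2, "curve": down(0.0, 130.0)},
        {"name": "DO", "weight": 4, "curve": up(0.0, 13.0)},
        {"name": "TDS", "weight": 2, "curve": down(0.0, 1600.0)},
        {"name": "TN", "weight": 3, "curve": down(0.0, 6.5)},
        {"name": "NH3-N", "weight": 3, "curve": down(0.0, 3.2)},
        {"name": "NO2-N", "weight": 2, "curve": down(0.0, 0.65)},
        {"name": "NO3-N", "weight": 2, "curve": down(0.0, 8.0)},
        {"name": "TP", "weight": 3, "curve": down(0.0, 0.85)},
        {"name": "CODMn", "weight": 3, "curve": down(0.0, 15.5)},
        {"name": "Chla", "weight": 2, "curve": down(0.0, 60.0)},
    ]


@dataclass
class PipelineConfig:
    """Everything tunable in the pipeline, loadable from YAML."""

    radii: list[float] = field(default_factory=lambda: [100.0, 500.0, 1000.0, 2000.0, 3000.0, 4000.0])
    class_names: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_CLASS_NAMES))
    hails_ci: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HAILS_CI))
    wqi_params: list[dict] = field(default_factory=_default_wqi_params)
    wqi_class_breaks: list[float] = field(default_factory=lambda: [25.0, 50.0, 70.0, 90.0])
    wqi_class_labels: list[str] = field(
        default_factory=lambda: ["Bad", "Poor", "Medium", "Good", "Excellent"]
    )
    opgd_methods: list[str] = field(
        default_factory=lambda: ["equal", "quantile", "natural", "geometric", "sd"]
    )
    opgd_class_range: tuple[int, int] = (3, 7)
    null_model_draws: int = 1000
    gdm_n_splines: int = 3
    gdm_knot_quantiles: list[float] | None = None

    def __post_init__(self) -> None:
        radii = list(self.radii)
        if any(r <= 0 for r in radii) or any(
            b <= a for a, b in zip(radii, radii[1:])
        ):
            raise ValidationError("buffer radii must be positive and strictly increasing")
        if len(self.wqi_class_labels) != len(self.wqi_class_breaks) + 1:
            raise ValidationError("need one more WQI class label than breaks")
        for cls in self.class_names.values():
            if cls not in self.hails_ci:
                raise ValidationError(f"HAILS coefficient missing for class {cls!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "class_names" in raw:
            raw["class_names"] = {int(k): v for k, v in raw["class_names"].items()}
        if "opgd_class_range" in raw:
            raw["opgd_class_range"] = tuple(raw["opgd_class_range"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            "radii": list(self.radii),
            "class_names": {int(k): v for k, v in self.class_names.items()},
            "hails_ci": dict(self.hails_ci),
            "wqi_params": self.wqi_params,
            "wqi_class_breaks": list(self.wqi_class_breaks),
            "wqi_class_labels": list(self.wqi_class_labels),
            "opgd_methods": list(self.opgd_methods),
            "opgd_class_range": list(self.opgd_class_range),
            "null_model_draws": self.null_model_draws,
            "gdm_n_splines": self.gdm_n_splines,
            "gdm_knot_quantiles": self.gdm_knot_quantiles,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def _coords(sites) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(sites, pd.DataFrame):
        sites = sites_from_dataframe(sites)
    ids = [s.site_id for s in sites]
    lon = np.array([s.longitude for s in sites], dtype=float)
    lat = np.array([s.latitude for s in sites], dtype=float)
    alt = np.array([s.altitude for s in sites], dtype=float)
    return ids, lon, lat, alt


def geodesic_distance_matrix(sites) -> DissimilarityMatrix:
    """Pairwise great-circle distance in metres (haversine, mean Earth
    radius 6371008.8 m; within 0.5% of ellipsoidal geodesics at study
    scale)."""
    ids, lon, lat, _ = _coords(sites)
    lam = np.radians(lon)
    phi = np.radians(lat)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2.0) ** 2
    h = np.clip(h, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(h))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DissimilarityMatrix(ids, "geographic_distance_m", d)


def altitude_distance_matrix(sites) -> DissimilarityMatrix:
    """Pairwise absolute altitude difference in metres."""
    ids, _, _, alt = _coords(sites)
    if not np.isfinite(alt).all():
        raise ValidationError("non-finite altitudes")
    d = np.abs(alt[:, None] - alt[None, :])
    return DissimilarityMatrix(ids, "altitude_distance_m", d)


def env_dissimilarity(env: EnvMatrix, standardize: bool = True) -> DissimilarityMatrix:
    """Normalised environmental dissimilarity ``Ed = Euc/Euc_max + 0.001``.

    ``Euc`` is the Euclidean distance between two sites' variable
    vectors, by default after z-scoring each variable (population sd) so
    no unit dominates; ``Euc_max`` is the largest pairwise distance in
    the matrix.  Output lies in [0.001, 1.001]; the diagonal carries the
    literal formula value 0.001 and is excluded from pairwise analyses.
    """
    if len(env.site_ids) < 2:
        raise ValidationError("env dissimilarity needs at least 2 sites")
    x = np.asarray(env.values, dtype=float)
    if standardize:
        sd = x.std(axis=0)
        if (sd == 0).any():
            bad = [v for v, s in zip(env.variable_names, sd) if s == 0]
            raise ValidationError(f"zero-spread variables cannot be standardized: {bad}")
        x = (x - x.mean(axis=0)) / sd
    euc = squareform(pdist(x, metric="euclidean"))
    euc_max = euc.max()
    if euc_max == 0:
        raise ValidationError("all pairwise Euclidean distances are zero (Euc_max = 0)")
    ed = euc / euc_max + 0.001
    return DissimilarityMatrix(
        env.site_ids,
        "env_dissimilarity",
        ed,
        meta={"standardized": bool(standardize), "euc_max": float(euc_max)},
    )


# ---------------------------------------------------------------------------
# dataset loading
# ---------------------------------------------------------------------------


def load_dataset(community_path, sites_path, env_path, grid_path, config_path=None):
    """Load and cross-validate a full input bundle.

    Returns ``(CommunityMatrix, list[SiteRecord], EnvMatrix, LandUseGrid,
    PipelineConfig)`` with site ids ordered identically (site-table
    order) in every returned object.
    """
    from .landscape import LandUseGrid  # deferred to avoid a cycle

    sites = sites_from_csv(sites_path)
    order = [s.site_id for s in sites]
    cm = CommunityMatrix.from_csv(community_path)
    env = EnvMatrix.from_csv(env_path).validate()

    missing_in_sites = sorted(set(cm.site_ids) - set(order))
    missing_in_comm = sorted(set(order) - set(cm.site_ids))
    if missing_in_sites or missing_in_comm:
        raise ValidationError(
            "site id mismatch between community and site tables: "
            f"absent from site table {missing_in_sites}, "
            f"absent from community {missing_in_comm}"
        )
    missing_env = sorted(set(order) - set(env.site_ids))
    if missing_env:
        raise ValidationError(f"sites missing from env table: {missing_env}")

    cm = cm.subset_sites(order)
    env_df = env.to_dataframe().loc[order]
    env = EnvMatrix.from_dataframe(env_df)

    grid = LandUseGrid.from_ascii(grid_path)
    config = PipelineConfig.from_yaml(config_path) if config_path else PipelineConfig()
    codes = np.unique(grid.codes[grid.codes != grid.nodata])
    unknown = sorted(set(codes.tolist()) - set(config.class_names))
    if unknown:
        raise ValidationError(f"unknown land-use codes in grid: {unknown}")
    return cm, sites, env, grid, config
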