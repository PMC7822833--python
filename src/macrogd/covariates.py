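"""Predictor construction: life-history PCs, climate axes, temperature stability,
and the core-periphery position class.

Life-history traits (animal fecundity, body size, longevity) are collinear, so
they enter the models as two principal components: ``pc_size_longevity``
(loads positively on size and longevity — a K-strategy axis) and
``pc_fecundity`` (loads positively on fecundity).  Current-climate variables
are likewise reduced to synthetic temperature / precipitation / humidity axes.
Past-climate stability for a reference epoch (Mid-Holocene or Last Glacial
Maximum) is the standardized negated absolute difference between current and
past temperature, so larger values mean a more stable climate history.

The biogeographic position of a population inside its species range is
classified as core / subedge / edge by area bands (the inner region holding
50% of the range area, the 50-75% band, and the outer 25%), with overriding
classes endemic (range < 10,000 km²), and island / isle for populations on
insular landmasses above / below 10,000 km².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry
from shapely.ops import transform as shp_transform

from .errors import GeometryError, ZeroVarianceError

EARTH_RADIUS_KM = 6371.0

#: range (or landmass) area below which a species is endemic / a landmass an isle
ENDEMIC_AREA_KM2 = 10_000.0

POSITION_CLASSES = ("core", "subedge", "edge", "endemic", "island", "isle")

ANIMAL_TRAITS = ("fecundity", "size", "longevity")


# ---------------------------------------------------------------------------
# principal components
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Scores plus the pieces needed to audit a PCA: loadings (columns are
    components), explained-variance ratios, and the standardized input."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    standardized: pd.DataFrame


def _standardize(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ZeroVarianceError(f"constant columns: {', '.join(map(str, constant))}")
    return (df - df.mean()) / sd


def _pca(std: pd.DataFrame) -> PCAResult:
    """PCA via eigendecomposition of the correlation matrix; components sorted by
    eigenvalue, each flipped so its largest-magnitude loading is positive."""
    corr = np.cov(std.to_numpy(float), rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    for j in range(eigvec.shape[1]):
        k = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[k, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    comp_names = [f"pc{j + 1}" for j in range(eigvec.shape[1])]
    loadings = pd.DataFrame(eigvec, index=std.columns, columns=comp_names)
    scores = pd.DataFrame(std.to_numpy(float) @ eigvec, index=std.index, columns=comp_names)
    evr = eigval / eigval.sum()
    return PCAResult(scores, loadings, evr, std)


def lifehistory_pcs(traits: pd.DataFrame, log10: bool = True) -> tuple[pd.DataFrame, PCAResult]:
    """Reduce animal fecundity / size / longevity to two principal components.

    Parameters
    ----------
    traits
        One row per species with columns ``fecundity``, ``size``, ``longevity``
        (positive raw values, log10-transformed here unless ``log10=False``).
        The index identifies species.

    Returns
    -------
    (scores, pca)
        ``scores`` has columns ``pc_size_longevity`` and ``pc_fecundity``,
        sign-fixed so size and longevity load positively on the first and
        fecundity on the second; the scores have zero mean by construction.
    """
    complete = traits.loc[:, list(ANIMAL_TRAITS)].dropna()
    if len(complete) < 3:
        raise ValueError("need at least 3 species with complete fecundity/size/longevity")
    vals = complete.astype(float)
    if log10:
        if (vals <= 0).any().any():
            raise ValueError("traits must be positive for log10 transform")
        vals = np.log10(vals)
    pca = _pca(_standardize(vals))
    load = pca.loadings.copy()
    scores = pca.scores.copy()
    # orient PC1 with size+longevity, PC2 with fecundity
    if load.loc[["size", "longevity"], "pc1"].mean() < 0:
        load["pc1"] *= -1
        scores["pc1"] *= -1
    if load.loc["fecundity", "pc2"] < 0:
        load["pc2"] *= -1
        scores["pc2"] *= -1
    out = scores.rename(columns={"pc1": "pc_size_longevity", "pc2": "pc_fecundity"})
    pca.loadings = load.rename(columns={"pc1": "pc_size_longevity", "pc2": "pc_fecundity"})
    pca.scores = out
    return out[["pc_size_longevity", "pc_fecundity"]], pca


#: substrings used to map climate columns to an axis family
_FAMILY_PATTERNS: Mapping[str, tuple[str, ...]] = {
    "temperature": ("temp", "tmax", "tmin", "bio1", "bio5", "bio6"),
    "precipitation": ("prec", "rain", "ppt", "bio12"),
    "humidity": ("humid", "vapo", "arid", "moist"),
}


def _infer_family(column: str) -> str | None:
    low = column.lower()
    for family, pats in _FAMILY_PATTERNS.items():
        if any(p in low for p in pats):
            return family
    return None


def climate_pcs(
    climate: pd.DataFrame,
    families: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, PCAResult]:
    """Reduce site-level current-climate variables to three synthetic axes.

    PCA on the standardized variables; the three leading components are
    labeled ``temperature_pc`` / ``precipitation_pc`` / ``humidity_pc`` by the
    family of their dominant loadings.  ``families`` maps column name ->
    family; when omitted, families are inferred from column-name substrings
    ("temp", "prec", "humid", ...).

    Raises ``ValueError`` for rank-deficient input (listing collinear columns).
    """
    if climate.shape[1] < 4 or climate.shape[0] < 4:
        raise ValueError("need at least 4 climate variables measured at >= 4 sites")
    std = _standardize(climate.astype(float))
    rank = np.linalg.matrix_rank(std.to_numpy())
    if rank < std.shape[1]:
        corr = std.corr().abs()
        np.fill_diagonal(corr.to_numpy(), 0.0)
        pairs = corr.stack()
        collinear = sorted({c for (a, c) in pairs[pairs > 1 - 1e-10].index} | set())
        raise ValueError(f"rank-deficient climate table; collinear columns: {collinear}")
    pca = _pca(std)
    fam_of = dict(families) if families is not None else {
        c: _infer_family(c) for c in climate.columns
    }
    # greedy assignment: strongest |loading| mass wins each family
    weights = {}
    for comp in pca.loadings.columns[:3]:
        for family in _FAMILY_PATTERNS:
            cols = [c for c, f in fam_of.items() if f == family]
            weights[(comp, family)] = (
                pca.loadings.loc[cols, comp].abs().max() if cols else 0.0
            )
    labels: dict[str, str] = {}
    taken: set[str] = set()
    for (comp, family), _w in sorted(weights.items(), key=lambda kv: -kv[1]):
        if comp in labels or family in taken:
            continue
        labels[comp] = f"{family}_pc"
        taken.add(family)
    scores = pca.scores[pca.loadings.columns[:3]].rename(columns=labels)
    return scores, pca


def temperature_stability(
    temp_current: Sequence[float],
    temp_past: Sequence[float],
) -> np.ndarray:
    """Standardized temperature-stability score for one past epoch.

    The raw score is ``-|temp_current - temp_past|`` (a site whose temperature
    did not change is maximally stable), then z-standardized with the sample
    SD across the dataset.  Invariant to a common additive shift of both
    epochs.
    """
    cur = np.asarray(temp_current, dtype=float)
    past = np.asarray(temp_past, dtype=float)
    if cur.shape != past.shape:
        raise ValueError("temperature vectors must have identical length")
    if cur.size < 2:
        raise ValueError("need at least 2 sites")
    raw = -np.abs(cur - past)
    sd = raw.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("all current-past temperature differences identical")
    return (raw - raw.mean()) / sd


# ---------------------------------------------------------------------------
# range geometry and position classes
# ---------------------------------------------------------------------------

@dataclass
class RangeGeometry:
    """A species range in WGS84 with optional insular context.

    ``insular_context`` is ``"mainland"`` or the area (km²) of the landmass the
    population sits on; ``area_km2`` overrides the polygon-derived area when
    the published range size differs from the mapped polygon.
    """

    geometry: BaseGeometry
    area_km2: float | None = None
    insular_context: Literal["mainland"] | float = "mainland"
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.geometry.is_empty or not self.geometry.is_valid:
            raise GeometryError("invalid or empty range geometry")

    @property
    def total_area_km2(self) -> float:
        if self.area_km2 is not None:
            return float(self.area_km2)
        if "area" not in self._cache:
            self._cache["area"] = _project_local(self.geometry).area
        return self._cache["area"]


def _laea(lon0: float, lat0: float):
    """Forward Lambert azimuthal equal-area projection (sphere, km) centred on
    (lon0, lat0) — equal-area by construction, so polygon areas in the
    projected plane are areas on the sphere."""
    lam0, phi0 = math.radians(lon0), math.radians(lat0)

    def fwd(lon, lat):
        lam = np.radians(np.asarray(lon, float))
        phi = np.radians(np.asarray(lat, float))
        c = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
        c = np.maximum(c, 1e-12)
        k = np.sqrt(2.0 / c)
        x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam - lam0)
        y = EARTH_RADIUS_KM * k * (
            np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0)
        )
        return x, y

    return fwd


def _project_local(geom: BaseGeometry, origin: tuple[float, float] | None = None) -> BaseGeometry:
    """Project a WGS84 geometry to a local equal-area plane (km) at its centroid."""
    if origin is None:
        c = geom.centroid
        origin = (c.x, c.y)
    return shp_transform(_laea(*origin), geom)


def _erode_to_area(geom: BaseGeometry, target_area: float, rel_tol: float = 0.005) -> BaseGeometry:
    """Inward-buffer the (multi)polygon until its area is within ``rel_tol`` of
    ``target_area``; binary search on the buffer distance."""
    lo, hi = 0.0, math.sqrt(geom.area / math.pi) * 1.5
    eroded = geom
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        eroded = geom.buffer(-mid)
        if eroded.is_empty:
            hi = mid
            continue
        if abs(eroded.area - target_area) <= rel_tol * target_area:
            return eroded
        if eroded.area > target_area:
            lo = mid
        else:
            hi = mid
    return eroded


def classify_position(
    lon: float,
    lat: float,
    rng: RangeGeometry,
    boundary_tolerance_km: float = 1.0,
) -> str:
    """Classify one population's biogeographic position inside its species range.

    Precedence: (1) range area < 10,000 km² -> ``endemic``; (2) population on
    an insular landmass -> ``isle`` (< 10,000 km²) or ``island``; (3) mainland
    area bands -> ``core`` (inner region holding 50% of range area),
    ``subedge`` (50-75% band), ``edge`` (outer 25%).

    Raises ``GeometryError`` if the point lies outside the range by more than
    ``boundary_tolerance_km``.
    """
    if not (-180 <= lon <= 180 and -90 <= lat <= 90):
        raise GeometryError("coordinates outside WGS84 bounds")
    if rng.total_area_km2 < ENDEMIC_AREA_KM2:
        return "endemic"
    if rng.insular_context != "mainland":
        landmass = float(rng.insular_context)
        return "isle" if landmass < ENDEMIC_AREA_KM2 else "island"

    c = rng.geometry.centroid
    origin = (c.x, c.y)
    proj = _project_local(rng.geometry, origin)
    x, y = _laea(*origin)(lon, lat)
    pt = Point(float(x), float(y))
    if not proj.covers(pt):
        if proj.distance(pt) > boundary_tolerance_km:
            raise GeometryError("point lies outside the range geometry beyond tolerance")
        return "edge"

    key = ("bands",)
    if key not in rng._cache:
        rng._cache[key] = (
            _erode_to_area(proj, 0.50 * proj.area),
            _erode_to_area(proj, 0.75 * proj.area),
        )
    inner50, inner75 = rng._cache[key]
    if inner50.covers(pt):
        return "core"
    if inner75.covers(pt):
        return "subedge"
    return "edge"


def classify_positions(
    populations: pd.DataFrame,
    ranges: Mapping[str, RangeGeometry],
    lon_col: str = "longitude",
    lat_col: str = "latitude",
    species_col: str = "species",
) -> pd.Series:
    """Vectorized convenience wrapper; falls back to a precomputed ``position``
    column (pass-through mode) for species without a supplied range."""
    out = pd.Series(pd.NA, index=populations.index, dtype="string")
    for i, row in populations.iterrows():
        sp = row[species_col]
        if sp in ranges:
            out.loc[i] = classify_position(float(row[lon_col]), float(row[lat_col]), ranges[sp])
        elif "position" in populations.columns and pd.notna(row.get("position")):
            out.loc[i] = row["position"]
        else:
            raise GeometryError(f"no range geometry or precomputed position for species '{sp}'")
    return out
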