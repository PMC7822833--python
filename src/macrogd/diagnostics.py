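"""Robustness diagnostics: Moran's I autocorrelograms and delete-group jackknife.

The correlogram tests whether model residuals (or the raw response) carry
spatial structure: for each great-circle distance class, Moran's I is computed
with binary pair-membership weights and a one-sided permutation p-value
(values shuffled over locations).  Under spatial independence E[I] = -1/(n-1).

The jackknife refits the model leaving out, in turn, every species or every
occupied 3°x3° geographic cell, and reports the delete-group SE and normal
95% confidence interval per coefficient — a check that no single species or
region drives the estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, ZeroVarianceError
from .mixedmodel import ModelSpec, fit_weighted_lmm

EARTH_RADIUS_KM = 6371.0


def great_circle_km(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Haversine great-circle distance in km on a sphere of radius 6371 km.

    Vectorized; symmetric; 0 for identical points.  Raises ``DomainError``
    for coordinates outside WGS84 bounds.
    """
    arrs = [np.asarray(a, float) for a in (lon1, lat1, lon2, lat2)]
    if (
        np.any(np.abs(arrs[0]) > 180)
        or np.any(np.abs(arrs[2]) > 180)
        or np.any(np.abs(arrs[1]) > 90)
        or np.any(np.abs(arrs[3]) > 90)
        or any(np.any(~np.isfinite(a)) for a in arrs)
    ):
        raise DomainError("coordinates outside WGS84 bounds")
    lo1, la1, lo2, la2 = (np.radians(a) for a in arrs)
    dlat, dlon = la2 - la1, lo2 - lo1
    h = np.sin(dlat / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    return float(d) if d.ndim == 0 else d


def pairwise_distances_km(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Full symmetric n x n great-circle distance matrix."""
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    return great_circle_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])


def morans_i(values: np.ndarray, weights: np.ndarray) -> float:
    """Moran's I with an arbitrary non-negative weight matrix (zero diagonal):

        I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2,   z = x - mean(x).

    Raises ``ZeroVarianceError`` for constant values and ``ValueError`` for an
    all-zero weight matrix or n < 3.
    """
    x = np.asarray(values, float)
    W = np.asarray(weights, float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 values")
    if W.shape != (n, n):
        raise ValueError("weight matrix shape mismatch")
    if np.any(W < 0) or np.any(np.diag(W) != 0):
        raise ValueError("weights must be non-negative with a zero diagonal")
    s0 = W.sum()
    if s0 <= 0:
        raise ValueError("all-zero weight matrix")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ZeroVarianceError("constant values; Moran's I undefined")
    return float(n / s0 * (z @ W @ z) / denom)


@dataclass
class Correlogram:
    """Moran's I per geographic distance class.

    ``table`` columns: bin_lo_km, bin_hi_km, n_pairs, morans_i, p_value,
    empty.  Classes with fewer than 2 pairs are flagged empty and carry NaN
    statistics.  p-values are one-sided (upper tail: positive autocorrelation)
    permutation probabilities, bounded below by 1/(n_perm+1).
    """

    table: pd.DataFrame
    n_perm: int
    seed: int

    @property
    def expected_i(self) -> float:
        return -1.0 / (self._n - 1)

    _n: int = 0


def correlogram(
    values: np.ndarray,
    lon: np.ndarray,
    lat: np.ndarray,
    bin_width_km: float = 100.0,
    max_km: float = 5000.0,
    n_perm: int = 999,
    seed: int = 0,
) -> Correlogram:
    """Moran's I autocorrelogram over great-circle distance classes.

    Distance classes are half-open bins [k*w, (k+1)*w) up to ``max_km``; each
    class uses binary membership weights (1 when a pair's distance falls in
    the class).  The same ``n_perm`` random permutations of ``values`` (drawn
    once from ``seed``) serve every class, giving one-sided upper-tail
    p-values p = (1 + #{I_perm >= I_obs}) / (n_perm + 1).
    """
    x = np.asarray(values, float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 points for a correlogram")
    D = pairwise_distances_km(np.asarray(lon, float), np.asarray(lat, float))
    edges = np.arange(0.0, max_km + bin_width_km, bin_width_km)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ZeroVarianceError("constant values; correlogram undefined")
    iu = np.triu_indices(n, 1)
    d_flat = D[iu]
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (d_flat >= lo) & (d_flat < hi)
        npairs = int(sel.sum())
        if npairs < 2:
            rows.append(
                dict(bin_lo_km=lo, bin_hi_km=hi, n_pairs=npairs, morans_i=np.nan,
                     p_value=np.nan, empty=True)
            )
            continue
        ii, jj = iu[0][sel], iu[1][sel]
        s0 = 2.0 * npairs  # symmetric weights counted both ways
        obs = n / s0 * 2.0 * float(z[ii] @ z[jj]) / denom
        zp = z[perms]  # (n_perm, n): permuted deviations (mean unchanged)
        cross = np.einsum("pi,pi->p", zp[:, ii], zp[:, jj])
        i_perm = n / s0 * 2.0 * cross / denom
        p = (1.0 + float(np.sum(i_perm >= obs))) / (n_perm + 1.0)
        rows.append(
            dict(bin_lo_km=lo, bin_hi_km=hi, n_pairs=npairs, morans_i=obs,
                 p_value=p, empty=False)
        )
    cg = Correlogram(pd.DataFrame(rows), n_perm, seed)
    cg._n = n
    return cg


def grid_cell(lon, lat, cell_deg: float = 3.0) -> np.ndarray:
    """Assign points to geographic grid cells anchored at (-180, -90), half-open
    [a, a+cell) in both axes; points exactly on the antimeridian join the
    western (last) column.  Returns string labels "ix_iy"."""
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    nx = int(round(360.0 / cell_deg))
    ny = int(round(180.0 / cell_deg))
    ix = np.minimum(np.floor((lon + 180.0) / cell_deg).astype(int), nx - 1)
    iy = np.minimum(np.floor((lat + 90.0) / cell_deg).astype(int), ny - 1)
    out = np.char.add(np.char.add(ix.astype(str), "_"), iy.astype(str))
    return out


@dataclass
class JackknifeResult:
    """Delete-group jackknife over species or 3° grid cells.

    ``estimates`` holds one row of leave-out coefficients per unit (NaN rows
    for failed refits are dropped); ``summary`` has the full-data estimate,
    jackknife SE, and the normal 95% CI per coefficient.
    """

    unit: str
    estimates: pd.DataFrame
    summary: pd.DataFrame
    failed_units: list[str]

    @property
    def n_refits(self) -> int:
        return len(self.estimates)


def jackknife(
    data: pd.DataFrame,
    spec: ModelSpec,
    unit: Literal["species", "grid3deg"] = "species",
    cell_deg: float = 3.0,
    ci_level: float = 0.95,
) -> JackknifeResult:
    """Leave out one unit at a time, refit, and summarize coefficient stability.

    The delete-group SE is sqrt((m-1)/m * sum_i (theta_(-i) - mean)^2) over the
    m successful leave-out refits; the CI is the full-data estimate ±
    z * SE_jack.  Unequal group sizes are accepted as-is.  Refits that fail
    (typically a lost factor level) are logged and skipped with a warning.
    """
    if unit == "species":
        labels = data["species"].astype(str).to_numpy()
    elif unit == "grid3deg":
        labels = grid_cell(data["longitude"].to_numpy(float), data["latitude"].to_numpy(float), cell_deg)
    else:
        raise ValueError("unit must be 'species' or 'grid3deg'")
    units = sorted(pd.unique(labels))
    if len(units) < 3:
        raise ValueError("need at least 3 distinct units for the jackknife")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        full_fit = fit_weighted_lmm(spec, data)
        levels = full_fit.design.levels

        rows, failed = {}, []
        for u in units:
            sub = data.loc[labels != u]
            try:
                fit = fit_weighted_lmm(spec, sub, levels=levels)
                rows[u] = fit.params
            except Exception as e:
                failed.append(u)
                warnings.warn(f"jackknife refit failed for unit '{u}': {e}", RuntimeWarning)
    estimates = pd.DataFrame.from_dict(rows, orient="index")
    m = len(estimates)
    if m < 2:
        raise ValueError("fewer than 2 successful jackknife refits")
    mean = estimates.mean(axis=0)
    se = np.sqrt((m - 1) / m * ((estimates - mean) ** 2).sum(axis=0))
    zcrit = stats.norm.ppf(0.5 + ci_level / 2)
    summary = pd.DataFrame(
        {
            "estimate": full_fit.params,
            "se_jackknife": se,
            "lower": full_fit.params - zcrit * se,
            "upper": full_fit.params + zcrit * se,
        }
    )
    return JackknifeResult(unit, estimates, summary, failed)
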