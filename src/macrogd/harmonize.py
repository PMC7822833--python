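"""Record filtering and harmonization of expected heterozygosity across marker types.

Published per-population expected-heterozygosity (H_E) estimates are not directly
comparable across marker technologies: dominant markers (AFLP) bound H_E at 0.5,
codominant markers (microsatellites, SNPs) at 1.0, and allozymes occupy a lower
range again.  The response used throughout the pipeline (``gdp``) therefore
applies a two-stage transform: a z-score within each marker type (sample
variance) followed by a single min-max rescale over the pooled standardized
values, mapping the whole dataset onto [0, 1] on one common scale.

Records also pass study-level inclusion rules before harmonization: a minimum
of 10 sampled individuals, no marine habitat, no introduced/invasive/cultivar
provenance, and non-missing coordinates.

Precision weights for the downstream meta-regression are ``1/sqrt(log(loci *
sample_size))`` — estimates built from more loci and more individuals carry
more weight.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DomainError, NoRecordsRetainedError, ZeroVarianceError

#: Columns a raw population table must provide.
REQUIRED_COLUMNS = (
    "population_id",
    "species",
    "phylum",
    "kingdom",
    "latitude",
    "longitude",
    "marker_type",
    "n_loci",
    "sample_size",
    "he_raw",
)

MARKER_TYPES = ("codominant", "dominant", "enzyme")

#: minimum individuals per population for inclusion
MIN_SAMPLE_SIZE = 10

# exclusion reason codes, checked in this order; the first match is logged
_REASONS = ("missing_coordinates", "min_sample_size", "marine_habitat", "provenance_flag")


def validate_records(records: pd.DataFrame, required: Iterable[str] = REQUIRED_COLUMNS) -> None:
    """Raise ``ValueError`` listing any missing required columns or invariant violations."""
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise ValueError(f"missing required columns: {', '.join(missing)}")
    lat = pd.to_numeric(records["latitude"], errors="coerce")
    lon = pd.to_numeric(records["longitude"], errors="coerce")
    if (lat.dropna().abs() > 90).any():
        raise ValueError("latitude outside [-90, 90]")
    if (lon.dropna().abs() > 180).any():
        raise ValueError("longitude outside [-180, 180]")
    he = pd.to_numeric(records["he_raw"], errors="coerce").dropna()
    if ((he < 0) | (he > 1)).any():
        raise ValueError("he_raw outside [0, 1]")
    for col in ("n_loci", "sample_size"):
        if (pd.to_numeric(records[col], errors="coerce").dropna() < 1).any():
            raise ValueError(f"{col} must be >= 1")


def apply_inclusion_filters(
    records: pd.DataFrame, min_sample_size: int = MIN_SAMPLE_SIZE
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the study inclusion rules.

    Parameters
    ----------
    records
        Population table conforming to :data:`REQUIRED_COLUMNS`; optional columns
        ``habitat`` ({terrestrial, freshwater, marine}) and ``provenance_flags``
        (comma/semicolon separated subset of {introduced, invasive, cultivar};
        empty or NaN means none).
    min_sample_size
        Inclusive lower bound on individuals per population (default 10).

    Returns
    -------
    (retained, exclusion_log)
        ``retained`` preserves the input row order; ``exclusion_log`` has columns
        ``population_id`` and ``reason`` with exactly one reason code per
        dropped row (the first rule that fired).

    Raises
    ------
    NoRecordsRetainedError
        If every record is excluded.
    """
    validate_records(records)
    lat = pd.to_numeric(records["latitude"], errors="coerce")
    lon = pd.to_numeric(records["longitude"], errors="coerce")
    n = pd.to_numeric(records["sample_size"], errors="coerce")

    missing_coords = lat.isna() | lon.isna()
    too_small = n.isna() | (n < min_sample_size)
    if "habitat" in records.columns:
        marine = records["habitat"].astype("string").str.lower().eq("marine").fillna(False)
    else:
        marine = pd.Series(False, index=records.index)
    if "provenance_flags" in records.columns:
        flags = records["provenance_flags"].fillna("").astype(str).str.strip()
        flagged = flags.ne("") & flags.str.lower().ne("none")
    else:
        flagged = pd.Series(False, index=records.index)

    reason = pd.Series(pd.NA, index=records.index, dtype="string")
    for code, mask in zip(_REASONS, (missing_coords, too_small, marine, flagged)):
        reason = reason.mask(reason.isna() & mask, code)

    dropped = reason.notna()
    exclusion_log = pd.DataFrame(
        {"population_id": records.loc[dropped, "population_id"].to_numpy(), "reason": reason[dropped].to_numpy()}
    )
    retained = records.loc[~dropped].copy()
    if retained.empty:
        raise NoRecordsRetainedError("no records retained after inclusion filtering")
    return retained, exclusion_log


def precision_weight(n_loci, sample_size, base: float = math.e):
    """Meta-regression precision weight ``1 / sqrt(log(n_loci * sample_size))``.

    The logarithm is natural by default; ``base`` switches it.  Strictly
    decreasing in the product, so larger studies are down-weighted less.
    Accepts scalars or array-likes (vectorized).

    Raises
    ------
    DomainError
        If any product ``n_loci * sample_size`` is <= 1 (log would be <= 0).
    """
    product = np.asarray(n_loci, dtype=float) * np.asarray(sample_size, dtype=float)
    if np.any(product <= 1):
        raise DomainError("n_loci * sample_size must exceed 1 for a positive log")
    w = 1.0 / np.sqrt(np.log(product) / math.log(base))
    if w.ndim == 0:
        return float(w)
    return w


def standardize_by_marker(he: pd.Series, marker_type: pd.Series) -> pd.Series:
    """Z-score heterozygosity within each marker type using the sample (n-1) variance."""
    out = pd.Series(np.nan, index=he.index, dtype=float)
    for marker, idx in he.groupby(marker_type).groups.items():
        vals = he.loc[idx].astype(float)
        if len(vals) < 2 or float(vals.std(ddof=1)) == 0.0:
            raise ZeroVarianceError(f"constant heterozygosity within marker type '{marker}'")
        out.loc[idx] = (vals - vals.mean()) / vals.std(ddof=1)
    return out


def minmax_normalize(values: pd.Series) -> pd.Series:
    """Rescale to [0, 1] via (x - min) / (max - min)."""
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        raise ZeroVarianceError("cannot min-max normalize constant values")
    return (values - lo) / (hi - lo)


def harmonize_gdp(
    records: pd.DataFrame,
    pooled: bool = True,
    log_base: float = math.e,
) -> pd.DataFrame:
    """Transform retained records into the analysis-ready harmonized dataset.

    Adds columns ``gdp`` (z-score within marker type, then min-max rescaled to
    [0, 1]), ``weight`` (precision weight), and ``abs_latitude``.  With
    ``pooled=True`` (default) the min-max step runs over the pooled
    standardized values of the whole table so both kingdoms share a scale;
    ``pooled=False`` rescales within each kingdom separately.

    Rank order within each marker type is preserved by construction (both
    stages are increasing affine maps within a marker type).
    """
    out = records.copy()
    z = standardize_by_marker(out["he_raw"].astype(float), out["marker_type"])
    if pooled:
        out["gdp"] = minmax_normalize(z)
    else:
        out["gdp"] = (
            z.groupby(out["kingdom"], group_keys=False).apply(minmax_normalize).reindex(out.index)
        )
    out["weight"] = precision_weight(
        out["n_loci"].to_numpy(float), out["sample_size"].to_numpy(float), base=log_base
    )
    out["abs_latitude"] = out["latitude"].astype(float).abs()
    return out


def harmonize(
    records: pd.DataFrame,
    min_sample_size: int = MIN_SAMPLE_SIZE,
    pooled: bool = True,
    log_base: float = math.e,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter then harmonize; returns ``(harmonized, exclusion_log)``."""
    retained, log = apply_inclusion_filters(records, min_sample_size=min_sample_size)
    return harmonize_gdp(retained, pooled=pooled, log_base=log_base), log


def drop_incomplete(
    data: pd.DataFrame, required: Iterable[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Listwise-delete rows missing any of ``required``; log them as ``missing_covariate``.

    Rows with missing elevation or climate stay in the latitude models but are
    excluded from the kingdom models, which need the full covariate set.
    """
    required = [c for c in required if c in data.columns]
    mask = data[required].isna().any(axis=1)
    log = pd.DataFrame(
        {"population_id": data.loc[mask, "population_id"].to_numpy(), "reason": "missing_covariate"}
    )
    return data.loc[~mask].copy(), log
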