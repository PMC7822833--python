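"""End-to-end orchestration: harmonize -> latitude models -> kingdom dredge ->
spatial diagnostics -> jackknife, with a config file, a run manifest, and CSV/
JSON report bundles.

Every stage writes its outputs under the configured directory; a manifest
records the config hash, seed, and package versions so a run can be reproduced
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, MacroGDError
from .harmonize import apply_inclusion_filters, drop_incomplete, harmonize_gdp
from .mixedmodel import (
    build_latitude_spec,
    extract_group_slopes,
    fit_with_marker_fallback,
)
from .model_selection import (
    DEFAULT_DELTA,
    DEFAULT_RI_THRESHOLD,
    build_full_kingdom_spec,
    dredge,
    select_final_terms,
)
from .diagnostics import correlogram, jackknife
from .synthetic import SyntheticConfig, make_dataset

log = logging.getLogger("macrogd")

#: default trimmed main-effect set for the dredge (keeps the submodel space
#: tractable at synthetic-study scale; pass mains="all" for the full structure)
DEFAULT_DREDGE_MAINS = (
    "position",
    "temperature_pc",
    "precipitation_pc",
    "mh_stability",
    "lgm_stability",
    "phylum",
)


@dataclass
class PipelineConfig:
    """Everything a run needs; loadable from YAML via :meth:`from_yaml`."""

    input_csv: str | None = None  # None -> simulate
    out_dir: str = "macrogd_out"
    seed: int = 0
    column_map: Mapping[str, str] = field(default_factory=dict)
    min_sample_size: int = 10
    pooled_normalization: bool = True
    log_base: float = float(np.e)
    kingdoms: tuple[str, ...] = ("animal", "plant")
    delta: float = DEFAULT_DELTA
    ri_threshold: float = DEFAULT_RI_THRESHOLD
    dredge_mains: tuple[str, ...] | str = DEFAULT_DREDGE_MAINS
    phylum_interactions: tuple[str, ...] | str = ("mh_stability", "lgm_stability")
    correlogram_bin_km: float = 500.0
    correlogram_max_km: float = 5000.0
    n_perm: int = 199
    jackknife_units: tuple[str, ...] = ("species", "grid3deg")
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def __post_init__(self):
        if self.delta <= 0:
            raise ConfigError("delta must be > 0")
        if not (0 < self.ri_threshold < 100):
            raise ConfigError("ri_threshold must be in (0, 100)")
        if self.input_csv is not None and not Path(self.input_csv).exists():
            raise ConfigError(f"input file not found: {self.input_csv}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if syn:
            cfg.synthetic = SyntheticConfig(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in syn.items()
            })
        return cfg

    def digest(self) -> str:
        def _default(o):
            if isinstance(o, Mapping):
                return dict(o)
            return str(o)

        blob = json.dumps(asdict(self), sort_keys=True, default=_default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_input(config: PipelineConfig) -> pd.DataFrame:
    if config.input_csv is None:
        data, truth = make_dataset(config.synthetic, seed=config.seed)
        data.attrs["ground_truth"] = truth
        return data
    df = pd.read_csv(config.input_csv)
    if config.column_map:
        df = df.rename(columns=dict(config.column_map))
    return df


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            log.info("stage %s: start", name)
            try:
                out = fn(*a, **kw)
            except MacroGDError:
                raise
            except Exception as e:
                raise MacroGDError(f"stage '{name}' failed: {e}") from e
            log.info("stage %s: done", name)
            return out

        return wrapped

    return deco


@_stage("harmonize")
def stage_harmonize(config: PipelineConfig, data: pd.DataFrame, out: Path):
    retained, excl = apply_inclusion_filters(data, min_sample_size=config.min_sample_size)
    if "gdp" not in retained.columns:
        retained = harmonize_gdp(
            retained, pooled=config.pooled_normalization, log_base=config.log_base
        )
    elif "weight" not in retained.columns:
        from .harmonize import precision_weight

        retained["weight"] = precision_weight(
            retained["n_loci"].to_numpy(float), retained["sample_size"].to_numpy(float)
        )
    if "abs_latitude" not in retained.columns:
        retained["abs_latitude"] = retained["latitude"].astype(float).abs()
    retained.to_csv(out / "harmonized.csv", index=False)
    excl.to_csv(out / "exclusions.csv", index=False)
    return retained


@_stage("fit_latitude")
def stage_latitude(config: PipelineConfig, data: pd.DataFrame, out: Path):
    results = {}
    for level, group in (("kingdom", "kingdom"), ("phylum", "phylum")):
        spec = build_latitude_spec(level)
        fit = fit_with_marker_fallback(spec, data)
        slopes = extract_group_slopes(fit, group)
        results[level] = (fit, slopes)
        (out / f"latitude_{level}_fit.json").write_text(json.dumps(fit.to_dict(), indent=2))
        slopes.rename_axis(group).to_csv(out / f"latitude_{level}_slopes.csv")
    return results


@_stage("dredge")
def stage_dredge(config: PipelineConfig, data: pd.DataFrame, out: Path, kingdom: str):
    sub = data.loc[data["kingdom"] == kingdom].copy()
    full = build_full_kingdom_spec(kingdom, phylum_interactions=config.phylum_interactions)
    if config.dredge_mains != "all":
        keep = set(config.dredge_mains)
        terms = [t for t in full.fixed if set(t) <= keep]
        full = full.with_terms(terms)
    needed = sorted({v for t in full.fixed for v in t})
    sub, dropped = drop_incomplete(sub, needed)
    if len(dropped):
        dropped.to_csv(out / f"dredge_{kingdom}_excluded.csv", index=False)
    # a single phylum (or other single-level factor) in the subset would alias
    # its term; drop such terms rather than fail
    usable = []
    for t in full.fixed:
        if all(sub[v].nunique() > 1 or pd.api.types.is_numeric_dtype(sub[v]) for v in t):
            usable.append(t)
    full = full.with_terms(usable)
    cs, ri = dredge(full, sub, delta=config.delta)
    cs.table.to_csv(out / f"candidate_set_{kingdom}.csv", index=False)
    ri.to_frame().to_csv(out / f"ri_table_{kingdom}.csv", index=False)
    final_spec = select_final_terms(ri, full, threshold=config.ri_threshold)
    final_fit = fit_with_marker_fallback(replace(final_spec, method="REML"), sub)
    (out / f"final_model_{kingdom}.json").write_text(json.dumps(final_fit.to_dict(), indent=2))
    return sub, cs, ri, final_fit


@_stage("diagnostics")
def stage_diagnostics(config: PipelineConfig, sub: pd.DataFrame, fit, out: Path, kingdom: str):
    for label, vals in (("residuals", fit.resid), ("raw", sub["gdp"].to_numpy(float))):
        cg = correlogram(
            vals,
            sub["longitude"].to_numpy(float),
            sub["latitude"].to_numpy(float),
            bin_width_km=config.correlogram_bin_km,
            max_km=config.correlogram_max_km,
            n_perm=config.n_perm,
            seed=config.seed,
        )
        cg.table.to_csv(out / f"correlogram_{label}_{kingdom}.csv", index=False)


@_stage("jackknife")
def stage_jackknife(config: PipelineConfig, sub: pd.DataFrame, spec, out: Path, kingdom: str):
    results = {}
    for unit in config.jackknife_units:
        jk = jackknife(sub, spec, unit=unit)
        jk.summary.rename_axis("coefficient").to_csv(out / f"jackknife_{unit}_{kingdom}.csv")
        results[unit] = jk
    return results


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage; returns the in-memory report bundle and writes files
    under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = _load_input(config)
    missing = [c for c in ("species", "kingdom", "latitude", "longitude", "marker_type",
                           "n_loci", "sample_size") if c not in data.columns]
    if missing:
        raise ConfigError(f"missing required columns: {', '.join(missing)}")

    bundle: dict[str, Any] = {}
    harmonized = stage_harmonize(config, data, out)
    bundle["harmonized"] = harmonized
    bundle["latitude"] = stage_latitude(config, harmonized, out)
    bundle["kingdom"] = {}
    for kingdom in config.kingdoms:
        sub, cs, ri, final_fit = stage_dredge(config, harmonized, out, kingdom)
        stage_diagnostics(config, sub, final_fit, out, kingdom)
        jk = stage_jackknife(config, sub, final_fit.spec, out, kingdom)
        bundle["kingdom"][kingdom] = {
            "data": sub, "candidate_set": cs, "ri": ri, "final_fit": final_fit, "jackknife": jk,
        }

    manifest = {
        "package": "macrogd",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "config": json.loads(json.dumps(asdict(config), default=str)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    return bundle
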