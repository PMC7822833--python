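"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates a global heterozygosity compilation: species nested in
phyla nested in the plant and animal kingdoms, a handful of populations per
species scattered around a species-specific range centre, marker metadata
(type, locus count, sample size), biogeographic position classes, climate
covariates, and life-history traits.  The response is simulated directly on
the harmonized [0, 1]-type scale from a Gaussian mixed model with known fixed
effects, species and marker random intercepts, and residual variance inversely
proportional to the precision weight — so every downstream stage can be tested
against known ground truth.  A per-marker back-transform to raw heterozygosity
is provided for I/O realism only.

One root seed drives independent sub-streams (species, populations, climate,
response) so components can be regenerated in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import Term, build_design
from .errors import ConfigError
from .harmonize import precision_weight

#: phylum -> kingdom for the nine taxonomic groups in the compilation
PHYLUM_KINGDOM = {
    "eudicot": "plant",
    "magnolid": "plant",
    "monocot": "plant",
    "pine": "plant",
    "amphibian": "animal",
    "reptile": "animal",
    "mollusc": "animal",
    "mammal": "animal",
    "bird": "animal",
}

#: species counts of the source compilation, used as sampling proportions
_STUDY_SPECIES = {
    "eudicot": 242, "magnolid": 10, "monocot": 82, "pine": 50,
    "amphibian": 51, "reptile": 36, "mollusc": 44, "mammal": 139, "bird": 73,
}

#: per-population plant trait class frequencies of the compilation
PLANT_TRAIT_PROBS = {
    "pollen": {"biotic": 2341 / 4254, "abiotic": 1913 / 4254},
    "seed": {"animal": 1398 / 4254, "wind": 1779 / 4254, "water": 497 / 4254, "local": 580 / 4254},
    "mating": {
        "self_incompatible": 1731 / 4255,
        "self_compatible": 1408 / 4255,
        "clonal": 753 / 4255,
        "non_clonal": 363 / 4255,
    },
    "lifeform": {"annual": 164 / 4214, "perennial": 1405 / 4214, "shrub": 308 / 4214, "tree": 2337 / 4214},
}

#: raw-heterozygosity centre and spread per marker technology (back-transform)
MARKER_SCALES = {
    "codominant": {"center": 0.60, "scale": 0.15, "lo": 0.0, "hi": 1.0},
    "dominant": {"center": 0.25, "scale": 0.08, "lo": 0.0, "hi": 0.5},
    "enzyme": {"center": 0.15, "scale": 0.06, "lo": 0.0, "hi": 1.0},
}


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults emulate the source compilation.

    ``beta`` maps design-column names (built from ``effect_terms``) to true
    fixed effects; unnamed columns are zero.  Variances are on the harmonized
    response scale.
    """

    n_species: int = 250
    pops_per_species: tuple[int, int] = (2, 50)
    species_proportions: Mapping[str, int] = field(default_factory=lambda: dict(_STUDY_SPECIES))
    marker_probs: Mapping[str, float] = field(
        default_factory=lambda: {"codominant": 0.60, "dominant": 0.25, "enzyme": 0.15}
    )
    position_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "core": 0.35, "subedge": 0.20, "edge": 0.20,
            "endemic": 0.10, "island": 0.10, "isle": 0.05,
        }
    )
    lat_range: tuple[float, float] = (-60.0, 70.0)
    species_spread_deg: float = 4.0
    n_loci_range: tuple[int, int] = (5, 30)
    sample_size_range: tuple[int, int] = (10, 50)
    effect_terms: tuple[Term, ...] = (("abs_latitude",), ("kingdom",))
    beta: Mapping[str, float] = field(
        default_factory=lambda: {"Intercept": 0.55, "abs_latitude": -0.006, "kingdom[plant]": -0.15}
    )
    tau2_species: float = 0.02
    tau2_marker: float = 0.002
    sigma2: float = 0.01
    clip_response: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 1:
            raise ConfigError("n_species must be >= 1")
        if self.pops_per_species[0] < 1 or self.pops_per_species[1] < self.pops_per_species[0]:
            raise ConfigError("invalid pops_per_species bounds")
        for name, probs in (("marker_probs", self.marker_probs), ("position_probs", self.position_probs)):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1")
        if min(self.tau2_species, self.tau2_marker) < 0 or self.sigma2 <= 0:
            raise ConfigError("variances must be non-negative and sigma2 positive")


def recovery_config(seed: int = 0) -> SyntheticConfig:
    """Preset for parameter-recovery experiments: 250 species with 2-10
    populations each (~1500 rows), a true latitude slope of -0.05, and
    tau2_species = 0.5 * sigma2."""
    return SyntheticConfig(
        n_species=250,
        pops_per_species=(2, 10),
        beta={"Intercept": 0.55, "abs_latitude": -0.05, "kingdom[plant]": -0.15},
        sigma2=0.04,
        tau2_species=0.02,
        tau2_marker=0.004,
        seed=seed,
    )


def ri_config(seed: int = 0) -> SyntheticConfig:
    """Preset for relative-importance discrimination: two active continuous
    predictors (effects several SE above zero at this size) and two
    pure-noise predictors."""
    return SyntheticConfig(
        n_species=120,
        pops_per_species=(2, 8),
        effect_terms=(
            ("abs_latitude",), ("temperature_pc",), ("precipitation_pc",), ("elevation_km",),
        ),
        beta={"Intercept": 0.55, "abs_latitude": -0.01, "temperature_pc": 0.08},
        sigma2=0.04,
        tau2_species=0.02,
        tau2_marker=0.002,
        seed=seed,
    )


@dataclass
class GroundTruth:
    """The realized simulation truth: design columns with their coefficients,
    variance components, and the per-row linear predictor."""

    beta: dict[str, float]
    tau2: dict[str, float]
    sigma2: float
    terms: tuple[str, ...]
    linear_predictor: np.ndarray
    seed: int

    def to_json(self) -> str:
        d = asdict(self)
        d["linear_predictor"] = np.asarray(self.linear_predictor).tolist()
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["linear_predictor"] = np.asarray(d["linear_predictor"], float)
        d["terms"] = tuple(d["terms"])
        return cls(**d)


def _choice(rng: np.random.Generator, probs: Mapping[str, float], size: int) -> np.ndarray:
    keys = list(probs)
    return rng.choice(keys, size=size, p=[probs[k] for k in keys])


def generate_metadata(config: SyntheticConfig, seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the species and population tables (no response yet).

    Species are allocated to phyla by the configured proportions; each species
    gets a range centre, a marker technology (a study typically uses one), and
    kingdom-appropriate life-history traits.  Populations scatter around the
    range centre with clustered coordinates, and carry elevation, locus and
    sample counts, a position class, and latitude-linked climate covariates.
    Fully reproducible from the seed.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    sp_rng, pop_rng, clim_rng = (np.random.default_rng(s) for s in root.spawn(3))

    phyla = list(config.species_proportions)
    weights = np.array([config.species_proportions[p] for p in phyla], float)
    weights /= weights.sum()
    sp_phyla = sp_rng.choice(phyla, size=config.n_species, p=weights)

    species = pd.DataFrame(
        {
            "species": [f"sp{i:04d}" for i in range(config.n_species)],
            "phylum": sp_phyla,
            "kingdom": [PHYLUM_KINGDOM[p] for p in sp_phyla],
        }
    )
    species["marker_type"] = _choice(sp_rng, config.marker_probs, config.n_species)
    species["range_area"] = np.exp(sp_rng.normal(12.0, 2.0, config.n_species))  # km², log-normal
    species["center_lat"] = sp_rng.uniform(*config.lat_range, config.n_species)
    species["center_lon"] = sp_rng.uniform(-170.0, 170.0, config.n_species)
    animal = species["kingdom"] == "animal"
    n_anim = int(animal.sum())
    # correlated size/longevity (K axis), independent fecundity (log10 scale)
    sl = sp_rng.multivariate_normal([1.0, 0.8], [[0.25, 0.18], [0.18, 0.25]], n_anim)
    species.loc[animal, "size"] = 10 ** sl[:, 0]
    species.loc[animal, "longevity"] = 10 ** sl[:, 1]
    species.loc[animal, "fecundity"] = 10 ** sp_rng.normal(1.5, 0.6, n_anim)
    for trait, probs in PLANT_TRAIT_PROBS.items():
        probs = {k: v / sum(probs.values()) for k, v in probs.items()}
        species.loc[~animal, trait] = _choice(sp_rng, probs, config.n_species - n_anim)

    lo, hi = config.pops_per_species
    n_pops = pop_rng.integers(lo, hi + 1, size=config.n_species)
    rows = np.repeat(np.arange(config.n_species), n_pops)
    total = int(n_pops.sum())
    pops = pd.DataFrame(
        {
            "population_id": [f"pop{i:06d}" for i in range(total)],
            "species": species["species"].to_numpy()[rows],
            "phylum": species["phylum"].to_numpy()[rows],
            "kingdom": species["kingdom"].to_numpy()[rows],
            "marker_type": species["marker_type"].to_numpy()[rows],
        }
    )
    lat = species["center_lat"].to_numpy()[rows] + pop_rng.normal(0, config.species_spread_deg, total)
    lon = species["center_lon"].to_numpy()[rows] + pop_rng.normal(0, config.species_spread_deg, total)
    pops["latitude"] = np.clip(lat, -90.0, 90.0)
    pops["longitude"] = (lon + 180.0) % 360.0 - 180.0
    pops["abs_latitude"] = pops["latitude"].abs()
    pops["elevation"] = np.abs(pop_rng.normal(0, 600.0, total))  # metres
    pops["elevation_km"] = pops["elevation"] / 1000.0
    pops["n_loci"] = pop_rng.integers(*config.n_loci_range, size=total, endpoint=True)
    pops["sample_size"] = pop_rng.integers(*config.sample_size_range, size=total, endpoint=True)
    pops["position"] = _choice(pop_rng, config.position_probs, total)
    pops["habitat"] = "terrestrial"
    pops["provenance_flags"] = ""

    # climate axes: temperature tracks distance from the equator, the others
    # are independent standardized site effects
    t_raw = -pops["abs_latitude"].to_numpy() / 30.0 + clim_rng.normal(0, 0.5, total)
    pops["temperature_pc"] = (t_raw - t_raw.mean()) / t_raw.std(ddof=1)
    pops["precipitation_pc"] = clim_rng.normal(0, 1, total)
    pops["humidity_pc"] = clim_rng.normal(0, 1, total)
    for col in ("mh_stability", "lgm_stability"):
        raw = -np.abs(clim_rng.normal(0, 1.5, total) + pops["abs_latitude"].to_numpy() / 60.0)
        pops[col] = (raw - raw.mean()) / raw.std(ddof=1)
    pops["range_area"] = np.log10(species["range_area"].to_numpy()[rows])
    return species, pops


def simulate_gdp(
    X: np.ndarray,
    truth: GroundTruth,
    weights: np.ndarray,
    groups: Mapping[str, np.ndarray],
    seed: int,
    clip: bool = False,
) -> np.ndarray:
    """Draw the response y = X beta + sum_f Z_f u_f + eps with
    u_f ~ N(0, tau2_f) per level and eps_i ~ N(0, sigma2 / w_i).

    ``groups`` maps each random factor to its integer level codes.  Optionally
    clip to [0, 1] (off by default; clipping breaks Gaussianity and is only
    for I/O realism).
    """
    X = np.asarray(X, float)
    beta = np.asarray([truth.beta.get(c, 0.0) for c in truth.terms], float)
    if X.shape[1] != beta.size:
        raise ValueError("design matrix and coefficient vector dimensions differ")
    w = np.asarray(weights, float)
    if w.shape[0] != X.shape[0] or np.any(w <= 0):
        raise ValueError("weights must be positive and match the design rows")
    rng = np.random.default_rng(seed)
    y = X @ beta
    for factor, codes in groups.items():
        tau2 = truth.tau2.get(factor, 0.0)
        codes = np.asarray(codes)
        u = rng.normal(0.0, np.sqrt(tau2), codes.max() + 1)
        y = y + u[codes]
    y = y + rng.normal(0.0, np.sqrt(truth.sigma2 / w))
    if clip:
        y = np.clip(y, 0.0, 1.0)
    return y


def to_raw_he(gdp: np.ndarray, marker_type: Sequence[str]) -> np.ndarray:
    """Affine per-marker back-transform of a harmonized-scale response onto
    marker-specific raw heterozygosity ranges (for I/O realism tests; the
    analysis path consumes the harmonized response directly)."""
    gdp = np.asarray(gdp, float)
    marker_type = np.asarray(marker_type)
    out = np.empty_like(gdp)
    for marker, sc in MARKER_SCALES.items():
        m = marker_type == marker
        if not m.any():
            continue
        g = gdp[m]
        z = (g - gdp.mean()) / (gdp.std(ddof=1) or 1.0)
        out[m] = np.clip(sc["center"] + sc["scale"] * z, sc["lo"], sc["hi"])
    return out


def make_dataset(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Produce one analysis-ready table plus its ground truth.

    The table carries everything the pipeline consumes: taxonomy, coordinates,
    marker metadata, covariates, precision ``weight``, the simulated harmonized
    response ``gdp``, and a back-transformed ``he_raw``.  With the default
    (clean) config it passes the inclusion filters with zero exclusions.
    """
    config.validate()
    use_seed = config.seed if seed is None else seed
    species, pops = generate_metadata(config, seed=use_seed)
    data = pops.merge(species.drop(columns=["marker_type", "phylum", "kingdom"]), on="species")
    data = data.set_index(pops.index)

    dm = build_design(data, config.effect_terms)
    unknown = set(config.beta) - set(dm.column_names)
    if unknown:
        raise ConfigError(f"beta names not in the design: {sorted(unknown)}")
    truth = GroundTruth(
        beta={c: float(config.beta.get(c, 0.0)) for c in dm.column_names},
        tau2={"species": config.tau2_species, "marker_type": config.tau2_marker},
        sigma2=config.sigma2,
        terms=tuple(dm.column_names),
        linear_predictor=dm.X @ np.asarray([config.beta.get(c, 0.0) for c in dm.column_names]),
        seed=use_seed,
    )
    w = precision_weight(data["n_loci"].to_numpy(float), data["sample_size"].to_numpy(float))
    data["weight"] = w
    groups = {
        "species": pd.factorize(data["species"], sort=True)[0],
        "marker_type": pd.factorize(data["marker_type"], sort=True)[0],
    }
    resp_seed = int(np.random.SeedSequence(use_seed).spawn(4)[3].generate_state(1)[0] % (2**31))
    data["gdp"] = simulate_gdp(dm.X, truth, w, groups, resp_seed, clip=config.clip_response)
    data["he_raw"] = to_raw_he(data["gdp"].to_numpy(), data["marker_type"])
    return data, truth
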