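"""Exhaustive multi-model inference: submodel enumeration, AICc, Akaike
weights, per-term relative importance, and final-model assembly.

All marginality-respecting subsets of the full kingdom model's fixed terms are
fitted by ML with identical random structure and weights; models within
ΔAICc < 4 of the best form the candidate set.  Each term's relative importance
(RI) is the sum of Akaike weights of candidate models containing it,
renormalized over the candidate set so RI runs from 0 to 100%.  Terms with
RI strictly above 50% enter the final model, which is refit (REML) for the
reported estimates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .design import Term, build_design, canonical_term, marginality_closure, term_name
from .errors import DomainError, EnumerationCapError
from .mixedmodel import FitResult, ModelSpec, fit_weighted_lmm

#: default ΔAICc window for the candidate set
DEFAULT_DELTA = 4.0
#: default RI threshold (percent, strict) for final-model inclusion
DEFAULT_RI_THRESHOLD = 50.0
#: refuse to enumerate more than this many submodels
DEFAULT_ENUMERATION_CAP = 100_000

ANIMAL_PHYLA = ("amphibian", "bird", "mammal", "mollusc", "reptile")
PLANT_PHYLA = ("eudicot", "magnolid", "monocot", "pine")

_SHARED_MAINS = (
    "position",
    "range_area",
    "elevation",
    "temperature_pc",
    "precipitation_pc",
    "humidity_pc",
    "mh_stability",
    "lgm_stability",
)
ANIMAL_LIFE_HISTORY = ("pc_size_longevity", "pc_fecundity")
PLANT_LIFE_HISTORY = ("pollen", "seed", "mating", "lifeform")


def build_full_kingdom_spec(
    kingdom: Literal["animal", "plant"],
    response: str = "gdp",
    weights: str = "weight",
    phylum_interactions: Sequence[str] | Literal["all"] = "all",
) -> ModelSpec:
    """Full fixed-effect structure for one kingdom.

    Mains: biogeographic position, life history (two animal PCs, or the four
    plant trait classes), range area, elevation, the three current-climate
    axes, the two past-temperature stabilities, and phylum.  Interactions:
    position × each life-history term, plus phylum × every other predictor
    (restrict via ``phylum_interactions`` to keep the dredge tractable on
    small datasets).  Random intercepts: species and marker type.
    """
    life = ANIMAL_LIFE_HISTORY if kingdom == "animal" else PLANT_LIFE_HISTORY
    mains = list(_SHARED_MAINS[:1]) + list(life) + list(_SHARED_MAINS[1:]) + ["phylum"]
    inter: list[Term] = [canonical_term(("position", lh)) for lh in life]
    partners = [m for m in mains if m != "phylum"]
    if phylum_interactions != "all":
        partners = [m for m in partners if m in set(phylum_interactions)]
    inter += [canonical_term(("phylum", m)) for m in partners]
    fixed = tuple([(m,) for m in mains] + inter)
    return ModelSpec(response, fixed, ("species", "marker_type"), weights, "ML")


def count_submodels(full_terms: Sequence[Term]) -> int:
    """Number of marginality-respecting subsets of ``full_terms`` (including
    the intercept-only model): sum over main subsets S of 2^(#interactions
    whose parents are all in S)."""
    terms = [canonical_term(t) for t in full_terms]
    mains = [t for t in terms if len(t) == 1]
    inters = [t for t in terms if len(t) > 1]
    total = 0
    for r in range(len(mains) + 1):
        for S in itertools.combinations(mains, r):
            sset = {t[0] for t in S}
            k = sum(1 for i in inters if all(v in sset for v in i))
            total += 2**k
    return total


def enumerate_submodels(
    full: ModelSpec, cap: int = DEFAULT_ENUMERATION_CAP
) -> list[ModelSpec]:
    """All marginality-respecting submodels of ``full`` (intercept-only model
    included), with identical random structure and weights; deterministic
    order.  Raises :class:`EnumerationCapError` above ``cap`` models."""
    n_models = count_submodels(full.fixed)
    if n_models > cap:
        raise EnumerationCapError(
            f"{n_models} submodels exceed the cap of {cap}; reduce the number of "
            "terms (e.g. restrict phylum interactions) or raise the cap"
        )
    mains = sorted(t for t in full.fixed if len(t) == 1)
    inters = sorted(t for t in full.fixed if len(t) > 1)
    out: list[ModelSpec] = []
    for r in range(len(mains) + 1):
        for S in itertools.combinations(mains, r):
            sset = {t[0] for t in S}
            allowed = [i for i in inters if all(v in sset for v in i)]
            for ri in range(len(allowed) + 1):
                for I in itertools.combinations(allowed, ri):
                    out.append(full.with_terms(list(S) + list(I)))
    return out


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion:
    AIC + 2k(k+1)/(n-k-1).  Requires n > k + 1."""
    if n <= k + 1:
        raise DomainError(f"AICc undefined for n={n} <= k+1={k + 1}")
    aic = -2.0 * loglik + 2.0 * k
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class CandidateSet:
    """Models within ΔAICc < delta of the best, with normalized Akaike weights.

    ``table`` columns: model_id, terms (joined by " + "), loglik, k, aicc,
    delta_aicc, weight — sorted by AICc.  ``specs`` aligns with ``table``
    rows; ``fits`` is kept when the set came from :func:`dredge`.
    """

    table: pd.DataFrame
    specs: list[ModelSpec]
    delta: float
    fits: list[FitResult] | None = None

    def __len__(self) -> int:
        return len(self.specs)


def candidate_set(
    models: Sequence[tuple[ModelSpec, float]],
    delta: float = DEFAULT_DELTA,
    extra: dict | None = None,
) -> CandidateSet:
    """Retain models with AICc within ``delta`` of the minimum and attach
    Akaike weights exp(-Δ_i/2) normalized over the retained set."""
    if not models:
        raise ValueError("need at least one model")
    aiccs = np.array([a for _, a in models], float)
    best = aiccs.min()
    keep = np.where(aiccs - best < delta)[0]
    order = keep[np.argsort(aiccs[keep], kind="stable")]
    deltas = aiccs[order] - best
    wraw = np.exp(-deltas / 2.0)
    weights = wraw / wraw.sum()
    specs = [models[i][0] for i in order]
    rows = []
    for rank, (i, d, w) in enumerate(zip(order, deltas, weights)):
        spec = models[i][0]
        rows.append(
            {
                "model_id": int(i),
                "terms": " + ".join(spec.term_names) or "1",
                "aicc": float(aiccs[i]),
                "delta_aicc": float(d),
                "weight": float(w),
                **({k: v[i] for k, v in extra.items()} if extra else {}),
            }
        )
    return CandidateSet(pd.DataFrame(rows), specs, delta)


@dataclass
class RITable:
    """Per-term relative importance (percent) over a candidate set."""

    ri: pd.Series  # term name -> RI in [0, 100]
    supporting: dict[str, list[int]]  # term name -> candidate model_ids containing it

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": self.ri.index, "ri_percent": self.ri.to_numpy()}
        ).reset_index(drop=True)


def relative_importance(cs: CandidateSet, all_terms: Sequence[Term] | None = None) -> RITable:
    """RI(term) = 100 x sum of (candidate-set-normalized) Akaike weights of the
    candidate models containing the term.  ``all_terms`` fixes the set of
    reported terms (defaults to the union over candidate models); terms absent
    from every candidate get RI 0."""
    if len(cs) == 0:
        raise ValueError("empty candidate set")
    if all_terms is None:
        names = sorted({nm for spec in cs.specs for nm in spec.term_names})
    else:
        names = [term_name(canonical_term(t)) for t in all_terms]
    ri = {}
    supporting: dict[str, list[int]] = {}
    weights = cs.table["weight"].to_numpy()
    ids = cs.table["model_id"].to_numpy()
    for nm in names:
        mask = np.array([nm in spec.term_names for spec in cs.specs])
        ri[nm] = 100.0 * float(weights[mask].sum())
        supporting[nm] = [int(i) for i in ids[mask]]
    return RITable(pd.Series(ri, name="ri_percent"), supporting)


def select_final_terms(
    ri: RITable, full: ModelSpec, threshold: float = DEFAULT_RI_THRESHOLD
) -> ModelSpec:
    """Terms with RI strictly above ``threshold`` percent, closed under
    marginality (a selected interaction pulls in its mains); empty selection
    degrades to the intercept-only spec with a warning."""
    chosen = [canonical_term(nm) for nm, v in ri.ri.items() if v > threshold]
    if not chosen:
        import warnings

        warnings.warn("no term exceeded the RI threshold; returning intercept-only model")
        return full.with_terms([])
    return full.with_terms(marginality_closure(chosen))


def dredge(
    full: ModelSpec,
    data: pd.DataFrame,
    delta: float = DEFAULT_DELTA,
    cap: int = DEFAULT_ENUMERATION_CAP,
    progress: Callable[[int, int], None] | None = None,
) -> tuple[CandidateSet, RITable]:
    """Fit every marginality-respecting submodel (ML), assemble the ΔAICc <
    ``delta`` candidate set, and compute relative importance for every term of
    the full model.  Deterministic: results do not depend on fit order."""
    ml_full = replace(full, method="ML")
    levels = build_design(data, ml_full.fixed).levels  # pin level order once
    specs = enumerate_submodels(ml_full, cap=cap)
    scored: list[tuple[ModelSpec, float]] = []
    extra = {"loglik": {}, "k": {}}
    import warnings

    for i, spec in enumerate(specs):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # boundary flags are per-fit noise here
            fit = fit_weighted_lmm(spec, data, levels=levels)
        scored.append((spec, fit.aicc))
        extra["loglik"][i] = fit.loglik
        extra["k"][i] = fit.k
        if progress is not None:
            progress(i + 1, len(specs))
    cs = candidate_set(scored, delta=delta, extra=extra)
    ri = relative_importance(cs, all_terms=full.fixed)
    return cs, ri
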