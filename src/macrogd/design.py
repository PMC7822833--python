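"""Term-based fixed-effect design matrices.

Models are specified as sets of *terms* over named data columns: a main effect
is a 1-tuple ``("elevation",)``, a pairwise interaction a 2-tuple
``("position", "pc_fecundity")``.  Categorical columns (object / string /
category / bool dtype) get treatment coding against the first sorted level;
interactions are elementwise products of the component encodings.  Keeping the
term -> column mapping explicit is what lets model selection add and remove
whole terms (all levels of a categorical together) and lets group-slope
contrasts find their interaction columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import RankDeficiencyError

Term = tuple[str, ...]


def canonical_term(term: Sequence[str] | str) -> Term:
    """Normalize a term: a bare string is a main effect; variable order within
    an interaction is alphabetical so ``A:B`` and ``B:A`` are the same term."""
    if isinstance(term, str):
        parts = term.split(":")
    else:
        parts = list(term)
    if len(parts) == 1:
        return (parts[0],)
    return tuple(sorted(parts))


def term_name(term: Term) -> str:
    return ":".join(term)


def is_categorical(s: pd.Series) -> bool:
    return (
        isinstance(s.dtype, pd.CategoricalDtype)
        or pd.api.types.is_object_dtype(s)
        or pd.api.types.is_string_dtype(s)
        or pd.api.types.is_bool_dtype(s)
    )


@dataclass
class DesignMatrix:
    """Fixed-effect design with bookkeeping.

    ``X`` includes the intercept as column 0.  ``term_columns`` maps each term
    name (and ``"Intercept"``) to its column indices; ``levels`` records the
    full level order (reference first) of each categorical variable.
    """

    X: np.ndarray
    column_names: list[str]
    term_columns: dict[str, list[int]]
    levels: dict[str, list[str]]
    terms: tuple[Term, ...]

    @property
    def n_params(self) -> int:
        return self.X.shape[1]

    def column_index(self, name: str) -> int:
        return self.column_names.index(name)


def _encode_main(data: pd.DataFrame, var: str, levels: dict[str, list[str]]):
    """Return (columns, names) for one variable; categoricals drop the reference."""
    s = data[var]
    if is_categorical(s):
        if var not in levels:
            levels[var] = sorted(pd.Series(s).astype(str).dropna().unique().tolist())
        lv = levels[var]
        cols = [(pd.Series(s).astype(str) == l).to_numpy(float) for l in lv[1:]]
        names = [f"{var}[{l}]" for l in lv[1:]]
        return cols, names
    return [s.to_numpy(float)], [var]


def build_design(
    data: pd.DataFrame,
    terms: Sequence[Term],
    levels: dict[str, list[str]] | None = None,
    check_rank: bool = True,
) -> DesignMatrix:
    """Build the design matrix for ``terms`` over ``data``.

    ``levels`` pins categorical level order (reference first); pass the full
    dataset's levels when fitting on subsets (jackknife) so coefficients stay
    aligned.  Raises :class:`RankDeficiencyError` naming aliased columns when
    the design is column-rank deficient.
    """
    levels = dict(levels) if levels else {}
    terms = tuple(canonical_term(t) for t in terms)
    cols: list[np.ndarray] = [np.ones(len(data))]
    names: list[str] = ["Intercept"]
    term_columns: dict[str, list[int]] = {"Intercept": [0]}

    for term in terms:
        parts = [_encode_main(data, v, levels) for v in term]
        # cartesian product of component encodings
        prod_cols = parts[0][0]
        prod_names = parts[0][1]
        for pcols, pnames in parts[1:]:
            prod_cols = [a * b for a in prod_cols for b in pcols]
            prod_names = [f"{na}:{nb}" for na in prod_names for nb in pnames]
        idx = list(range(len(cols), len(cols) + len(prod_cols)))
        term_columns[term_name(term)] = idx
        cols.extend(prod_cols)
        names.extend(prod_names)

    X = np.column_stack(cols)
    if check_rank:
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            aliased = _find_aliased(X, names)
            raise RankDeficiencyError(
                f"design matrix rank {rank} < {X.shape[1]} columns; aliased: {aliased}",
                aliased=aliased,
            )
    return DesignMatrix(X, names, term_columns, levels, terms)


def _find_aliased(X: np.ndarray, names: list[str]) -> list[str]:
    aliased, kept = [], np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        cand = np.column_stack([kept, X[:, j]])
        if np.linalg.matrix_rank(cand) == kept.shape[1]:
            aliased.append(names[j])
        else:
            kept = cand
    return aliased


def marginality_ok(terms: Sequence[Term]) -> bool:
    """True when every interaction's component mains are present."""
    tset = {canonical_term(t) for t in terms}
    for t in tset:
        if len(t) > 1 and any((v,) not in tset for v in t):
            return False
    return True


def marginality_closure(terms: Sequence[Term]) -> tuple[Term, ...]:
    """Add the missing mains of every interaction; deterministic order
    (mains alphabetical, then interactions alphabetical)."""
    tset = {canonical_term(t) for t in terms}
    for t in list(tset):
        for v in t:
            tset.add((v,))
    mains = sorted(t for t in tset if len(t) == 1)
    inter = sorted(t for t in tset if len(t) > 1)
    return tuple(mains + inter)
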