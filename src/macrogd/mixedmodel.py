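"""Precision-weighted Gaussian linear mixed models with crossed random intercepts.

The observation model is

    y = X beta + sum_f Z_f u_f + eps,
    u_f ~ N(0, tau2_f I),   eps_i ~ N(0, sigma2 / w_i),

with known positive precision weights w_i and independent random intercepts
for each grouping factor f (species, marker type, kingdom — crossed, not
nested).  Estimation profiles beta and sigma2 out of the (restricted)
likelihood and optimizes the variance ratios theta_f = tau2_f / sigma2 by
bounded quasi-Newton.  Because every random term is an intercept, the
marginal covariance is diagonal-plus-low-rank,

    V0 = diag(1/w) + Z G Z',   G = diag(theta_f repeated per level),

and the Woodbury identity reduces every solve and log-determinant to a dense
q x q system, q = total number of random levels — the per-iteration cost is
O(n q + q^3) rather than O(n^3).

ML fits are comparable across fixed structures (used for model selection);
REML refits are used for reported final estimates.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import (
    DesignMatrix,
    Term,
    build_design,
    canonical_term,
    marginality_ok,
    term_name,
)
from .errors import ConvergenceError, ZeroVarianceError

_LOG2PI = math.log(2.0 * math.pi)

#: variance ratio below which a random factor is flagged as at the boundary
BOUNDARY_TOL = 1e-6


@dataclass(frozen=True)
class ModelSpec:
    """Symbolic model description: response, fixed terms, random intercept
    factors, weight column, and estimation method."""

    response: str
    fixed: tuple[Term, ...]
    random: tuple[str, ...] = ()
    weights: str | None = None
    method: Literal["ML", "REML"] = "ML"

    def __post_init__(self):
        object.__setattr__(self, "fixed", tuple(canonical_term(t) for t in self.fixed))
        if not marginality_ok(self.fixed):
            raise ValueError("fixed terms violate marginality (interaction without its mains)")
        fixed_vars = {v for t in self.fixed for v in t}
        clash = fixed_vars & set(self.random)
        if clash:
            raise ValueError(f"random factors also appear in fixed terms: {sorted(clash)}")

    @property
    def term_names(self) -> tuple[str, ...]:
        return tuple(term_name(t) for t in self.fixed)

    def formula(self) -> str:
        rhs = " + ".join(self.term_names) or "1"
        rand = "".join(f" + (1|{g})" for g in self.random)
        w = f", weights={self.weights}" if self.weights else ""
        return f"{self.response} ~ {rhs}{rand}{w}"

    def with_terms(self, terms: Sequence[Term]) -> "ModelSpec":
        return replace(self, fixed=tuple(canonical_term(t) for t in terms))


_FORMULA_RE = re.compile(r"^\s*(?P<lhs>[\w.]+)\s*~\s*(?P<rhs>.+?)\s*$")
_RANDOM_RE = re.compile(r"\(\s*1\s*\|\s*([\w.]+)\s*\)")


def parse_formula(formula: str, method: Literal["ML", "REML"] = "ML") -> ModelSpec:
    """Parse the plain-text mini-grammar, e.g.

        "gdp ~ abs_latitude * kingdom + (1|species) + (1|marker), weights=weight"

    ``a*b`` expands to ``a + b + a:b``; ``(1|g)`` adds a random intercept for
    ``g``; a trailing ``, weights=col`` names the precision-weight column.
    """
    weights = None
    if "," in formula:
        formula, _, tail = formula.partition(",")
        m = re.search(r"weights\s*=\s*([\w.]+)", tail)
        if not m:
            raise ValueError(f"cannot parse formula tail: '{tail.strip()}'")
        weights = m.group(1)
    m = _FORMULA_RE.match(formula)
    if not m:
        raise ValueError(f"cannot parse formula: '{formula}'")
    rhs = m.group("rhs")
    random = tuple(_RANDOM_RE.findall(rhs))
    rhs = _RANDOM_RE.sub("", rhs)
    terms: list[Term] = []
    for piece in (p.strip() for p in rhs.split("+")):
        if not piece or piece == "1":
            continue
        if "*" in piece:
            vars_ = [v.strip() for v in piece.split("*")]
            for v in vars_:
                terms.append((v,))
            terms.append(canonical_term(vars_))
        elif ":" in piece:
            terms.append(canonical_term(piece))
        else:
            terms.append((piece,))
    seen, uniq = set(), []
    for t in terms:
        if t not in seen:
            seen.add(t)
            uniq.append(t)
    return ModelSpec(m.group("lhs"), tuple(uniq), random, weights, method)


# ---------------------------------------------------------------------------
# fitting machinery
# ---------------------------------------------------------------------------


class _Profile:
    """Profiled (RE)ML deviance over variance ratios for fixed X, y, w, Z."""

    def __init__(self, X: np.ndarray, y: np.ndarray, w: np.ndarray, codes: list[np.ndarray], nlev: list[int]):
        self.X, self.y, self.w = X, y, w
        self.codes, self.nlev = codes, nlev
        self.n, self.p = X.shape
        self.eval_trace: list[tuple[np.ndarray, float]] = []

    def _woodbury(self, theta: np.ndarray):
        """Return callables/values for V0^{-1} products and log|V0|."""
        w = self.w
        active = [i for i, t in enumerate(theta) if t > 0]
        if not active:
            return None, float(-np.sum(np.log(w)))
        offs, blocks = [], 0
        for i in active:
            offs.append(blocks)
            blocks += self.nlev[i]
        q = blocks
        # A = Z' D^{-1} Z  (dense q x q; q is small)
        A = np.zeros((q, q))
        for ai, i in enumerate(active):
            ci = self.codes[i]
            np.add.at(A, (offs[ai] + ci, offs[ai] + ci), w)
            for aj in range(ai + 1, len(active)):
                j = active[aj]
                cj = self.codes[j]
                np.add.at(A, (offs[ai] + ci, offs[aj] + cj), w)
        iu = np.triu_indices(q, 1)
        A[(iu[1], iu[0])] = A[iu]
        g = np.concatenate([np.full(self.nlev[i], theta[i]) for i in active])
        B = A + np.diag(1.0 / g)
        # log|V0| = -sum log w + log|I + G A| = -sum log w + log|B| + sum log g
        sign, logdetB = np.linalg.slogdet(B)
        if sign <= 0:
            raise FloatingPointError("non-PD inner matrix")
        logdetV0 = float(-np.sum(np.log(w)) + logdetB + np.sum(np.log(g)))
        Binv = np.linalg.inv(B)

        def ztd(M):  # Z' D^{-1} M
            M = np.atleast_2d(M.T).T
            out = np.zeros((q, M.shape[1]))
            wm = M * w[:, None]
            for ai, i in enumerate(active):
                ci = self.codes[i]
                for k in range(M.shape[1]):
                    out[offs[ai] : offs[ai] + self.nlev[i], k] += np.bincount(
                        ci, weights=wm[:, k], minlength=self.nlev[i]
                    )
            return out

        def v0inv(M):  # V0^{-1} M
            M2 = np.atleast_2d(M.T).T
            zt = ztd(M2)
            corr = Binv @ zt
            back = np.zeros_like(M2)
            for ai, i in enumerate(active):
                back += corr[offs[ai] + self.codes[i], :]
            res = M2 * self.w[:, None] - back * self.w[:, None]
            return res if M.ndim > 1 else res[:, 0]

        return (v0inv, ztd, Binv, offs, active, g), logdetV0

    def solve(self, theta: np.ndarray, reml: bool):
        """GLS at fixed theta; returns dict with beta, sigma2, loglik, pieces."""
        wb, logdetV0 = self._woodbury(theta)
        if wb is None:
            V0invX = self.X * self.w[:, None]
            V0invy = self.y * self.w
        else:
            v0inv = wb[0]
            V0invX = v0inv(self.X)
            V0invy = v0inv(self.y)
        XtVX = self.X.T @ V0invX
        XtVy = self.X.T @ V0invy
        try:
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError as e:  # pragma: no cover - guarded upstream
            raise ConvergenceError(f"singular GLS system: {e}")
        r = self.y - self.X @ beta
        if wb is None:
            qform = float(r @ (r * self.w))
        else:
            qform = float(r @ wb[0](r))
        qform = max(qform, 1e-300)
        n, p = self.n, self.p
        if reml:
            sigma2 = qform / (n - p)
            sign, logdetXtVX = np.linalg.slogdet(XtVX)
            m2ll = (n - p) * (_LOG2PI + math.log(sigma2)) + logdetV0 + logdetXtVX + (n - p)
        else:
            sigma2 = qform / n
            m2ll = n * (_LOG2PI + math.log(sigma2)) + logdetV0 + n
        return {
            "beta": beta,
            "sigma2": sigma2,
            "m2ll": float(m2ll),
            "XtVX": XtVX,
            "resid_marginal": r,
            "wb": wb,
            "logdetV0": logdetV0,
        }

    def objective(self, theta: np.ndarray, reml: bool) -> float:
        try:
            val = self.solve(theta, reml)["m2ll"]
        except FloatingPointError:
            val = 1e12
        self.eval_trace.append((theta.copy(), val))
        return val


@dataclass
class FitResult:
    """A fitted precision-weighted LMM.

    ``params`` / ``bse`` / ``pvalues`` are indexed by design column name;
    ``tau2`` maps each random factor to its intercept variance; ``k`` counts
    fixed coefficients plus variance components (one per random factor plus
    the residual), the parameter count used by AICc.
    """

    spec: ModelSpec
    method: str
    params: pd.Series
    cov_params: pd.DataFrame
    tau2: dict[str, float]
    sigma2: float
    loglik: float
    n: int
    k: int
    design: DesignMatrix
    fitted_marginal: np.ndarray
    resid_marginal: np.ndarray
    fitted: np.ndarray
    resid: np.ndarray
    ranef: dict[str, pd.Series]
    converged: bool
    boundary: tuple[str, ...] = ()
    opt_trace: list = field(default_factory=list, repr=False)
    index: pd.Index | None = None

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params.to_numpy())), index=self.params.index)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.zvalues)), index=self.params.index)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    @property
    def aicc(self) -> float:
        from .model_selection import aicc as _aicc

        return _aicc(self.loglik, self.k, self.n)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        zcrit = stats.norm.ppf(0.5 + level / 2)
        return pd.DataFrame(
            {"lower": self.params - zcrit * self.bse, "upper": self.params + zcrit * self.bse}
        )

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
            }
        )

    def to_dict(self) -> dict:
        r2m, r2c = r2_nakagawa(self)
        return {
            "formula": self.spec.formula(),
            "method": self.method,
            "n": self.n,
            "k": self.k,
            "loglik": self.loglik,
            "aicc": self.aicc,
            "sigma2": self.sigma2,
            "tau2": self.tau2,
            "r2_marginal": r2m,
            "r2_conditional": r2c,
            "coefficients": {
                name: {
                    "estimate": float(self.params[name]),
                    "se": float(self.bse[name]),
                    "p": float(self.pvalues[name]),
                }
                for name in self.params.index
            },
            "converged": self.converged,
            "boundary": list(self.boundary),
        }


def fit_weighted_lmm(
    spec: ModelSpec,
    data: pd.DataFrame,
    levels: dict[str, list[str]] | None = None,
    fix_theta: Mapping[str, float] | None = None,
    design: DesignMatrix | None = None,
) -> FitResult:
    """Fit ``spec`` to ``data`` by profiled ML or REML.

    Parameters
    ----------
    spec
        Model description; ``spec.method`` selects ML (model comparison) or
        REML (final estimates).
    data
        Harmonized table containing the response, every fixed-term variable,
        each random factor, and the weight column (all weights > 0; missing
        weight column means unit weights).
    levels
        Optional categorical level pinning (see :func:`~macrogd.design.build_design`).
    fix_theta
        Map random factor -> fixed variance ratio tau2/sigma2; factors listed
        here are not optimized (0 constrains the variance to zero).
    design
        Pre-built design matrix (used by model selection to avoid rebuilding).

    Raises
    ------
    RankDeficiencyError, ConvergenceError, ValueError
    """
    y = data[spec.response].to_numpy(float)
    if np.any(~np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    if spec.weights is not None:
        w = data[spec.weights].to_numpy(float)
        if np.any(w <= 0) or np.any(~np.isfinite(w)):
            raise ValueError("all weights must be positive and finite")
    else:
        w = np.ones(len(data))
    if design is None:
        design = build_design(data, spec.fixed, levels=levels)
    X = design.X

    codes, nlev, factor_levels = [], [], {}
    for g in spec.random:
        code, lev = pd.factorize(data[g].astype(str), sort=True)
        if len(lev) < 2:
            raise ValueError(f"random factor '{g}' has fewer than 2 levels")
        codes.append(code)
        nlev.append(len(lev))
        factor_levels[g] = list(lev)

    prof = _Profile(X, y, w, codes, nlev)
    nfac = len(spec.random)
    reml = spec.method == "REML"

    free = [i for i, g in enumerate(spec.random) if not (fix_theta and g in fix_theta)]
    theta_full = np.zeros(nfac)
    if fix_theta:
        for i, g in enumerate(spec.random):
            if g in fix_theta:
                theta_full[i] = float(fix_theta[g])

    converged = True
    if free:
        def obj(tfree):
            th = theta_full.copy()
            th[free] = tfree
            return prof.objective(th, reml)

        x0 = np.ones(len(free))
        res = optimize.minimize(
            obj,
            x0,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * len(free),
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        if not res.success:
            # one restart from a smaller ratio before giving up
            res2 = optimize.minimize(
                obj, np.full(len(free), 0.1), method="L-BFGS-B",
                bounds=[(0.0, None)] * len(free), options={"maxiter": 500, "ftol": 1e-12},
            )
            if res2.fun <= res.fun:
                res = res2
            if not res.success and not np.isfinite(res.fun):
                raise ConvergenceError(f"optimizer failed: {res.message}", trace=prof.eval_trace)
            converged = bool(res.success or res2.success)
        theta_full[free] = res.x
    sol = prof.solve(theta_full, reml)

    sigma2 = sol["sigma2"]
    tau2 = {g: float(theta_full[i] * sigma2) for i, g in enumerate(spec.random)}
    boundary = tuple(g for i, g in enumerate(spec.random) if theta_full[i] <= BOUNDARY_TOL)
    if boundary:
        warnings.warn(
            f"random-intercept variance at boundary for: {', '.join(boundary)}",
            RuntimeWarning,
            stacklevel=2,
        )

    cov = pd.DataFrame(
        sigma2 * np.linalg.inv(sol["XtVX"]), index=design.column_names, columns=design.column_names
    )
    params = pd.Series(sol["beta"], index=design.column_names)
    fitted_marginal = X @ sol["beta"]
    r = sol["resid_marginal"]

    # BLUPs: u = G Z' V0^{-1} r
    ranef: dict[str, pd.Series] = {}
    fitted = fitted_marginal.copy()
    wb = sol["wb"]
    if wb is not None:
        v0inv_r = wb[0](r)
        _, _, _, offs, active, _g = wb
        for ai, i in enumerate(active):
            g = spec.random[i]
            u = theta_full[i] * np.bincount(codes[i], weights=v0inv_r, minlength=nlev[i])
            ranef[g] = pd.Series(u, index=factor_levels[g])
            fitted += u[codes[i]]
    for i, g in enumerate(spec.random):
        if g not in ranef:
            ranef[g] = pd.Series(np.zeros(nlev[i]), index=factor_levels[g])

    k = design.n_params + nfac + 1
    loglik = -0.5 * sol["m2ll"]
    return FitResult(
        spec=spec,
        method=spec.method,
        params=params,
        cov_params=cov,
        tau2=tau2,
        sigma2=float(sigma2),
        loglik=float(loglik),
        n=len(y),
        k=k,
        design=design,
        fitted_marginal=fitted_marginal,
        resid_marginal=r,
        fitted=fitted,
        resid=y - fitted,
        ranef=ranef,
        converged=converged,
        boundary=boundary,
        opt_trace=prof.eval_trace,
        index=data.index,
    )


def r2_nakagawa(fit: FitResult) -> tuple[float, float]:
    """Marginal and conditional R² for a Gaussian mixed model.

    R²m = var(X beta) / (var(X beta) + sum tau2 + sigma2); R²c adds the random
    intercept variances to the numerator.  For weighted fits sigma2 is the
    residual variance at unit weight.  Variance of the fixed-effect predictor
    uses the sample (n-1) denominator.
    """
    var_f = float(np.var(fit.fitted_marginal, ddof=1)) if fit.n > 1 else 0.0
    var_r = float(sum(fit.tau2.values()))
    total = var_f + var_r + fit.sigma2
    if total <= 0:
        raise ZeroVarianceError("zero total variance; R² undefined")
    return var_f / total, (var_f + var_r) / total


def build_latitude_spec(
    level: Literal["kingdom", "phylum"],
    response: str = "gdp",
    weights: str = "weight",
    method: Literal["ML", "REML"] = "REML",
) -> ModelSpec:
    """Latitudinal-gradient model specs.

    ``kingdom``: gdp ~ |latitude| * kingdom + (1|species) + (1|marker);
    ``phylum``: gdp ~ |latitude| * phylum + (1|species) + (1|marker) +
    (1|kingdom) — kingdom becomes a random term once phylum is the fixed
    grouping.
    """
    if level == "kingdom":
        fixed = (("abs_latitude",), ("kingdom",), canonical_term(("abs_latitude", "kingdom")))
        random = ("species", "marker_type")
    elif level == "phylum":
        fixed = (("abs_latitude",), ("phylum",), canonical_term(("abs_latitude", "phylum")))
        random = ("species", "marker_type", "kingdom")
    else:
        raise ValueError("level must be 'kingdom' or 'phylum'")
    return ModelSpec(response, fixed, random, weights, method)


def extract_group_slopes(
    fit: FitResult,
    group: str,
    continuous: str = "abs_latitude",
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-group slopes of ``continuous`` from a model with a
    ``continuous * group`` interaction.

    The reference group's slope is the base coefficient; every other group's
    slope is base + interaction, with the SE of the contrast c'beta taken from
    the full coefficient covariance: sqrt(c' Sigma c).  Returns a table with
    columns slope, se, lower, upper, p indexed by group level.
    """
    inter = term_name(canonical_term((continuous, group)))
    if inter not in fit.design.term_columns:
        raise ValueError(f"model has no '{inter}' interaction term")
    if group not in fit.design.levels:
        raise ValueError(f"'{group}' is not categorical in this design")
    levels_ = fit.design.levels[group]
    names = fit.params.index.tolist()
    base_idx = names.index(continuous)
    Sigma = fit.cov_params.to_numpy()
    zcrit = stats.norm.ppf(0.5 + level / 2)
    rows = {}
    for lv in levels_:
        c = np.zeros(len(names))
        c[base_idx] = 1.0
        if lv != levels_[0]:
            target = {f"{continuous}:{group}[{lv}]", f"{group}[{lv}]:{continuous}"}
            j = next(i for i, nm in enumerate(names) if nm in target)
            c[j] = 1.0
        est = float(c @ fit.params.to_numpy())
        se = float(np.sqrt(c @ Sigma @ c))
        z = est / se if se > 0 else np.inf
        rows[lv] = {
            "slope": est,
            "se": se,
            "lower": est - zcrit * se,
            "upper": est + zcrit * se,
            "p": float(2 * stats.norm.sf(abs(z))),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def fit_with_marker_fallback(
    spec: ModelSpec, data: pd.DataFrame, marker_factor: str = "marker_type", **kwargs
) -> FitResult:
    """Fit ``spec``; if the marker random-intercept variance lands on the zero
    boundary, refit with marker as a fixed main effect instead (few-level
    factors often cannot support a variance estimate)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = fit_weighted_lmm(spec, data, **kwargs)
    if marker_factor in fit.boundary:
        fallback = replace(
            spec,
            fixed=tuple(spec.fixed) + ((marker_factor,),),
            random=tuple(g for g in spec.random if g != marker_factor),
        )
        return fit_weighted_lmm(fallback, data, **kwargs)
    return fit
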