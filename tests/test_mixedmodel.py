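import shutil
import subprocess
import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from macrogd.design import build_design
from macrogd.mixedmodel import (
    ModelSpec,
    build_latitude_spec,
    extract_group_slopes,
    fit_weighted_lmm,
    fit_with_marker_fallback,
    parse_formula,
    r2_nakagawa,
)


@pytest.fixture(scope="module")
def data():
    from macrogd.synthetic import SyntheticConfig, make_dataset

    cfg = SyntheticConfig(n_species=30, pops_per_species=(2, 6), seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d, _ = make_dataset(cfg)
    return d


SPEC = ModelSpec(
    "gdp",
    (("abs_latitude",), ("kingdom",), ("abs_latitude", "kingdom")),
    ("species", "marker_type"),
    "weight",
    "ML",
)


class TestSpecAndFormula:
    def test_marginality_enforced(self):
        with pytest.raises(ValueError):
            ModelSpec("y", (("a", "b"),))

    def test_random_fixed_disjoint(self):
        with pytest.raises(ValueError):
            ModelSpec("y", (("species",),), ("species",))

    def test_parse_formula_roundtrip(self):
        spec = parse_formula(
            "gdp ~ abs_latitude * kingdom + (1|species) + (1|marker_type), weights=weight"
        )
        assert spec == SPEC

    def test_build_latitude_specs(self):
        k = build_latitude_spec("kingdom")
        assert len(k.fixed) == 3 and k.random == ("species", "marker_type")
        p = build_latitude_spec("phylum")
        assert "kingdom" in p.random
        assert marginal_ok(p)


def marginal_ok(spec):
    from macrogd.design import marginality_ok

    return marginality_ok(spec.fixed)


class TestDegenerateLimits:
    def test_zero_variance_equal_weights_equals_ols(self, data):
        d = data.assign(weight=1.0)
        fit = fit_weighted_lmm(SPEC, d, fix_theta={"species": 0.0, "marker_type": 0.0})
        X = build_design(d, SPEC.fixed).X
        y = d["gdp"].to_numpy()
        beta_ols = np.linalg.solve(X.T @ X, X.T @ y)  # normal-equations oracle
        assert np.allclose(fit.params.to_numpy(), beta_ols, atol=1e-8)

    def test_intercept_only_equals_mean(self, data):
        spec = ModelSpec("gdp", (), (), None, "ML")
        fit = fit_weighted_lmm(spec, data)
        assert fit.params["Intercept"] == pytest.approx(data["gdp"].mean(), abs=1e-10)

    def test_duplicate_rows_half_weight_same_beta(self, data):
        spec = ModelSpec("gdp", SPEC.fixed, (), "weight", "ML")
        fit1 = fit_weighted_lmm(spec, data)
        doubled = pd.concat([data, data], ignore_index=True)
        doubled["weight"] = doubled["weight"] / 2.0
        fit2 = fit_weighted_lmm(spec, doubled)
        assert np.allclose(fit1.params.to_numpy(), fit2.params.to_numpy(), atol=1e-8)

    def test_weights_rescale_invariance_of_beta(self, data):
        fit1 = fit_weighted_lmm(SPEC, data)
        # multiplying all weights by a constant only rescales sigma2
        d2 = data.assign(weight=data["weight"] * 3.0)
        fit2 = fit_weighted_lmm(SPEC, d2)
        assert np.allclose(fit1.params.to_numpy(), fit2.params.to_numpy(), atol=1e-6)
        assert fit2.sigma2 == pytest.approx(3.0 * fit1.sigma2, rel=1e-4)


@pytest.fixture(scope="module")
def lme4_oracle(data, tmp_path_factory):
    p = tmp_path_factory.mktemp("lmm")
    csv = p / "d.csv"
    data[["gdp", "abs_latitude", "kingdom", "species", "marker_type", "weight"]].to_csv(
        csv, index=False
    )
    script = p / "fit.R"
    script.write_text(
        """
        suppressMessages(library(lme4))
        d <- read.csv(commandArgs(TRUE)[1])
        for (reml in c(FALSE, TRUE)) {
          m <- lmer(gdp ~ abs_latitude*kingdom + (1|species) + (1|marker_type),
                    data=d, weights=weight, REML=reml)
          cat(sprintf("%.10f", logLik(m)), fixef(m), "\\n")
        }
        """
    )
    out = subprocess.run(
        ["Rscript", str(script), str(csv)], capture_output=True, text=True, check=True
    )
    lines = [l.split() for l in out.stdout.strip().splitlines()]
    return {m: (float(l[0]), np.array(l[1:], float)) for m, l in zip(("ML", "REML"), lines)}


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
class TestLme4Oracle:
    """Independent cross-check: the in-package profiled (RE)ML fitter against
    lme4 on the same small dataset."""

    @pytest.mark.parametrize("method", ["ML", "REML"])
    def test_loglik_and_coefficients_match(self, data, lme4_oracle, method):
        fit = fit_weighted_lmm(replace(SPEC, method=method), data)
        ll, beta = lme4_oracle[method]
        assert fit.loglik == pytest.approx(ll, abs=1e-4)
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-5)


class TestFitInternals:
    def test_refit_from_solution_reproduces_loglik(self, data):
        fit = fit_weighted_lmm(SPEC, data)
        theta = {g: v / fit.sigma2 for g, v in fit.tau2.items()}
        refit = fit_weighted_lmm(SPEC, data, fix_theta=theta)
        assert refit.loglik == pytest.approx(fit.loglik, abs=1e-6)

    def test_objective_trace_reaches_minimum(self, data):
        fit = fit_weighted_lmm(SPEC, data)
        vals = [v for _, v in fit.opt_trace]
        # the optimizer's best-so-far deviance is non-increasing and ends optimal
        assert min(vals) == pytest.approx(-2 * fit.loglik, abs=1e-8)

    def test_k_counts_fixed_plus_variance_components(self, data):
        fit = fit_weighted_lmm(SPEC, data)
        assert fit.k == fit.design.n_params + 2 + 1

    def test_marker_fallback_on_boundary(self, data):
        # force a marker boundary by removing marker-level signal
        rng = np.random.default_rng(0)
        d = data.copy()
        d["gdp"] = rng.normal(0.5, 0.1, len(d))
        fit = fit_with_marker_fallback(SPEC, d)
        if "marker_type" not in fit.spec.random:
            assert ("marker_type",) in fit.spec.fixed


class TestR2:
    def test_direct_formula(self, data):
        fit = fit_weighted_lmm(SPEC, data)
        r2m, r2c = r2_nakagawa(fit)
        var_f = np.var(fit.fitted_marginal, ddof=1)
        tot = var_f + sum(fit.tau2.values()) + fit.sigma2
        assert r2m == pytest.approx(var_f / tot)
        assert r2c == pytest.approx((var_f + sum(fit.tau2.values())) / tot)
        assert 0 <= r2m <= r2c <= 1

    def test_no_random_terms_r2c_equals_r2m(self, data):
        spec = ModelSpec("gdp", SPEC.fixed, (), "weight", "ML")
        fit = fit_weighted_lmm(spec, data)
        r2m, r2c = r2_nakagawa(fit)
        assert r2m == pytest.approx(r2c)

    def test_null_model_r2m_zero(self, data):
        spec = ModelSpec("gdp", (), ("species",), "weight", "ML")
        fit = fit_weighted_lmm(spec, data)
        r2m, _ = r2_nakagawa(fit)
        assert r2m == pytest.approx(0.0, abs=1e-12)

    def test_known_variance_shares(self):
        # simulated model with known shares: var(Xb)=1, tau2=1, sigma2=2
        rng = np.random.default_rng(5)
        n = 6000
        x = rng.normal(0, 1, n)
        g = np.repeat(np.arange(n // 20), 20)
        u = rng.normal(0, 1.0, n // 20)
        y = 1.0 * x + u[g] + rng.normal(0, np.sqrt(2.0), n)
        d = pd.DataFrame({"y": y, "x": x, "g": g.astype(str)})
        fit = fit_weighted_lmm(ModelSpec("y", (("x",),), ("g",), None, "ML"), d)
        r2m, r2c = r2_nakagawa(fit)
        assert r2m == pytest.approx(0.25, abs=0.02)
        assert r2c == pytest.approx(0.50, abs=0.02)


class TestGroupSlopes:
    def test_reference_group_is_base_coefficient(self, data):
        fit = fit_weighted_lmm(SPEC, data)
        slopes = extract_group_slopes(fit, "kingdom")
        assert slopes.loc["animal", "slope"] == pytest.approx(fit.params["abs_latitude"])

    def test_contrast_oracle(self, data):
        fit = fit_weighted_lmm(SPEC, data)
        slopes = extract_group_slopes(fit, "kingdom")
        names = list(fit.params.index)
        c = np.zeros(len(names))
        c[names.index("abs_latitude")] = 1.0
        c[names.index("abs_latitude:kingdom[plant]")] = 1.0
        est = c @ fit.params.to_numpy()
        se = np.sqrt(c @ fit.cov_params.to_numpy() @ c)
        assert slopes.loc["plant", "slope"] == pytest.approx(est)
        assert slopes.loc["plant", "se"] == pytest.approx(se)

    def test_ci_contains_estimate(self, data):
        fit = fit_weighted_lmm(SPEC, data)
        slopes = extract_group_slopes(fit, "kingdom")
        assert ((slopes["lower"] <= slopes["slope"]) & (slopes["slope"] <= slopes["upper"])).all()

    def test_missing_interaction_errors(self, data):
        spec = ModelSpec("gdp", (("abs_latitude",), ("kingdom",)), ("species",), "weight", "ML")
        fit = fit_weighted_lmm(spec, data)
        with pytest.raises(ValueError):
            extract_group_slopes(fit, "kingdom")
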