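import numpy as np
import pandas as pd
import pytest

from phenoplast.lmm import (
    Design,
    ModelSpec,
    RandomTerm,
    backward_eliminate,
    build_design,
    expand_terms,
    extract_blups,
    fit_lmm,
    loglik_ratio_test,
    restricted_loglik,
    satterthwaite_df,
    standardize,
)


class TestStandardize:
    def test_simple_vector(self):
        z, mean, sd = standardize([1.0, 2.0, 3.0])
        assert mean == 2.0 and sd == 1.0  # sample (n-1) convention
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])

    def test_idempotent_and_moments(self, rng):
        x = rng.normal(3, 7, 100)
        z, _, _ = standardize(x)
        z2, m2, s2 = standardize(z)
        np.testing.assert_allclose(z, z2, atol=1e-12)
        assert abs(np.mean(z)) < 1e-12
        assert np.std(z, ddof=1) == pytest.approx(1.0)

    def test_constant_errors(self):
        with pytest.raises(ValueError):
            standardize([2.0, 2.0, 2.0])


class TestModelSpec:
    def test_star_expansion(self):
        assert expand_terms(["a*b", "c"]) == ["a", "b", "a:b", "c"]

    def test_compact_random_syntax(self):
        spec = ModelSpec("y", random=["g", "f:slope(x)"])
        assert spec.random[0] == RandomTerm("g")
        assert spec.random[1] == RandomTerm("f", "x")

    def test_drop_fixed(self):
        spec = ModelSpec("y", ["a", "b"])
        assert spec.drop_fixed("a").fixed == ("b",)
        with pytest.raises(ValueError):
            spec.drop_fixed("zzz")


class TestBuildDesign:
    def test_intercept_only(self, rng):
        df = pd.DataFrame({"y": rng.normal(size=10)})
        d = build_design(df, ModelSpec("y"))
        np.testing.assert_array_equal(d.X, np.ones((10, 1)))

    def test_indicator_block_one_per_row(self, rng):
        df = pd.DataFrame({"y": rng.normal(size=9), "g": [0, 1, 2] * 3})
        d = build_design(df, ModelSpec("y", random=[RandomTerm("g")]))
        Z = d.Z.toarray()
        assert Z.shape == (9, 3)
        np.testing.assert_array_equal(Z.sum(axis=1), np.ones(9))

    def test_slope_block_structure(self, rng):
        df = pd.DataFrame(
            {"y": rng.normal(size=12), "g": [0, 1, 2, 3] * 3, "d": rng.normal(size=12)}
        )
        dz = build_design(df, ModelSpec("y", random=[RandomTerm("g", "d")]))
        Z = dz.Z.toarray()
        assert Z.shape == (12, 8)
        for i in range(12):
            level = df["g"].iloc[i]
            expected = np.zeros(8)
            expected[2 * level] = 1.0
            expected[2 * level + 1] = df["d"].iloc[i]
            np.testing.assert_allclose(Z[i], expected)

    def test_rank_deficiency_names_terms(self, rng):
        df = pd.DataFrame({"y": rng.normal(size=20), "a": rng.normal(size=20)})
        df["b"] = 2 * df["a"]
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            build_design(df, ModelSpec("y", ["a", "b"]))

    def test_missing_rows_dropped_with_count(self, rng):
        df = pd.DataFrame({"y": rng.normal(size=10), "x": rng.normal(size=10)})
        df.loc[3, "x"] = np.nan
        d = build_design(df, ModelSpec("y", ["x"]))
        assert d.n == 9 and d.n_dropped == 1


class TestFitLMM:
    def test_no_random_terms_equals_ols(self, rng):
        n = 60
        df = pd.DataFrame({"x": rng.normal(size=n)})
        df["y"] = 2 + 1.5 * df.x + rng.normal(0, 1, n)
        fit = fit_lmm(df, ModelSpec("y", ["x"]))
        X = np.column_stack([np.ones(n), df.x])
        beta = np.linalg.lstsq(X, df.y, rcond=None)[0]
        rss = float(((df.y - X @ beta) ** 2).sum())
        np.testing.assert_allclose(fit.beta.to_numpy(), beta, atol=1e-10)
        assert fit.sigma2 == pytest.approx(rss / (n - 2), rel=1e-10)

    def test_balanced_oneway_matches_anova_estimators(self, balanced_oneway):
        df, q, m, var_between, var_within = balanced_oneway
        fit = fit_lmm(df, ModelSpec("y", random=[RandomTerm("g")]))
        assert fit.varcomps[0].var_intercept == pytest.approx(var_between, abs=1e-6)
        assert fit.sigma2 == pytest.approx(var_within, abs=1e-6)

    def test_zero_group_variance_hits_boundary(self, rng):
        n, q = 400, 10
        df = pd.DataFrame({"g": np.repeat(np.arange(q), n // q)})
        df["y"] = rng.normal(0, 1, n)  # no group structure at all
        fit = fit_lmm(df, ModelSpec("y", random=[RandomTerm("g")]))
        assert fit.varcomps[0].var_intercept <= 0.02
        # boundary flag fires when the component collapses to zero exactly
        if fit.varcomps[0].var_intercept == 0.0:
            assert fit.varcomps[0].boundary

    def test_reml_criterion_matches_dense_brute_force(self, crossed_slope_data, crossed_slope_spec):
        """The profiled q x q computation must agree with a direct dense
        evaluation of the REML criterion (determinant + quadratic form)."""
        fit = fit_lmm(crossed_slope_data, crossed_slope_spec)
        design = fit.design_
        Z = design.Z.toarray() if hasattr(design.Z, "toarray") else design.Z
        Lam = design.lambda_matrix(fit.theta_)
        Lam = Lam.toarray() if hasattr(Lam, "toarray") else Lam
        V0 = np.eye(design.n) + Z @ Lam @ Lam.T @ Z.T
        Vi = np.linalg.inv(V0)
        X, y = design.X, design.y
        XtVX = X.T @ Vi @ X
        beta = np.linalg.solve(XtVX, X.T @ Vi @ y)
        r = y - X @ beta
        r2 = float(r @ Vi @ r)
        npars = design.n - design.p
        sig2 = r2 / npars
        ll_dense = -0.5 * (
            np.linalg.slogdet(V0)[1]
            + np.linalg.slogdet(XtVX)[1]
            + npars * np.log(2 * np.pi * sig2)
            + npars
        )
        assert fit.loglik_reml == pytest.approx(ll_dense, abs=1e-8)

    def test_restricted_loglik_profile_consistency(self, crossed_slope_data, crossed_slope_spec):
        fit = fit_lmm(crossed_slope_data, crossed_slope_spec)
        ll = restricted_loglik(fit.design_, fit.theta_, fit.sigma2)
        assert ll == pytest.approx(fit.loglik_reml, abs=1e-8)

    def test_ml_loglik_monotone_in_nesting(self, crossed_slope_data):
        full = fit_lmm(
            crossed_slope_data,
            ModelSpec("y", ["x"], [RandomTerm("f1"), RandomTerm("f2", "x")], reml=False),
        )
        reduced = fit_lmm(
            crossed_slope_data,
            ModelSpec("y", ["x"], [RandomTerm("f1"), RandomTerm("f2")], reml=False),
        )
        assert full.loglik_ml >= reduced.loglik_ml - 1e-6

    def test_estimates_invariant_to_standardization(self, rng):
        n = 150
        df = pd.DataFrame({"g": rng.integers(0, 10, n), "x": rng.normal(50, 9, n)})
        df["y"] = 3 - 0.4 * df.x + rng.normal(0, 2, 10)[df.g] + rng.normal(0, 1, n)
        fit_raw = fit_lmm(df, ModelSpec("y", ["x"], [RandomTerm("g")], reml=False))
        z, mean, sd = standardize(df["x"])
        dfz = df.assign(x=z)
        fit_z = fit_lmm(dfz, ModelSpec("y", ["x"], [RandomTerm("g")], reml=False))
        assert fit_z.beta["x"] / sd == pytest.approx(fit_raw.beta["x"], rel=1e-6)
        # the ML likelihood is invariant under the affine reparameterization
        # (REML is not: its criterion shifts by the transform determinant)
        assert fit_z.loglik_ml == pytest.approx(fit_raw.loglik_ml, abs=1e-6)

    def test_too_few_levels_or_rows_error(self, rng):
        df = pd.DataFrame({"y": rng.normal(size=6), "g": [0] * 6})
        with pytest.raises(ValueError, match="levels"):
            fit_lmm(df, ModelSpec("y", random=[RandomTerm("g")]))


class TestLRT:
    def test_identical_models_give_zero(self, crossed_slope_data):
        spec = ModelSpec("y", ["x"], [RandomTerm("f1")], reml=False)
        a = fit_lmm(crossed_slope_data, spec)
        b = fit_lmm(crossed_slope_data, spec)
        res = loglik_ratio_test(a, b, "fixed")
        assert res.statistic == pytest.approx(0.0, abs=1e-8)
        assert res.p == 1.0

    def test_correlated_slope_adds_two_df(self, crossed_slope_data):
        full = fit_lmm(
            crossed_slope_data, ModelSpec("y", ["x"], [RandomTerm("f1"), RandomTerm("f2", "x")])
        )
        reduced = fit_lmm(
            crossed_slope_data, ModelSpec("y", ["x"], [RandomTerm("f1"), RandomTerm("f2")])
        )
        res = loglik_ratio_test(full, reduced, "random")
        assert res.df == 2
        assert res.statistic >= 0

    def test_non_nested_specs_rejected(self, crossed_slope_data):
        a = fit_lmm(crossed_slope_data, ModelSpec("y", ["x"], [RandomTerm("f1")]))
        b = fit_lmm(crossed_slope_data, ModelSpec("y", ["x"], [RandomTerm("f2")]))
        with pytest.raises(ValueError, match="nested"):
            loglik_ratio_test(a, b, "random")

    def test_random_scope_requires_same_fixed_effects(self, crossed_slope_data):
        a = fit_lmm(crossed_slope_data, ModelSpec("y", ["x"], [RandomTerm("f1")]))
        b = fit_lmm(crossed_slope_data, ModelSpec("y", [], [RandomTerm("f1")]))
        with pytest.raises(ValueError, match="fixed"):
            loglik_ratio_test(a, b, "random")

    def test_boundary_mixture_halves_small_p(self, crossed_slope_data):
        full = fit_lmm(crossed_slope_data, ModelSpec("y", ["x"], [RandomTerm("f1"), RandomTerm("f2")]))
        reduced = fit_lmm(crossed_slope_data, ModelSpec("y", ["x"], [RandomTerm("f2")]))
        naive = loglik_ratio_test(full, reduced, "random")
        mixed = loglik_ratio_test(full, reduced, "random", boundary_mixture=True)
        assert mixed.p <= naive.p


class TestSatterthwaite:
    def test_no_random_effects_reduces_to_residual_df(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=40)})
        df["y"] = 1 + df.x + rng.normal(size=40)
        fit = fit_lmm(df, ModelSpec("y", ["x"]))
        assert satterthwaite_df(fit, 1) == pytest.approx(38.0)

    def test_balanced_between_group_contrast_classical_df(self, rng):
        # a group-constant covariate in a balanced one-way design: the
        # classical denominator df is q - 2 (q group means, 2 fixed params)
        q, m = 10, 6
        g = np.repeat(np.arange(q), m)
        xg = rng.normal(0, 1, q)
        y = 5 + 2 * xg[g] + np.repeat(rng.normal(0, 2, q), m) + rng.normal(0, 1, q * m)
        df = pd.DataFrame({"y": y, "g": g, "x": xg[g]})
        fit = fit_lmm(df, ModelSpec("y", ["x"], [RandomTerm("g")]))
        assert satterthwaite_df(fit, 1) == pytest.approx(q - 2, rel=0.05)

    def test_unbalanced_design_within_naive_bounds(self, rng):
        sizes = rng.integers(2, 15, 12)
        g = np.repeat(np.arange(12), sizes)
        n = len(g)
        x = rng.normal(size=n)
        y = 1 + 0.5 * x + rng.normal(0, 1.5, 12)[g] + rng.normal(size=n)
        df = pd.DataFrame({"y": y, "g": g, "x": x})
        fit = fit_lmm(df, ModelSpec("y", ["x"], [RandomTerm("g")]))
        df_x = satterthwaite_df(fit, 1)
        assert 11 <= df_x <= n - 2 + 1e-6


class TestBackwardElimination:
    def test_strong_effects_retained_unchanged(self, rng):
        n = 400
        df = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        df["y"] = 1 + 2 * df.a - 3 * df.b + rng.normal(0, 1, n)
        fit, trace = backward_eliminate(df, ModelSpec("y", ["a", "b"], reml=False))
        assert set(fit.beta.index) == {"Intercept", "a", "b"}
        assert not trace["removed"].any() if len(trace) else True

    def test_marginality_protects_interaction_parents(self, rng):
        n = 500
        df = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        # strong interaction, weak main effect of a
        df["y"] = 1 + 0.01 * df.a + 1.0 * df.b + 2.0 * df.a * df.b + rng.normal(0, 1, n)
        fit, _ = backward_eliminate(df, ModelSpec("y", ["a*b"], reml=False))
        assert "a:b" in fit.beta.index
        assert "a" in fit.beta.index  # retained despite tiny own effect

    def test_noise_covariate_eliminated_at_alpha_rate(self, rng):
        kept = 0
        reps = 120
        for _ in range(reps):
            n = 120
            df = pd.DataFrame({"real": rng.normal(size=n), "noise": rng.normal(size=n)})
            df["y"] = 2 - 1.0 * df.real + rng.normal(0, 1, n)
            fit, _ = backward_eliminate(df, ModelSpec("y", ["real", "noise"], reml=False))
            kept += "noise" in fit.beta.index
        # noise should be retained in roughly alpha = 5% of replicates
        assert kept / reps <= 0.12


class TestBLUPs:
    def test_balanced_shrinkage_closed_form(self, balanced_oneway):
        df, q, m, _, _ = balanced_oneway
        fit = fit_lmm(df, ModelSpec("y", random=[RandomTerm("g")]))
        vg, s2 = fit.varcomps[0].var_intercept, fit.sigma2
        shrink = m * vg / (m * vg + s2)
        gm = df.groupby("g")["y"].mean()
        expected = shrink * (gm.to_numpy() - fit.beta["Intercept"])
        got = extract_blups(fit, "g")["intercept"].to_numpy()
        np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_single_observation_group_strongly_shrunk(self, rng):
        g = np.array([0] * 20 + [1] * 20 + [2])
        y = np.concatenate([rng.normal(0, 1, 20), rng.normal(0, 1, 20), [8.0]])
        df = pd.DataFrame({"y": y, "g": g})
        fit = fit_lmm(df, ModelSpec("y", random=[RandomTerm("g")]))
        blup = extract_blups(fit, "g").loc[2, "intercept"]
        raw_dev = 8.0 - fit.beta["Intercept"]
        assert abs(blup) < abs(raw_dev)

    def test_blups_average_near_zero(self, crossed_slope_data, crossed_slope_spec):
        fit = fit_lmm(crossed_slope_data, crossed_slope_spec)
        b = extract_blups(fit, "f1")["intercept"]
        assert abs(b.mean()) < 0.25 * b.std()

    def test_unknown_factor_errors(self, crossed_slope_data, crossed_slope_spec):
        fit = fit_lmm(crossed_slope_data, crossed_slope_spec)
        with pytest.raises(KeyError):
            extract_blups(fit, "nope")
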