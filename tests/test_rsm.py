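"""Response-surface fitting, ANOVA diagnostics, transforms, and optimum search."""

import numpy as np
import pytest
from scipy import stats

from rsmtune.doe import DesignSpec, FactorSpec, build_ccd
from rsmtune.rsm import (
    SingularDesignError,
    SurfaceModel,
    TransformSpec,
    anova,
    apply_transform,
    find_optimum,
    fit_quadratic,
    invert_transform,
    predict,
    scan_transform,
)
from rsmtune.workflow import reference_design_spec


def _toy_spec(k=2, n_center=3):
    return DesignSpec(
        numeric_factors=tuple(FactorSpec(f"x{i}", low=0.0, high=1.0) for i in range(k)),
        n_center=n_center,
    )


class TestTransform:
    def test_log_of_first_reference_response(self):
        assert apply_transform([0.0257], TransformSpec(0.0))[0] == pytest.approx(-3.66, abs=0.005)

    def test_identity(self):
        y = np.array([0.1, -2.0, 3.0])
        assert np.array_equal(apply_transform(y, TransformSpec(1.0)), y)

    @pytest.mark.parametrize("lam", [-1.0, 0.0, 0.5, 1.0])
    def test_round_trip(self, lam):
        y = np.array([0.02, 0.5, 1.7, 9.0])
        t = TransformSpec(lam)
        assert np.allclose(invert_transform(apply_transform(y, t), t), y, atol=1e-12)

    def test_nonpositive_response_names_run(self):
        with pytest.raises(ValueError, match="index 2"):
            apply_transform([1.0, 2.0, -0.5], TransformSpec(0.0))

    def test_invalid_lambda(self):
        with pytest.raises(ValueError):
            TransformSpec(0.25)


class TestFit:
    def test_constant_response_gives_intercept_only(self):
        design = build_ccd(_toy_spec()).with_responses(np.full(11, 3.5))
        model = fit_quadratic(design, TransformSpec(1.0))
        assert model.intercept == pytest.approx(3.5)
        assert np.allclose(model.coefficients[1:], 0.0, atol=1e-10)

    def test_exact_recovery_of_known_coefficients(self):
        """A noise-free response built from a chosen coefficient vector is
        recovered exactly by the least-squares fit."""
        design = build_ccd(reference_design_spec())
        probe = fit_quadratic(design.with_responses(np.ones(60)), TransformSpec(1.0))
        rng = np.random.default_rng(42)
        beta = rng.normal(0, 1, size=len(probe.terms))
        y = np.array(
            [
                sum(
                    b * np.prod([_coded_at(design, i, n) for n in term])
                    for term, b in zip(probe.terms, beta)
                )
                for i in range(len(design))
            ]
        )
        model = fit_quadratic(design.with_responses(y), TransformSpec(1.0))
        assert np.allclose(model.coefficients, beta, atol=1e-9)

    def test_statsmodels_agrees(self, reference_design, reference_surface):
        """Independent OLS route (statsmodels) reproduces our coefficient vector."""
        import statsmodels.api as sm

        from rsmtune.rsm import _coded_columns, _model_matrix

        cols = _coded_columns(reference_surface.factors, reference_design)
        X = _model_matrix(reference_surface.terms, cols, 60)
        z = np.log(reference_design.responses)
        fit = sm.OLS(z, X).fit()
        assert np.allclose(fit.params, reference_surface.coefficients, atol=1e-8)

    def test_singular_design_names_aliased_terms(self):
        # replicated factorial-only rows alias the squared terms (both
        # identically 1) with the intercept
        import pandas as pd

        from rsmtune.doe import DesignMatrix

        spec = _toy_spec(k=2, n_center=1)
        design = build_ccd(spec)
        fact = design.table["space_type"] == "factorial"
        table = pd.concat([design.table[fact]] * 2, ignore_index=True).assign(response=1.0)
        coded = pd.concat([design.coded[fact]] * 2, ignore_index=True)
        small = DesignMatrix(spec, table, coded)
        with pytest.raises(SingularDesignError, match=r"\^2"):
            fit_quadratic(small, TransformSpec(1.0))

    def test_center_predictions_split_by_sign_convention(self, reference_surface):
        """With the first algorithm level coded −1, the two center-point
        predictions are intercept ∓ the algorithm main effect."""
        m = reference_surface
        center = {"neurons": 0, "learning_rate": 0, "momentum": 0, "epochs": 0}
        lm = predict(m, {**center, "train_function": "trainlm"})
        gdm = predict(m, {**center, "train_function": "traingdm"})
        assert lm == pytest.approx(m.intercept - m.coef("train_function"), abs=1e-12)
        assert gdm == pytest.approx(m.intercept + m.coef("train_function"), abs=1e-12)

    def test_predict_contracts(self, reference_surface):
        center = {"neurons": 0, "learning_rate": 0, "momentum": 0, "epochs": 0}
        with pytest.raises(ValueError, match="trainbfg"):
            predict(reference_surface, {**center, "train_function": "trainbfg"})
        with pytest.warns(UserWarning, match="extrapolation"):
            predict(
                reference_surface,
                {**center, "neurons": 2.0, "train_function": "trainlm"},
            )


def _coded_at(design, i, name):
    if name in design.coded.columns:
        return design.coded[name].iloc[i]
    f = next(f for f in design.spec.categorical_factors if f.name == name)
    return -1.0 if design.table[name].iloc[i] == f.levels[0] else 1.0


class TestAnova:
    def test_ss_and_df_additivity(self, reference_anova):
        t = reference_anova
        assert t.model.ss + t.residual.ss == pytest.approx(t.cor_total.ss)
        assert t.lack_of_fit.ss + t.pure_error.ss == pytest.approx(t.residual.ss)
        assert t.model.df + t.residual.df == t.cor_total.df
        assert t.lack_of_fit.df + t.pure_error.df == t.residual.df
        assert t.predicted_r2 <= t.r2 and t.adjusted_r2 <= t.r2

    def test_fitted_values_and_residual_orthogonality(self, reference_design, reference_surface):
        from rsmtune.rsm import _coded_columns, _model_matrix

        cols = _coded_columns(reference_surface.factors, reference_design)
        X = _model_matrix(reference_surface.terms, cols, 60)
        z = np.log(reference_design.responses)
        resid = z - X @ reference_surface.coefficients
        # residuals orthogonal to every model column
        assert np.max(np.abs(X.T @ resid)) / len(z) < 1e-8

    def test_zero_residual_fit(self):
        design = build_ccd(_toy_spec())
        probe = fit_quadratic(design.with_responses(np.ones(len(design))), TransformSpec(1.0))
        beta = np.arange(1.0, len(probe.terms) + 1)
        y = np.array(
            [
                sum(
                    b * np.prod([_coded_at(design, i, n) for n in term])
                    for term, b in zip(probe.terms, beta)
                )
                for i in range(len(design))
            ]
        )
        fitted = design.with_responses(y)
        t = anova(fit_quadratic(fitted, TransformSpec(1.0)), fitted)
        assert t.r2 == pytest.approx(1.0)
        assert t.residual.ss == pytest.approx(0.0, abs=1e-16)

    def test_one_factor_f_equals_squared_t(self):
        """On a replicated two-level one-factor design, the factor's ANOVA F
        equals the squared pooled two-sample t statistic."""
        rng = np.random.default_rng(11)
        lo = rng.normal(1.0, 0.3, 6)
        hi = rng.normal(2.0, 0.3, 6)
        spec = DesignSpec(
            numeric_factors=(FactorSpec("x", low=0.0, high=1.0),), n_center=1
        )
        import pandas as pd

        from rsmtune.doe import DesignMatrix

        coded = np.repeat([-1.0, 1.0], 6)
        table = pd.DataFrame(
            {
                "run": np.arange(1, 13),
                "space_type": "factorial",
                "x": np.repeat([0.0, 1.0], 6),
                "response": np.concatenate([lo, hi]),
            }
        )
        design = DesignMatrix(spec, table, pd.DataFrame({"x": coded}))
        # linear-only model: drop the aliased quadratic by fitting k=1 with
        # two distinct levels -> use the linear+intercept sub-design via OLS
        model = SurfaceModel(
            factors=spec.factors,
            terms=[(), ("x",)],
            coefficients=np.linalg.lstsq(
                np.column_stack([np.ones(12), coded]), design.responses, rcond=None
            )[0],
            transform=TransformSpec(1.0),
        )
        t_table = anova(model, design)
        t_stat, _ = stats.ttest_ind(hi, lo)
        f_x = next(r.f for r in t_table.terms if r.source == "x")
        assert f_x == pytest.approx(t_stat ** 2, rel=1e-9)

    def test_partial_equals_sequential_for_orthogonal_terms(
        self, reference_design, reference_surface
    ):
        """Linear and interaction columns of the face-centered CCD are mutually
        orthogonal, so their partial and sequential SS agree; sequential SS sum
        to the model SS."""
        part = anova(reference_surface, reference_design, ss_type="partial")
        seq = anova(reference_surface, reference_design, ss_type="sequential")
        part_by = {r.source: r.ss for r in part.terms}
        seq_by = {r.source: r.ss for r in seq.terms}
        for label in part_by:
            if "^2" not in label:
                assert seq_by[label] == pytest.approx(part_by[label], rel=1e-8)
        assert sum(seq_by.values()) == pytest.approx(part.model.ss, rel=1e-10)

    def test_no_replicates_reports_undefined_lack_of_fit(self):
        design = build_ccd(_toy_spec(k=2, n_center=1)).with_responses(
            np.linspace(1.0, 2.0, 9)
        )
        t = anova(fit_quadratic(design, TransformSpec(1.0)), design)
        assert t.lack_of_fit is None and t.pure_error is None


class TestCoefficientSampling:
    def test_noise_spread_matches_ols_covariance(self, reference_design):
        """Over 200 noisy replicates of a known surface, the per-coefficient
        sampling standard deviation matches the theoretical OLS value."""
        from rsmtune.rsm import _coded_columns, _model_matrix

        design = reference_design
        probe = fit_quadratic(design.with_responses(np.ones(60)), TransformSpec(1.0))
        cols = _coded_columns(probe.factors, design)
        X = _model_matrix(probe.terms, cols, 60)
        rng = np.random.default_rng(2024)
        beta = rng.normal(0, 1, size=X.shape[1])
        sigma = 0.3
        estimates = np.empty((200, X.shape[1]))
        for r in range(200):
            y = X @ beta + rng.normal(0, sigma, size=60)
            m = fit_quadratic(design.with_responses(y), TransformSpec(1.0))
            estimates[r] = m.coefficients
        theory_sd = sigma * np.sqrt(np.diag(np.linalg.inv(X.T @ X)))
        emp_sd = estimates.std(axis=0, ddof=1)
        assert np.allclose(estimates.mean(axis=0), beta, atol=4 * theory_sd / np.sqrt(200) + 1e-12)
        assert np.all(emp_sd / theory_sd > 0.8) and np.all(emp_sd / theory_sd < 1.25)


class TestScanTransform:
    def test_log_generated_response_selects_log(self):
        design = build_ccd(reference_design_spec())
        probe = fit_quadratic(design.with_responses(np.ones(60)), TransformSpec(1.0))
        rng = np.random.default_rng(3)
        beta = rng.normal(0, 0.5, size=len(probe.terms))
        ln_y = np.array(
            [
                sum(
                    b * np.prod([_coded_at(design, i, n) for n in term])
                    for term, b in zip(probe.terms, beta)
                )
                for i in range(60)
            ]
        ) + rng.normal(0, 0.05, 60)
        best, table = scan_transform(design.with_responses(np.exp(ln_y)))
        assert best.lam == 0.0
        assert len(table) == 4


class TestFindOptimum:
    def _paraboloid(self):
        spec = _toy_spec(k=2)
        factors = spec.factors
        # yhat = (x0 - 0.2)^2 + (x1 + 0.4)^2 expanded in model terms
        terms = [(), ("x0",), ("x1",), ("x0", "x1"), ("x0", "x0"), ("x1", "x1")]
        coefs = np.array([0.2 ** 2 + 0.4 ** 2, -0.4, 0.8, 0.0, 1.0, 1.0])
        return SurfaceModel(factors, terms, coefs, TransformSpec(1.0))

    def test_analytic_minimum(self):
        best, _ = find_optimum(self._paraboloid(), "minimize")
        assert best["coded"]["x0"] == pytest.approx(0.2, abs=1e-4)
        assert best["coded"]["x1"] == pytest.approx(-0.4, abs=1e-4)
        assert best["predicted"] == pytest.approx(0.0, abs=1e-8)

    def test_maximize_is_minimize_of_negation(self):
        m = self._paraboloid()
        neg = SurfaceModel(m.factors, m.terms, -m.coefficients, m.transform)
        best_min, _ = find_optimum(m, "minimize")
        best_max, _ = find_optimum(neg, "maximize")
        assert best_min["coded"]["x0"] == pytest.approx(best_max["coded"]["x0"], abs=1e-6)
        assert best_min["predicted"] == pytest.approx(-best_max["predicted"], abs=1e-8)

    def test_reference_optimum_beats_center_point(self, reference_surface):
        """The located minimum predicts at least as low as the design-center
        configuration the study selected."""
        best, per_level = find_optimum(reference_surface, "minimize")
        center_lm = predict(
            reference_surface,
            {"neurons": 0, "learning_rate": 0, "momentum": 0, "epochs": 0,
             "train_function": "trainlm"},
        )
        assert best["predicted"] <= center_lm
        assert best["categorical"]["train_function"] == "trainlm"
        assert len(per_level) == 2
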