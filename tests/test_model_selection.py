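"""Response transform, predictor screening, GLM fitting and AICc ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

from vinemites.model_selection import (
    CandidateModel,
    DensityModelSelection,
    back_transform_response,
    collinearity_screen,
    design_matrix,
    enumerate_candidates,
    fit_gaussian_glm,
    rank_models,
    study_candidate_config,
    transform_response,
    vif,
)


class TestTransform:
    @pytest.mark.parametrize("y,expected", [(0.0, 0.0), (9.0, 1.0), (99.0, 2.0)])
    def test_log10_plus_one(self, y, expected):
        assert transform_response([y])[0] == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            transform_response([-0.1])

    @given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_and_monotone(self, ys):
        t = transform_response(ys)
        back = back_transform_response(t)
        assert np.allclose(back, ys, rtol=1e-12, atol=1e-9)
        order = np.argsort(ys)
        assert (np.diff(t[order]) >= -1e-15).all()


class TestCollinearityScreen:
    def test_independent_columns_not_excluded(self):
        rng = np.random.default_rng(42)
        df = pd.DataFrame({"a": rng.normal(size=1000), "b": rng.normal(size=1000)})
        pairs, constant = collinearity_screen(df)
        assert pairs == [] and constant == []

    def test_duplicate_column_excluded(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        pairs, _ = collinearity_screen(pd.DataFrame({"a": x, "b": x}))
        assert pairs == [("a", "b")]

    def test_negative_correlation_uses_absolute_value(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        pairs, _ = collinearity_screen(pd.DataFrame({"x": x, "y": -x}))
        assert pairs == [("x", "y")]

    def test_constant_column_flagged_not_correlated(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"a": rng.normal(size=30), "c": np.ones(30)})
        pairs, constant = collinearity_screen(df)
        assert constant == ["c"] and pairs == []

    def test_categorical_contrast_crossing_threshold(self):
        # management determines x exactly -> its indicator correlates 1 with x
        df = pd.DataFrame(
            {
                "management": ["organic", "integrated"] * 10,
                "x": [1.0, 0.0] * 10,
            }
        )
        pairs, _ = collinearity_screen(df)
        assert ("management", "x") in pairs


class TestVif:
    def test_orthogonal_predictors_unit_vif(self):
        n = 64
        t = np.arange(n)
        df = pd.DataFrame(
            {"a": np.cos(2 * np.pi * t / n), "b": np.sin(2 * np.pi * t / n)}
        )
        v = vif(df)
        assert np.allclose(v.to_numpy(), 1.0, atol=1e-10)

    def test_duplicated_predictor_infinite(self):
        x = np.random.default_rng(3).normal(size=40)
        v = vif(pd.DataFrame({"a": x, "b": x}))
        assert np.isinf(v).all()

    def test_matches_independent_least_squares_oracle(self):
        rng = np.random.default_rng(7)
        x1 = rng.normal(size=200)
        x2 = x1 + rng.normal(scale=0.3, size=200)
        x3 = rng.normal(size=200)
        df = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        v = vif(df)
        # independent oracle: aux regression via numpy polyfit-style lstsq
        X = np.column_stack([np.ones(200), x2, x3])
        beta, *_ = np.linalg.lstsq(X, x1, rcond=None)
        resid = x1 - X @ beta
        r2 = 1 - resid @ resid / ((x1 - x1.mean()) ** 2).sum()
        assert v["x1"] == pytest.approx(1 / (1 - r2), rel=1e-8)
        # and statsmodels' implementation agrees
        Xfull = np.column_stack([np.ones(200), x1, x2, x3])
        assert v["x1"] == pytest.approx(
            variance_inflation_factor(Xfull, 1), rel=1e-8
        )


class TestEnumeration:
    def test_minimal_pool(self):
        models = enumerate_candidates("y", ("date",), forced=("date",))
        labels = {m.label for m in models}
        assert labels == {"null model", "date"}

    def test_exclusion_filtered_pairs(self):
        models = enumerate_candidates(
            "y", ("date", "A", "B"), exclusions=[("A", "B")],
            max_extra_terms=2, forced=("date",),
        )
        terms = {m.terms for m in models}
        assert terms == {(), ("date",), ("date", "A"), ("date", "B")}

    def test_study_config_enumerates_42_models(self):
        cfg = study_candidate_config()
        models = enumerate_candidates(
            "phytoseiid", cfg["pool"], exclusions=cfg["exclusions"],
            max_extra_terms=cfg["max_extra_terms"], forced=cfg["forced"],
        )
        assert len(models) == 42

    def test_explicit_list_validated(self):
        with pytest.raises(ValueError, match="exclusion"):
            enumerate_candidates(
                "y", ("A", "B"), exclusions=[("A", "B")],
                explicit=[("A", "B")],
            )

    def test_explicit_list_used_verbatim(self):
        models = enumerate_candidates(
            "y", ("A", "B"), explicit=[("A",), ("A", "B")]
        )
        assert [m.terms for m in models] == [(), ("A",), ("A", "B")]


class TestGaussianGlm:
    def test_perfect_linear_fit(self):
        table = pd.DataFrame({"x": np.arange(10.0), "y": 2 * np.arange(10.0) + 1})
        fit = fit_gaussian_glm(CandidateModel("y", ("x",)), table)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.adj_r2 == pytest.approx(1.0)
        assert fit.params["x"] == pytest.approx(2.0)

    def test_intercept_only_closed_form_likelihood(self):
        """Gaussian ML on y=(0,0,1,1): sigma2=0.25, the closed-form log
        likelihood is -(n/2)(ln(2*pi*sigma2)+1) and AICc follows with k=2."""
        table = pd.DataFrame({"y": [0.0, 0.0, 1.0, 1.0]})
        fit = fit_gaussian_glm(CandidateModel("y", ()), table)
        n, k = 4, 2
        loglik = -(n / 2) * (math.log(2 * math.pi * 0.25) + 1)
        aic = -2 * loglik + 2 * k
        aicc = aic + 2 * k * (k + 1) / (n - k - 1)
        assert fit.loglik == pytest.approx(loglik, abs=1e-9)
        assert fit.aicc == pytest.approx(aicc, abs=1e-9)

    def test_aicc_exceeds_aic(self, analysis_table):
        fit = fit_gaussian_glm(
            CandidateModel("phytoseiid_log", ("date", "management")),
            analysis_table,
        )
        assert fit.aicc > fit.aic

    def test_coefficients_match_statsmodels(self, analysis_table):
        model = CandidateModel(
            "phytoseiid_log", ("date", "management", "pct_vineyards")
        )
        fit = fit_gaussian_glm(model, analysis_table)
        X = design_matrix(analysis_table, model.terms)
        sm_fit = sm.OLS(analysis_table["phytoseiid_log"], X).fit()
        assert np.allclose(fit.params, sm_fit.params, atol=1e-8)
        assert np.allclose(fit.bse, sm_fit.bse, atol=1e-8)
        # ML log likelihood identical to statsmodels' OLS llf
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-8)

    def test_rank_deficient_design_names_alias(self):
        table = pd.DataFrame(
            {"y": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
             "a": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
             "b": [2.0, 4.0, 6.0, 8.0, 10.0, 12.0]}
        )
        with pytest.raises(np.linalg.LinAlgError, match="aliased"):
            fit_gaussian_glm(CandidateModel("y", ("a", "b")), table)

    def test_too_few_rows_rejected(self):
        table = pd.DataFrame({"y": [1.0, 2.0, 3.0], "a": [1.0, 2.0, 4.0]})
        with pytest.raises(ValueError, match="too small"):
            fit_gaussian_glm(CandidateModel("y", ("a",)), table)


class TestRanking:
    def _fits(self, table, term_sets):
        return [
            fit_gaussian_glm(CandidateModel("y", terms), table)
            for terms in term_sets
        ]

    def test_single_model_selected(self):
        table = pd.DataFrame({"y": [0.1, 0.5, 0.3, 0.8, 0.2, 0.9]})
        ranking = rank_models(self._fits(table, [()]))
        assert ranking["delta_i"].iloc[0] == 0.0
        assert bool(ranking["selected"].iloc[0])

    def test_delta_threshold_boundary_arithmetic(self):
        """Δi arithmetic on a frozen AICc pair just outside the cut:
        (-45.87, -43.74) -> (0, 2.13), second model not selected."""

        class Stub:
            def __init__(self, aicc, terms):
                self.aicc = aicc
                self.k = len(terms) + 2
                self.loglik = 0.0
                self.adj_r2 = 0.44
                self.model = CandidateModel("y", terms)
                self.label = " + ".join(terms)
                self.delta_i = math.nan

        fits = [Stub(-45.87, ("a",)), Stub(-43.74, ("a", "b"))]
        ranking = rank_models(fits)
        assert list(ranking["delta_i"]) == pytest.approx([0.0, 2.13])
        assert list(ranking["selected"]) == [True, False]

    def test_order_invariance(self, analysis_table):
        cfg = study_candidate_config()
        models = enumerate_candidates(
            "phytoseiid_log", cfg["pool"], exclusions=cfg["exclusions"],
            max_extra_terms=2, forced=("date",),
        )
        fits_fwd = [fit_gaussian_glm(m, analysis_table) for m in models]
        fits_rev = [fit_gaussian_glm(m, analysis_table) for m in models[::-1]]
        r1 = rank_models(fits_fwd)
        r2 = rank_models(fits_rev)
        assert list(r1["model"]) == list(r2["model"])
        assert np.allclose(r1["aicc"], r2["aicc"])


class TestSelectionModel:
    def test_fit_returns_ranked_results(self, analysis_table):
        results = DensityModelSelection(analysis_table, "phytoseiid").fit()
        assert len(results.fits) == 42
        assert results.best.delta_i == 0.0
        assert results.ranking["aicc"].is_monotonic_increasing
        assert all(f.delta_i <= 2.0 for f in results.parsimonious)

    def test_selection_table_shape(self, analysis_table):
        results = DensityModelSelection(analysis_table, "tydeoid").fit()
        table = results.selection_table()
        assert list(table.columns) == ["model", "AICc", "delta_i", "adjusted_R2"]
        assert "null model" in set(table["model"])

    def test_summary_mentions_best_model(self, analysis_table):
        results = DensityModelSelection(analysis_table, "phytoseiid").fit()
        text = results.summary()
        assert "AICc model selection" in text
        assert results.best.label in text

    def test_scaling_constant_does_not_change_ranking(self, study, analysis_table):
        """The toxicity display scaling must not affect rank-based results:
        multiplying aaptlc by a constant leaves the AICc ranking identical."""
        rescaled = analysis_table.copy()
        rescaled["aaptlc"] = rescaled["aaptlc"] * 1e4
        r1 = DensityModelSelection(analysis_table, "phytoseiid").fit()
        r2 = DensityModelSelection(rescaled, "phytoseiid").fit()
        assert list(r1.ranking["model"]) == list(r2.ranking["model"])
        assert np.allclose(r1.ranking["aicc"], r2.ranking["aicc"], atol=1e-6)
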