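"""Association-model layer: binomial and NB2 GLMs, Nagelkerke R^2, screens."""

import warnings

import numpy as np
import pandas as pd
import pytest

from floranat import (
    ModelSpec,
    SpeciesTable,
    ValidationError,
    fit_binomial,
    fit_negbin,
    full_models,
    nagelkerke_r2,
    suitability_screen,
    univariate_screen,
)
from floranat.exceptions import ConvergenceError, SeparationError
from floranat.glm import GlmFit, _params_frame
from floranat.simulate import simulate_table
from floranat.table import standardize

from conftest import tiny_config


def _table_2x2():
    # x=0: 10/40 naturalized; x=1: 30/40 naturalized
    df = pd.DataFrame(
        {
            "species_id": [f"s{i}" for i in range(80)],
            "naturalized": [1] * 10 + [0] * 30 + [1] * 30 + [0] * 10,
            "x": [0] * 40 + [1] * 40,
        }
    )
    return SpeciesTable(df)


class TestBinomial:
    def test_2x2_closed_form_log_odds(self):
        fit = fit_binomial(_table_2x2(), ModelSpec("naturalized", ["x"], "binomial-logit"))
        assert fit.coef("x") == pytest.approx(np.log(9), abs=1e-6)
        assert fit.coef("const") == pytest.approx(np.log(1 / 3), abs=1e-6)
        assert fit.zvalue("x") == fit.coef("x") / fit.se("x")

    def test_constant_response_errors(self):
        df = _table_2x2().df.copy()
        df["naturalized"] = 0
        with pytest.raises(ConvergenceError, match="constant"):
            fit_binomial(SpeciesTable(df), ModelSpec("naturalized", ["x"], "binomial-logit"))

    def test_perfect_separation_names_predictor(self):
        df = _table_2x2().df.copy()
        df["naturalized"] = df["x"]
        with pytest.raises(SeparationError, match="x"):
            fit_binomial(SpeciesTable(df), ModelSpec("naturalized", ["x"], "binomial-logit"))

    def test_deterministic(self, tiny_table):
        tstd, _ = tiny_table
        spec = ModelSpec("naturalized", ["x"], "binomial-logit")
        a, b = fit_binomial(tstd, spec), fit_binomial(tstd, spec)
        pd.testing.assert_frame_equal(a.params, b.params)

    def test_standardized_predictor_unit_invariance(self, tiny_table):
        tstd, _ = tiny_table
        df = tstd.df.copy()
        df["x_rescaled"] = df["x"] * 1000.0
        rescaled, _ = standardize(SpeciesTable(df, dict(tstd.provenance)), ["x_rescaled"])
        a = fit_binomial(tstd, ModelSpec("naturalized", ["x"], "binomial-logit"))
        b = fit_binomial(rescaled, ModelSpec("naturalized", ["x_rescaled"], "binomial-logit"))
        assert a.coef("x") == pytest.approx(b.coef("x_rescaled"), rel=1e-9)


class TestNegbin:
    def test_parameter_recovery(self):
        table, _ = simulate_table(tiny_config(seed=21, n=5000, a=0.5), n_oracle=10_000)
        tstd, _ = standardize(table, ["x"], {"x": "log10"})
        fit = fit_negbin(tstd, ModelSpec("suitability", ["x"], "negbin-log"))
        # truth: intercept 5.0, slope 0.5, theta 1
        assert fit.coef("x") == pytest.approx(0.5, abs=3 * fit.se("x"))
        assert fit.theta == pytest.approx(1.0, abs=0.1)

    def test_equidispersed_constant_counts_poisson_limit(self):
        df = pd.DataFrame(
            {
                "species_id": list("abcd"),
                "naturalized": [0, 1, 0, 1],
                "suitability": [2, 2, 2, 2],
            }
        )
        with pytest.warns(UserWarning, match="Poisson limit"):
            fit = fit_negbin(SpeciesTable(df), ModelSpec("suitability", [], "negbin-log"))
        assert fit.poisson_limit
        assert np.exp(fit.coef("const")) == pytest.approx(2.0)

    def test_single_positive_count_warns_unstable(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "species_id": [f"s{i}" for i in range(60)],
                "naturalized": rng.integers(0, 2, 60),
                "x": rng.standard_normal(60),
                "suitability": [40] + [0] * 59,
            }
        )
        with pytest.warns(UserWarning, match="dispersion"):
            fit_negbin(SpeciesTable(df), ModelSpec("suitability", ["x"], "negbin-log"))

    def test_all_zero_counts_error(self):
        df = pd.DataFrame(
            {
                "species_id": list("abcdef"),
                "naturalized": [0, 1, 0, 1, 0, 1],
                "x": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "suitability": [0] * 6,
            }
        )
        with pytest.raises(ConvergenceError, match="zero"):
            fit_negbin(SpeciesTable(df), ModelSpec("suitability", ["x"], "negbin-log"))

    def test_aic_counts_dispersion_parameter(self, tiny_table):
        tstd, _ = tiny_table
        fit = fit_negbin(tstd, ModelSpec("suitability", ["x"], "negbin-log"))
        assert fit.aic == pytest.approx(2 * 3 - 2 * fit.loglik)


class TestNagelkerke:
    def test_null_fit_gives_zero(self):
        fit = GlmFit(
            spec=ModelSpec("naturalized", ["x"], "binomial-logit"),
            params=_params_frame(["const"], [0.0], [1.0]),
            loglik=-100.0,
            loglik_null=-100.0,
            n_used=200,
            converged=True,
        )
        assert nagelkerke_r2(fit) == 0.0

    def test_perfect_fit_gives_one(self):
        fit = GlmFit(
            spec=ModelSpec("naturalized", ["x"], "binomial-logit"),
            params=_params_frame(["const"], [0.0], [1.0]),
            loglik=0.0,
            loglik_null=-120.0,
            n_used=200,
            converged=True,
        )
        assert nagelkerke_r2(fit) == pytest.approx(1.0)

    def test_2x2_matches_direct_formula(self):
        fit = fit_binomial(_table_2x2(), ModelSpec("naturalized", ["x"], "binomial-logit"))
        # independent plug-in of the two closed-form likelihoods
        l1 = 40 * (0.25 * np.log(0.25) + 0.75 * np.log(0.75)) + 40 * (
            0.75 * np.log(0.75) + 0.25 * np.log(0.25)
        )
        l0 = 80 * 0.5 * np.log(0.5) * 2
        expected = (1 - np.exp(2 * (l0 - l1) / 80)) / (1 - np.exp(2 * l0 / 80))
        assert nagelkerke_r2(fit) == pytest.approx(expected, abs=1e-9)

    def test_worse_than_null_is_an_error(self):
        fit = GlmFit(
            spec=ModelSpec("naturalized", ["x"], "binomial-logit"),
            params=_params_frame(["const"], [0.0], [1.0]),
            loglik=-130.0,
            loglik_null=-120.0,
            n_used=200,
            converged=True,
        )
        with pytest.raises(ValidationError, match="below the null"):
            nagelkerke_r2(fit)

    def test_non_decreasing_under_nesting(self, study_table):
        _, tstd, _ = study_table
        small = fit_binomial(
            tstd, ModelSpec("naturalized", ["native_range_size"], "binomial-logit")
        )
        big = fit_binomial(
            tstd,
            ModelSpec("naturalized", ["native_range_size", "height"], "binomial-logit"),
        )
        assert big.loglik >= small.loglik - 1e-9
        assert nagelkerke_r2(big) >= nagelkerke_r2(small) - 1e-12


class TestScreens:
    def test_univariate_screen_covers_characteristics(self, study_table):
        _, tstd, _ = study_table
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits = univariate_screen(tstd)
        assert "suitability" in fits
        assert "native_range_size" in fits
        for name, fit in fits.items():
            assert list(fit.params.index) == ["const", name]

    def test_single_signal_detected(self):
        table, _ = simulate_table(
            tiny_config(seed=5, n=5000, a=0.5, b=0.6), n_oracle=10_000
        )
        rng = np.random.default_rng(0)
        df = table.df.copy()
        df["noise"] = rng.standard_normal(len(df))
        tstd, _ = standardize(SpeciesTable(df), ["x", "noise"], {"x": "log10"})
        fits = univariate_screen(tstd, characteristics=["x", "noise"])
        assert abs(fits["x"].zvalue("x")) > 2
        assert abs(fits["noise"].zvalue("noise")) < 2

    def test_rare_dummy_skipped_with_warning(self, study_table):
        raw, _, _ = study_table
        df = raw.df.copy()
        df["gf_parasite"] = 0
        df.loc[:2, "gf_parasite"] = 1
        with pytest.warns(UserWarning, match="gf_parasite"):
            fits = univariate_screen(
                SpeciesTable(df), characteristics=["gf_parasite", "origin_europe"]
            )
        assert "gf_parasite" not in fits
        assert "origin_europe" in fits

    def test_suitability_screen_recovers_sign(self, tiny_table):
        tstd, _ = tiny_table
        fits = suitability_screen(tstd, characteristics=["x"])
        assert fits["x"].coef("x") > 0
        assert fits["x"].pvalue("x") < 0.01

    def test_suitability_screen_constant_counts_error(self):
        df = pd.DataFrame(
            {
                "species_id": [f"s{i}" for i in range(40)],
                "naturalized": [0, 1] * 20,
                "x": np.linspace(-2, 2, 40),
                "suitability": [7] * 40,
            }
        )
        with pytest.raises(ValidationError, match="constant"):
            suitability_screen(SpeciesTable(df), characteristics=["x"])


class TestFullModels:
    def test_suitability_improves_fit_when_it_matters(self, study_table):
        _, tstd, _ = study_table
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = full_models(tstd)
        assert full.delta_aic > 0  # data were generated with a suitability effect
        assert full.delta_r2 > 0
        assert full.with_suitability.coef("suitability") > 0
        assert full.with_suitability.n_used == full.without_suitability.n_used

    def test_fits_are_identical_across_calls(self, study_table):
        _, tstd, _ = study_table
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = full_models(tstd)
            b = full_models(tstd)
        pd.testing.assert_frame_equal(
            a.with_suitability.params, b.with_suitability.params
        )

    def test_rank_deficiency_reported(self, tiny_table):
        tstd, _ = tiny_table
        df = tstd.df.copy()
        df["x_copy"] = df["x"]
        with pytest.raises(ValidationError, match="x_copy"):
            full_models(SpeciesTable(df, dict(tstd.provenance)), predictors=["x", "x_copy"])
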