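"""Natural-effect decomposition: contrasts, composition, bootstrap, gate."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit
from sklearn.base import clone

from floranat import (
    CountMediation,
    ExposureContrast,
    MediationModels,
    ModelSpec,
    ValidationError,
    bootstrap,
    expected_outcome,
    exposure_contrast,
    mediator_law,
    point_effects,
    select_candidates,
)
from floranat.glm import GlmFit, _params_frame


def _mediator_fit(a0, a1, theta):
    return GlmFit(
        spec=ModelSpec("suitability", ["x"], "negbin-log"),
        params=_params_frame(["const", "x"], [a0, a1], [0.1, 0.1]),
        loglik=-10.0,
        loglik_null=-12.0,
        n_used=100,
        converged=True,
        theta=theta,
        poisson_limit=np.isinf(theta),
    )


def _outcome_fit(g0, gx, gm):
    return GlmFit(
        spec=ModelSpec(
            "naturalized", ["x", "suitability_z"], "binomial-logit",
            include_suitability=True,
        ),
        params=_params_frame(["const", "x", "suitability_z"], [g0, gx, gm], [0.1] * 3),
        loglik=-10.0,
        loglik_null=-12.0,
        n_used=100,
        converged=True,
    )


def _models(a0=3.0, a1=0.5, theta=1.5, g0=-0.5, gx=0.4, gm=0.8, mean=25.0, sd=30.0):
    return MediationModels(
        outcome_fit=_outcome_fit(g0, gx, gm),
        mediator_fit=_mediator_fit(a0, a1, theta),
        std_params=(mean, sd),
    )


CONTRAST = ExposureContrast("x", "continuous", -1.2, 1.3)


class TestExposureContrast:
    def test_equally_spaced_grid_percentiles(self):
        values = np.linspace(-2, 2, 101)
        c = exposure_contrast(values, "x")
        # rank 1 + (n-1)p lands exactly on grid points -1.6 and 1.6
        assert (c.x0, c.x1) == (pytest.approx(-1.6), pytest.approx(1.6))
        assert c.kind == "continuous"

    def test_dummy_contrast(self):
        c = exposure_contrast(np.array([0, 1] * 30), "origin_europe")
        assert (c.kind, c.x0, c.x1) == ("dummy", 0.0, 1.0)

    def test_single_level_dummy_errors(self):
        with pytest.raises(ValidationError, match="single occupied level"):
            exposure_contrast(np.zeros(50), "origin_pacific")

    def test_too_few_values_errors(self):
        with pytest.raises(ValidationError, match=">= 10"):
            exposure_contrast(np.array([0.1, 0.5, 2.0]), "x")

    def test_degenerate_spread_errors(self):
        vals = np.concatenate([np.full(50, 1.0), [0.0, 2.0]])
        with pytest.raises(ValidationError, match="degenerate"):
            exposure_contrast(vals, "x")


class TestMediatorLaw:
    @pytest.mark.parametrize("mu,theta", [(2.0, 0.5), (148.0, 1.0), (30.0, 8.0)])
    def test_truncated_pmf_matches_scipy(self, mu, theta):
        from scipy.stats import nbinom

        from floranat.mediation import _truncated_pmf

        support, pmf = _truncated_pmf(mu, theta, 1e-8)
        ref = nbinom.pmf(support, theta, theta / (theta + mu))
        np.testing.assert_allclose(pmf * ref.sum(), ref, rtol=1e-10)
        assert nbinom.sf(support[-1], theta, theta / (theta + mu)) <= 1e-8

    def test_masses_sum_to_one(self):
        support, pmf = mediator_law(_mediator_fit(3.0, 0.5, 1.5), x=0.7)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
        assert support[0] == 0

    def test_poisson_limit_pmf_at_zero(self):
        fit = _mediator_fit(np.log(2.0), 0.0, np.inf)
        support, pmf = mediator_law(fit, x=0.0)
        assert pmf[0] == pytest.approx(np.exp(-2.0), rel=1e-7)

    def test_large_theta_approaches_poisson(self):
        _, pmf_nb = mediator_law(_mediator_fit(np.log(2.0), 0.0, 1e6), x=0.0)
        assert pmf_nb[0] == pytest.approx(np.exp(-2.0), rel=1e-4)

    def test_mean_monotone_in_exposure_for_positive_slope(self):
        fit = _mediator_fit(3.0, 0.5, 2.0)
        means = []
        for x in (-1.0, 0.0, 1.0):
            support, pmf = mediator_law(fit, x)
            means.append(float(support @ pmf))
        assert means[0] < means[1] < means[2]

    def test_invalid_theta_errors(self):
        with pytest.raises(ValidationError, match="theta"):
            mediator_law(_mediator_fit(3.0, 0.5, -1.0), x=0.0)


class TestExpectedOutcome:
    def test_blocked_mediator_path(self):
        models = _models(gm=0.0)
        p_a = expected_outcome(models, x_y=0.5, x_m=-1.0)
        p_b = expected_outcome(models, x_y=0.5, x_m=1.0)
        assert p_a == pytest.approx(p_b, abs=1e-12)
        assert p_a == pytest.approx(expit(-0.5 + 0.4 * 0.5), abs=1e-12)

    def test_blocked_exposure_to_mediator_path(self):
        models = _models(a1=0.0)
        p_a = expected_outcome(models, x_y=0.5, x_m=-2.0)
        p_b = expected_outcome(models, x_y=0.5, x_m=2.0)
        assert p_a == pytest.approx(p_b, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_sampling_oracle(self, seed):
        rng = np.random.default_rng(seed)
        models = _models(
            a0=rng.uniform(1, 4),
            a1=rng.uniform(-0.6, 0.6),
            theta=rng.uniform(0.5, 4),
            g0=rng.uniform(-1, 1),
            gx=rng.uniform(-0.8, 0.8),
            gm=rng.uniform(-1, 1),
            mean=rng.uniform(5, 60),
            sd=rng.uniform(5, 60),
        )
        x_y, x_m = rng.uniform(-1.5, 1.5, 2)
        exact = expected_outcome(models, x_y, x_m)
        n = 400_000
        core_mu = np.exp(
            models.mediator_fit.coef("const") + models.mediator_fit.coef("x") * x_m
        )
        theta = models.mediator_fit.theta
        m = rng.poisson(core_mu * rng.gamma(theta, 1 / theta, n))
        s = (m - models.std_params[0]) / models.std_params[1]
        draws = expit(
            models.outcome_fit.coef("const")
            + models.outcome_fit.coef("x") * x_y
            + models.outcome_fit.coef("suitability_z") * s
        )
        se = draws.std(ddof=1) / np.sqrt(n)
        assert exact == pytest.approx(float(draws.mean()), abs=3 * se)


class TestPointEffects:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        a0=st.floats(0.5, 4.0),
        a1=st.floats(-0.7, 0.7),
        theta=st.floats(0.4, 5.0),
        g0=st.floats(-1.5, 1.5),
        gx=st.floats(-1.0, 1.0),
        gm=st.floats(-1.5, 1.5),
    )
    def test_additivity_exact(self, a0, a1, theta, g0, gx, gm):
        eff = point_effects(_models(a0, a1, theta, g0, gx, gm), CONTRAST)
        assert eff.total == pytest.approx(eff.indirect + eff.direct, abs=1e-15)

    def test_zero_mediator_coefficient_kills_indirect(self):
        eff = point_effects(_models(gm=0.0), CONTRAST)
        assert eff.indirect == pytest.approx(0.0, abs=1e-15)
        assert abs(eff.direct) > 1e-3

    def test_zero_mediator_slope_kills_indirect(self):
        eff = point_effects(_models(a1=0.0), CONTRAST)
        assert eff.indirect == 0.0  # identical laws at x0 and x1: exact

    def test_zero_exposure_coefficient_kills_direct(self):
        eff = point_effects(_models(gx=0.0), CONTRAST)
        assert eff.direct == 0.0  # same law, same outcome exposure: exact
        assert abs(eff.indirect) > 1e-3

    def test_sign_propagation(self):
        # gm > 0 and a1 > 0 with x1 > x0: indirect must be positive
        assert point_effects(_models(a1=0.5, gm=0.8), CONTRAST).indirect > 0
        assert point_effects(_models(a1=-0.5, gm=0.8), CONTRAST).indirect < 0
        assert point_effects(_models(a1=0.5, gm=-0.8), CONTRAST).indirect < 0


class TestBootstrap:
    def test_seeded_determinism(self, tiny_table):
        tstd, _ = tiny_table
        a = bootstrap(tstd, "x", n_boot=200, seed=42)
        b = bootstrap(tstd, "x", n_boot=200, seed=42)
        assert a.ci_indirect == b.ci_indirect
        assert a.ci_direct == b.ci_direct
        c = bootstrap(tstd, "x", n_boot=200, seed=43)
        assert a.ci_indirect != c.ci_indirect

    def test_strong_mediated_path_detected(self, tiny_table):
        tstd, _ = tiny_table
        res = bootstrap(tstd, "x", n_boot=300, seed=1)
        assert res.significant_indirect
        assert res.ci_indirect[0] > 0
        assert res.proportion_mediated == pytest.approx(
            res.indirect / res.total, abs=1e-12
        )

    def test_n_boot_floor_enforced(self, tiny_table):
        tstd, _ = tiny_table
        with pytest.raises(ValidationError, match="200"):
            bootstrap(tstd, "x", n_boot=50, seed=0)

    def test_estimator_is_sklearn_cloneable(self, tiny_table):
        tstd, _ = tiny_table
        est = CountMediation(exposure="x", n_boot=0, random_state=9)
        est2 = clone(est)
        assert est2.get_params() == est.get_params()
        est2.fit(tstd.df[["x", "suitability"]], tstd.df["naturalized"])
        assert est2.total_ == pytest.approx(est2.indirect_ + est2.direct_, abs=1e-15)


class TestCandidateGate:
    @staticmethod
    def _fit_with_p(name, p):
        return GlmFit(
            spec=ModelSpec("naturalized", [name], "binomial-logit"),
            params=pd.DataFrame(
                {"estimate": [0.0, 1.0], "se": [1.0, 1.0], "z": [0.0, 1.0], "p": [1.0, p]},
                index=["const", name],
            ),
            loglik=-10.0,
            loglik_null=-11.0,
            n_used=100,
            converged=True,
        )

    def test_requires_significance_on_both_screens(self):
        screen_y = {
            "a": self._fit_with_p("a", 0.001),
            "b": self._fit_with_p("b", 0.001),
            "c": self._fit_with_p("c", 0.50),
        }
        screen_m = {
            "a": self._fit_with_p("a", 0.01),
            "b": self._fit_with_p("b", 0.30),
            "c": self._fit_with_p("c", 0.001),
        }
        assert select_candidates(screen_y, screen_m, alpha=0.05) == ["a"]

    def test_suitability_itself_excluded(self):
        screens = {
            "suitability": self._fit_with_p("suitability", 1e-9),
            "a": self._fit_with_p("a", 0.001),
        }
        assert select_candidates(screens, screens, alpha=0.05) == ["a"]

    def test_empty_gate_warns(self):
        screen = {"a": self._fit_with_p("a", 0.9)}
        with pytest.warns(UserWarning, match="gate"):
            assert select_candidates(screen, screen) == []
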