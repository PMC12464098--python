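"""Causal mediation with a negative-binomial count mediator and a binary
outcome, on the risk-difference scale.

The estimand follows the counterfactual composition of two fitted models,

* mediator:  M | X = x  ~  NB2(mu(x) = exp(a0 + a1 x), theta),
* outcome:   P(Y = 1 | X = x, M = m) = logistic(g0 + gX x + gM s(m)),

where ``s(m)`` standardizes the raw count with the full-sample mean/sd
(continuous variables enter all models as z-scores). With
``p(x_y, x_m) = E_{M ~ law(x_m)}[ P(Y=1 | x_y, M) ]`` — evaluated by
deterministic truncated-pmf summation, not Monte Carlo — the natural
effects for an exposure contrast (x0, x1) telescope exactly:

* indirect (NIE)  = p(x1, x1) - p(x1, x0)   (mediator law shifts, exposure held at x1),
* direct   (NDE)  = p(x1, x0) - p(x0, x0)   (exposure moves, mediator law held at x0),
* total           = p(x1, x1) - p(x0, x0) = indirect + direct.

Continuous exposures are contrasted at their 10th vs 90th sample
percentiles; dummies at absence (0) vs presence (1). Inference is by
nonparametric bootstrap: rows are resampled, both models refitted (the
mediator standardization re-estimated per replicate), and percentile CIs
taken over the replicate effects with the contrast held fixed at its
full-sample value, since the estimand is defined on the study sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln
from sklearn.base import BaseEstimator

from . import _fastglm
from .exceptions import ConvergenceError, ValidationError
from .glm import GlmFit, ModelSpec, _params_frame
from .table import SpeciesTable

MAX_SUPPORT = 10_000_000  # truncation guard: beyond this theta is pathological


@dataclass
class ExposureContrast:
    """The (x0, x1) pair an effect compares: 10th vs 90th percentile for a
    continuous exposure, absence vs presence for a dummy."""

    x_name: str
    kind: str  # "continuous" | "dummy"
    x0: float
    x1: float

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "dummy"):
            raise ValidationError(f"unknown contrast kind {self.kind!r}")
        if self.kind == "dummy" and (self.x0, self.x1) != (0.0, 1.0):
            raise ValidationError("dummy contrast must be (0, 1)")
        if self.kind == "continuous" and not self.x0 < self.x1:
            raise ValidationError(
                f"degenerate contrast for {self.x_name!r}: x0 = {self.x0} >= x1 = {self.x1}"
            )


@dataclass
class MediationModels:
    """The fitted outcome and mediator models plus the mediator
    standardization they share (same complete-case rows underlie both)."""

    outcome_fit: GlmFit
    mediator_fit: GlmFit
    std_params: tuple[float, float]  # (mean, sd) of the raw mediator count

    def __post_init__(self) -> None:
        if not (self.outcome_fit.converged and self.mediator_fit.converged):
            raise ValidationError("mediation requires converged component fits")
        if self.std_params[1] <= 0:
            raise ValidationError("mediator sd must be positive")


class PointEffects(NamedTuple):
    indirect: float
    direct: float
    total: float


@dataclass
class MediationResult:
    contrast: ExposureContrast
    indirect: float
    direct: float
    total: float
    proportion_mediated: float
    ci_indirect: tuple[float, float]
    ci_direct: tuple[float, float]
    n_boot: int
    seed: int
    significant_indirect: bool
    significant_direct: bool
    n_dropped: int = 0
    models: MediationModels | None = None
    boot_indirect: np.ndarray | None = field(default=None, repr=False)
    boot_direct: np.ndarray | None = field(default=None, repr=False)


def exposure_contrast(
    table: SpeciesTable | pd.Series | np.ndarray,
    x_name: str,
    percentiles: tuple[float, float] = (10.0, 90.0),
) -> ExposureContrast:
    """Build the exposure contrast from observed values.

    Continuous: linear-interpolation percentiles (rank 1 + (n-1)p) of the
    (already standardized) variable. Dummy: (0, 1).
    """
    if isinstance(table, SpeciesTable):
        values = table.df[x_name]
    else:
        values = pd.Series(np.asarray(table), name=x_name)
    vals = pd.to_numeric(values, errors="coerce").dropna().to_numpy(dtype=float)
    uniq = np.unique(vals)
    if set(uniq) <= {0.0, 1.0}:
        if len(uniq) < 2:
            raise ValidationError(f"dummy {x_name!r} has a single occupied level")
        return ExposureContrast(x_name=x_name, kind="dummy", x0=0.0, x1=1.0)
    if len(vals) < 10:
        raise ValidationError(
            f"{x_name!r} has {len(vals)} non-missing values; need >= 10"
        )
    lo, hi = np.percentile(vals, list(percentiles), method="linear")
    if not lo < hi:
        raise ValidationError(f"degenerate spread for {x_name!r}: both percentiles {lo}")
    return ExposureContrast(x_name=x_name, kind="continuous", x0=float(lo), x1=float(hi))


class _Core(NamedTuple):
    """Scalar parameters of a fitted bivariate mediation pair; everything
    the effect computation needs, free of any container overhead."""

    a0: float  # mediator intercept (log scale)
    a1: float  # mediator slope
    theta: float
    g0: float  # outcome intercept (logit scale)
    gx: float  # outcome exposure slope
    gm: float  # outcome slope of the standardized mediator
    med_mean: float
    med_sd: float


def _truncated_pmf(
    mu: float, theta: float, tail_mass: float
) -> tuple[np.ndarray, np.ndarray]:
    """NB2 (or Poisson-limit) pmf truncated at the smallest support with
    cumulative mass >= 1 - tail_mass, renormalized."""
    if np.isinf(theta):
        bound = int(mu + 12.0 * np.sqrt(mu) + 30.0)
    else:
        q = mu / (theta + mu)
        b_norm = mu + 20.0 * np.sqrt(mu + mu * mu / theta) + 30.0
        # geometric-type tail bound, generous for small theta
        b_geom = 2.0 * np.log(tail_mass) / np.log(q) if 0.0 < q < 1.0 else 0.0
        bound = int(max(b_norm, b_geom))
    for _ in range(30):
        if bound > MAX_SUPPORT:
            raise ValidationError(
                f"truncation bound {bound} exceeds {MAX_SUPPORT}; "
                f"pathological dispersion theta = {theta:.3g}"
            )
        k = np.arange(bound + 1, dtype=float)
        if np.isinf(theta):
            logpmf = k * np.log(mu) - mu - gammaln(k + 1.0)
        else:
            logpmf = (
                gammaln(k + theta)
                - gammaln(theta)
                - gammaln(k + 1.0)
                + theta * np.log(theta / (theta + mu))
                + k * np.log(mu / (theta + mu))
            )
        pmf = np.exp(logpmf)
        cum = np.cumsum(pmf)
        if cum[-1] >= 1.0 - tail_mass:
            cut = int(np.searchsorted(cum, 1.0 - tail_mass))
            support = np.arange(cut + 1)
            p = pmf[: cut + 1]
            return support, p / p.sum()
        bound *= 2
    raise ValidationError("mediator pmf truncation failed to reach target mass")


def _expected_on_law(
    core: _Core, x_y: float, support: np.ndarray, pmf: np.ndarray
) -> float:
    s = (support - core.med_mean) / core.med_sd
    return float(np.sum(pmf * expit(core.g0 + core.gx * x_y + core.gm * s)))


def _point_core(core: _Core, contrast: ExposureContrast, tail_mass: float) -> PointEffects:
    law1 = _truncated_pmf(float(np.exp(core.a0 + core.a1 * contrast.x1)), core.theta, tail_mass)
    law0 = _truncated_pmf(float(np.exp(core.a0 + core.a1 * contrast.x0)), core.theta, tail_mass)
    p11 = _expected_on_law(core, contrast.x1, *law1)
    p10 = _expected_on_law(core, contrast.x1, *law0)
    p00 = _expected_on_law(core, contrast.x0, *law0)
    return PointEffects(indirect=p11 - p10, direct=p10 - p00, total=p11 - p00)


def _core_from_models(models: MediationModels) -> _Core:
    med, out = models.mediator_fit, models.outcome_fit
    med_terms = [t for t in med.params.index if t != "const"]
    out_terms = list(out.params.index)
    gm_term = out_terms[-1]  # mediator term is last by construction
    x_terms = [t for t in out_terms if t not in ("const", gm_term)]
    return _Core(
        a0=med.coef("const"),
        a1=med.coef(med_terms[0]) if med_terms else 0.0,
        theta=float(med.theta),
        g0=out.coef("const"),
        gx=out.coef(x_terms[0]) if x_terms else 0.0,
        gm=out.coef(gm_term),
        med_mean=models.std_params[0],
        med_sd=models.std_params[1],
    )


def mediator_law(
    mediator_fit: GlmFit, x: float, tail_mass: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """The counterfactual mediator distribution at exposure ``x``: NB2 pmf
    with mean exp(a0 + a1 x) and the fitted dispersion, truncated at the
    smallest support covering mass 1 - tail_mass and renormalized.

    Returns ``(support, pmf)`` with the pmf summing to 1.
    """
    if not np.isfinite(x):
        raise ValidationError("exposure value must be finite")
    theta = mediator_fit.theta
    if theta is None or theta <= 0:
        raise ValidationError(f"invalid dispersion theta = {theta}")
    terms = list(mediator_fit.params.index)
    a0 = mediator_fit.coef("const")
    slope_terms = [t for t in terms if t != "const"]
    a1 = mediator_fit.coef(slope_terms[0]) if slope_terms else 0.0
    mu = float(np.exp(a0 + a1 * x))
    return _truncated_pmf(mu, theta, tail_mass)


def expected_outcome(
    models: MediationModels, x_y: float, x_m: float, tail_mass: float = 1e-8
) -> float:
    """The composed counterfactual mean E[Y(x_y, M(x_m))]: the outcome
    probability at exposure ``x_y`` averaged over the mediator law at
    exposure ``x_m``. Deterministic truncated summation."""
    core = _core_from_models(models)
    law = _truncated_pmf(float(np.exp(core.a0 + core.a1 * x_m)), core.theta, tail_mass)
    return _expected_on_law(core, x_y, *law)


def point_effects(
    models: MediationModels, contrast: ExposureContrast, tail_mass: float = 1e-8
) -> PointEffects:
    """Natural indirect, direct and total effects on the risk-difference
    scale; total = indirect + direct holds exactly by construction."""
    return _point_core(_core_from_models(models), contrast, tail_mass)


def _fit_raw(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    tol: float,
    max_iter: int,
    starts: tuple[np.ndarray, float, np.ndarray] | None = None,
) -> tuple[_fastglm.FastFit, _fastglm.FastFit, float, float]:
    """Fit mediator (NB2) and outcome (logit, standardized mediator) on the
    same rows using the fast Newton fitters. ``starts`` warm-starts
    bootstrap replicates from the full-sample estimates."""
    n = len(y)
    med_b0, med_t0, out_b0 = starts if starts is not None else (None, None, None)
    Xm = np.column_stack([np.ones(n), x])
    med = _fastglm.fit_negbin(Xm, m, tol=tol, max_iter=max_iter, beta0=med_b0, theta0=med_t0)
    mean = float(np.mean(m))
    sd = float(np.std(m, ddof=1))
    if sd <= 0:
        raise ValidationError("mediator is constant; cannot standardize")
    s = (m - mean) / sd
    Xy = np.column_stack([np.ones(n), x, s])
    out = _fastglm.fit_logit(Xy, y, tol=tol, max_iter=max_iter, beta0=out_b0)
    return med, out, mean, sd


def _core_from_raw(
    med: _fastglm.FastFit, out: _fastglm.FastFit, mean: float, sd: float
) -> _Core:
    return _Core(
        a0=float(med.beta[0]),
        a1=float(med.beta[1]) if len(med.beta) > 1 else 0.0,
        theta=float(med.theta),
        g0=float(out.beta[0]),
        gx=float(out.beta[1]),
        gm=float(out.beta[2]),
        med_mean=mean,
        med_sd=sd,
    )


def _fit_models(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    x_name: str,
    tol: float,
    max_iter: int,
    starts: tuple[np.ndarray, float, np.ndarray] | None = None,
) -> MediationModels:
    """Full reporting variant of :func:`_fit_raw`: wraps the fits in
    :class:`GlmFit` containers."""
    med, out, mean, sd = _fit_raw(x, m, y, tol, max_iter, starts)
    n = len(y)

    med_fit = GlmFit(
        spec=ModelSpec(response="suitability", predictors=[x_name], family="negbin-log"),
        params=_params_frame(["const", x_name], med.beta, med.se),
        loglik=med.llf,
        loglik_null=med.llnull,
        n_used=n,
        converged=med.converged,
        theta=med.theta,
        theta_se=med.theta_se,
        poisson_limit=med.poisson_limit,
    )
    out_fit = GlmFit(
        spec=ModelSpec(
            response="naturalized",
            predictors=[x_name, "suitability_z"],
            family="binomial-logit",
            include_suitability=True,
        ),
        params=_params_frame(["const", x_name, "suitability_z"], out.beta, out.se),
        loglik=out.llf,
        loglik_null=out.llnull,
        n_used=n,
        converged=out.converged,
    )
    return MediationModels(outcome_fit=out_fit, mediator_fit=med_fit, std_params=(mean, sd))


class CountMediation(BaseEstimator):
    """Natural-effect decomposition of one exposure's effect on a binary
    outcome through a count mediator (scikit-learn estimator shape).

    Parameters
    ----------
    exposure : str
        Column of ``X`` holding the exposure (continuous exposures should
        already be standardized; dummies are 0/1).
    mediator : str
        Column of ``X`` holding the raw mediator count.
    percentiles : (float, float)
        Exposure percentiles defining the contrast for continuous
        exposures (default 10/90).
    n_boot : int
        Bootstrap replicates for percentile CIs; 0 disables inference.
    alpha : float
        1 - confidence level of the CIs.
    tail_mass : float
        Truncation mass of the mediator pmf in the composition sum.
    random_state : int
        Seed for the bootstrap stream; replicate r draws from an
        independent substream of (random_state, r), so dropped replicates
        do not shift the others.
    max_dropped_frac : float
        Error if more than this fraction of replicates fails to converge.

    Attributes (after ``fit``)
    --------------------------
    indirect_, direct_, total_ : float
        Point effects on the risk-difference scale.
    proportion_mediated_ : float
        indirect / total (nan when total == 0).
    ci_indirect_, ci_direct_ : (float, float)
        95% percentile bootstrap intervals.
    significant_indirect_, significant_direct_ : bool
        Whether the CI excludes 0.
    models_ : MediationModels
        The full-sample component fits.
    contrast_ : ExposureContrast
    result_ : MediationResult
    """

    def __init__(
        self,
        exposure: str = "x",
        mediator: str = "suitability",
        percentiles: tuple[float, float] = (10.0, 90.0),
        n_boot: int = 1000,
        alpha: float = 0.05,
        tail_mass: float = 1e-8,
        random_state: int = 0,
        max_dropped_frac: float = 0.05,
        tol: float = 1e-8,
        max_iter: int = 100,
    ):
        self.exposure = exposure
        self.mediator = mediator
        self.percentiles = percentiles
        self.n_boot = n_boot
        self.alpha = alpha
        self.tail_mass = tail_mass
        self.random_state = random_state
        self.max_dropped_frac = max_dropped_frac
        self.tol = tol
        self.max_iter = max_iter

    # -- internals -----------------------------------------------------

    def _extract(self, X, y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if isinstance(X, pd.DataFrame):
            for col in (self.exposure, self.mediator):
                if col not in X.columns:
                    raise ValidationError(f"column {col!r} not in X")
            x = pd.to_numeric(X[self.exposure], errors="coerce").to_numpy(float)
            m = pd.to_numeric(X[self.mediator], errors="coerce").to_numpy(float)
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValidationError(
                    "array X must have exactly two columns: [exposure, mediator]"
                )
            x, m = arr[:, 0], arr[:, 1]
        y = np.asarray(y, dtype=float)
        if len(y) != len(x):
            raise ValidationError("X and y length mismatch")
        keep = ~(np.isnan(x) | np.isnan(m) | np.isnan(y))
        x, m, y = x[keep], m[keep], y[keep]
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValidationError("outcome must be binary 0/1")
        if np.any(m < 0) or np.any(m != np.floor(m)):
            raise ValidationError("mediator must be non-negative integer counts")
        return x, m, y

    def fit(self, X, y):
        x, m, y = self._extract(X, y)
        self.n_used_ = len(y)
        self.contrast_ = exposure_contrast(x, self.exposure, self.percentiles)
        self.models_ = _fit_models(x, m, y, self.exposure, self.tol, self.max_iter)
        core = _core_from_models(self.models_)
        eff = _point_core(core, self.contrast_, self.tail_mass)
        self.indirect_, self.direct_, self.total_ = eff
        self.proportion_mediated_ = (
            eff.indirect / eff.total if eff.total != 0 else float("nan")
        )

        starts = (
            self.models_.mediator_fit.params["estimate"].to_numpy(),
            self.models_.mediator_fit.theta,
            self.models_.outcome_fit.params["estimate"].to_numpy(),
        )
        boot_ind: list[float] = []
        boot_dir: list[float] = []
        n_dropped = 0
        n = len(y)
        for r in range(self.n_boot):
            rng = np.random.default_rng([int(self.random_state), r])
            idx = rng.integers(0, n, n)
            try:
                med, out, mean, sd = _fit_raw(
                    x[idx], m[idx], y[idx], self.tol, self.max_iter, starts=starts
                )
                e = _point_core(
                    _core_from_raw(med, out, mean, sd), self.contrast_, self.tail_mass
                )
            except (ConvergenceError, ValidationError, np.linalg.LinAlgError):
                n_dropped += 1
                continue
            boot_ind.append(e.indirect)
            boot_dir.append(e.direct)
        if self.n_boot > 0:
            if n_dropped > self.max_dropped_frac * self.n_boot:
                raise ConvergenceError(
                    f"{n_dropped}/{self.n_boot} bootstrap replicates failed to converge"
                )
            lo, hi = 100 * self.alpha / 2, 100 * (1 - self.alpha / 2)
            bi = np.asarray(boot_ind)
            bd = np.asarray(boot_dir)
            self.ci_indirect_ = tuple(np.percentile(bi, [lo, hi]))
            self.ci_direct_ = tuple(np.percentile(bd, [lo, hi]))
            self.boot_indirect_ = bi
            self.boot_direct_ = bd
        else:
            self.ci_indirect_ = (float("nan"), float("nan"))
            self.ci_direct_ = (float("nan"), float("nan"))
            self.boot_indirect_ = np.empty(0)
            self.boot_direct_ = np.empty(0)
        self.n_dropped_ = n_dropped
        self.significant_indirect_ = bool(
            self.ci_indirect_[0] > 0 or self.ci_indirect_[1] < 0
        )
        self.significant_direct_ = bool(
            self.ci_direct_[0] > 0 or self.ci_direct_[1] < 0
        )
        if self.n_boot > 0 and not (
            self.ci_indirect_[0] <= self.indirect_ <= self.ci_indirect_[1]
        ):
            warnings.warn(
                "percentile CI does not bracket the point estimate "
                "(possible with skewed bootstrap distributions)",
                stacklevel=2,
            )
        self.result_ = MediationResult(
            contrast=self.contrast_,
            indirect=self.indirect_,
            direct=self.direct_,
            total=self.total_,
            proportion_mediated=self.proportion_mediated_,
            ci_indirect=self.ci_indirect_,
            ci_direct=self.ci_direct_,
            n_boot=self.n_boot,
            seed=int(self.random_state),
            significant_indirect=self.significant_indirect_,
            significant_direct=self.significant_direct_,
            n_dropped=n_dropped,
            models=self.models_,
            boot_indirect=self.boot_indirect_,
            boot_direct=self.boot_direct_,
        )
        return self


def bootstrap(
    table: SpeciesTable,
    x_name: str,
    n_boot: int = 1000,
    seed: int = 0,
    mediator: str = "suitability",
    response: str = "naturalized",
    percentiles: tuple[float, float] = (10.0, 90.0),
    alpha: float = 0.05,
    tail_mass: float = 1e-8,
) -> MediationResult:
    """Mediation analysis of one characteristic with nonparametric
    bootstrap CIs (thin wrapper over :class:`CountMediation`)."""
    if n_boot < 200:
        raise ValidationError("n_boot must be at least 200 for percentile CIs")
    est = CountMediation(
        exposure=x_name,
        mediator=mediator,
        percentiles=percentiles,
        n_boot=n_boot,
        alpha=alpha,
        tail_mass=tail_mass,
        random_state=seed,
    )
    est.fit(table.df[[x_name, mediator]], table.df[response])
    return est.result_


def select_candidates(
    screen_y: Mapping[str, GlmFit],
    screen_m: Mapping[str, GlmFit],
    alpha: float = 0.05,
) -> list[str]:
    """Characteristics significantly associated with BOTH naturalization
    (univariate binomial screen) and suitability (NB screen) at level
    ``alpha``; suitability itself is excluded."""
    names = []
    for name in screen_y:
        if name == "suitability" or name not in screen_m:
            continue
        if screen_y[name].pvalue(name) < alpha and screen_m[name].pvalue(name) < alpha:
            names.append(name)
    if not names:
        warnings.warn("no characteristic passed the mediation candidate gate", stacklevel=2)
    return names


def mediation_table(
    table: SpeciesTable,
    candidates: Iterable[str],
    n_boot: int = 1000,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Run the bootstrap mediation for each candidate and return the
    report table (one row per characteristic)."""
    rows = []
    for i, name in enumerate(candidates):
        res = bootstrap(table, name, n_boot=n_boot, seed=seed + i, **kwargs)
        rows.append(
            {
                "characteristic": name,
                "x0": res.contrast.x0,
                "x1": res.contrast.x1,
                "indirect": res.indirect,
                "indirect_cil": res.ci_indirect[0],
                "indirect_ciu": res.ci_indirect[1],
                "direct": res.direct,
                "direct_cil": res.ci_direct[0],
                "direct_ciu": res.ci_direct[1],
                "total": res.total,
                "proportion_mediated": res.proportion_mediated,
                "significant_indirect": res.significant_indirect,
                "significant_direct": res.significant_direct,
                "n_boot": res.n_boot,
                "n_dropped": res.n_dropped,
                "seed": res.seed,
            }
        )
    return pd.DataFrame(rows)
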