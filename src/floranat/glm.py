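"""GLM layer: naturalization and suitability association models.

Three model families drive the screening step of the analysis:

* binomial-logit GLMs of naturalization (0/1) on single characteristics
  (univariate screen) and on the full characteristic set with and without
  climatic suitability (full models),
* NB2 negative-binomial GLMs (log link, variance mu + mu^2/theta, theta
  estimated by ML) of the suitability count on single characteristics,
* Nagelkerke's pseudo R^2 and AIC for model comparison.

Continuous predictors are expected standardized (1-SD scale) so estimates
are comparable across characteristics; the raw suitability count is
z-scored internally whenever it enters as a predictor, because it must
stay on the count scale as an NB response.

Fits go through statsmodels; this module adds the domain contracts
(validation, separation diagnostics, complete-case bookkeeping) and the
uniform :class:`GlmFit` summary container.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import ConvergenceError, SeparationError, ValidationError
from .table import GROWTH_FORM_COLUMNS, ORIGIN_COLUMNS, SpeciesTable

MIN_DUMMY_POSITIVES = 5  # dummies rarer than this are skipped in screens


@dataclass
class ModelSpec:
    """What to fit: response, ordered predictors, family."""

    response: str
    predictors: list[str]
    family: str  # "binomial-logit" | "negbin-log"
    include_suitability: bool = False

    def __post_init__(self) -> None:
        # an empty predictor list means an intercept-only (null) model
        if self.response == "suitability" and "suitability" in self.predictors:
            raise ValidationError("suitability cannot predict itself")
        if self.family not in ("binomial-logit", "negbin-log"):
            raise ValidationError(f"unknown family {self.family!r}")


@dataclass
class GlmFit:
    """Uniform fitted-model summary (coefficient table, likelihoods, AIC)."""

    spec: ModelSpec
    params: pd.DataFrame  # index: term; columns: estimate, se, z, p
    loglik: float
    loglik_null: float
    n_used: int
    converged: bool
    theta: float | None = None
    theta_se: float | None = None
    poisson_limit: bool = False
    extra: dict = field(default_factory=dict)

    @property
    def k_params(self) -> int:
        k = len(self.params)
        if self.spec.family == "negbin-log":
            k += 1  # the estimated dispersion
        return k

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.loglik

    def coef(self, term: str) -> float:
        return float(self.params.loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.params.loc[term, "se"])

    def zvalue(self, term: str) -> float:
        return float(self.params.loc[term, "z"])

    def pvalue(self, term: str) -> float:
        return float(self.params.loc[term, "p"])

    def to_frame(self) -> pd.DataFrame:
        out = self.params.copy()
        out.insert(0, "term", out.index)
        return out.reset_index(drop=True)


def _params_frame(terms: Sequence[str], beta, se) -> pd.DataFrame:
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {"estimate": beta, "se": se, "z": z, "p": p}, index=list(terms)
    )


def _design(
    table: SpeciesTable, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, list[str], int]:
    """Complete-case design matrix with intercept; suitability-as-predictor
    is z-scored over the estimation rows."""
    df = table.df
    cols = [spec.response] + spec.predictors
    for c in cols:
        if c not in df.columns:
            raise ValidationError(f"column {c!r} not in table")
    sub = df[cols].dropna()
    n = len(sub)
    y = sub[spec.response].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(n)] + [sub[p].to_numpy(dtype=float) for p in spec.predictors]
    )
    terms = ["const"] + list(spec.predictors)
    if "suitability" in spec.predictors:
        j = terms.index("suitability")
        col = X[:, j]
        sd = col.std(ddof=1)
        if sd == 0:
            raise ValidationError("suitability is constant; cannot standardize")
        X[:, j] = (col - col.mean()) / sd
    return X, y, terms, n


def _check_rank(X: np.ndarray, terms: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # columns with a ~zero R diagonal in the QR are linearly dependent
        # on earlier ones
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        aliased = [terms[i] for i in range(len(terms)) if diag[i] < 1e-8]
        raise ValidationError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            f"aliased terms: {aliased or 'unidentified'}"
        )


def _separating_predictor(
    X: np.ndarray, y: np.ndarray, terms: Sequence[str]
) -> str | None:
    """Name a predictor that alone separates the binary response, if any."""
    for j, term in enumerate(terms):
        if term == "const":
            continue
        col = X[:, j]
        x1, x0 = col[y == 1], col[y == 0]
        if len(x1) == 0 or len(x0) == 0:
            continue
        if x1.min() > x0.max() or x0.min() > x1.max():
            return term
    return None


def fit_binomial(table: SpeciesTable, spec: ModelSpec) -> GlmFit:
    """Maximum-likelihood logistic regression of a binary response.

    Complete cases only; coefficients are on the log-odds scale per 1 SD
    for standardized continuous predictors, per category presence for
    dummies. Perfect separation raises :class:`SeparationError` naming the
    offending predictor where one predictor alone is responsible.
    """
    if spec.family != "binomial-logit":
        raise ValidationError("fit_binomial requires a binomial-logit spec")
    X, y, terms, n = _design(table, spec)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValidationError(f"response {spec.response!r} is not binary")
    if len(np.unique(y)) < 2:
        raise ConvergenceError(
            f"response {spec.response!r} is constant; no information"
        )
    if n < 10 * X.shape[1]:
        warnings.warn(
            f"only {n} complete cases for {X.shape[1]} parameters", stacklevel=2
        )
    _check_rank(X, terms)

    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = model.fit(maxiter=100, tol=1e-8)
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
            culprit = _separating_predictor(X, y, terms)
            raise SeparationError(
                f"perfect separation in logistic fit"
                + (f" (predictor {culprit!r})" if culprit else ""),
                predictor=culprit,
            ) from exc
    mu = res.fittedvalues
    if np.max(np.abs(res.params)) > 50 or np.all((mu < 1e-8) | (mu > 1 - 1e-8)):
        culprit = _separating_predictor(X, y, terms)
        raise SeparationError(
            "perfect separation in logistic fit"
            + (f" (predictor {culprit!r})" if culprit else ""),
            predictor=culprit,
        )
    if not res.converged:
        raise ConvergenceError(
            f"logistic fit did not converge ({res.fit_history['iteration']} iterations)"
        )
    pbar = float(np.mean(y))
    llnull = n * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar))
    return GlmFit(
        spec=spec,
        params=_params_frame(terms, res.params, res.bse),
        loglik=float(res.llf),
        loglik_null=float(llnull),
        n_used=n,
        converged=True,
    )


def fit_negbin(table: SpeciesTable, spec: ModelSpec) -> GlmFit:
    """NB2 negative-binomial regression (log link) with dispersion theta
    estimated jointly by ML.

    Equidispersed data (Pearson dispersion <= 1 under Poisson) is fitted as
    the Poisson limit and flagged via ``poisson_limit`` with theta = inf.
    """
    if spec.family != "negbin-log":
        raise ValidationError("fit_negbin requires a negbin-log spec")
    X, y, terms, n = _design(table, spec)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValidationError(
            f"response {spec.response!r} must be non-negative integer counts"
        )
    if np.all(y == 0):
        raise ConvergenceError("all counts are zero; NB mean model undefined")
    if len(np.unique(y)) < 2 and X.shape[1] > 1:
        raise ValidationError(
            f"response {spec.response!r} is constant; association model is vacuous"
        )
    _check_rank(X, terms)

    # Poisson pre-fit decides whether there is any overdispersion to model
    pois = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=100, tol=1e-8)
    pearson_disp = float(pois.pearson_chi2 / pois.df_resid) if pois.df_resid > 0 else 1.0
    if pearson_disp <= 1.0 + 1e-6:
        warnings.warn(
            "counts are equidispersed; reporting the Poisson limit (theta -> inf)",
            stacklevel=2,
        )
        return GlmFit(
            spec=spec,
            params=_params_frame(terms, pois.params, pois.bse),
            loglik=float(pois.llf),
            loglik_null=float(
                sm.GLM(y, np.ones((n, 1)), family=sm.families.Poisson())
                .fit()
                .llf
            ),
            n_used=n,
            converged=True,
            theta=np.inf,
            theta_se=np.nan,
            poisson_limit=True,
        )

    model = sm.NegativeBinomial(y, X, loglike_method="nb2")
    start = np.append(pois.params, max(pearson_disp - 1.0, 0.05) / max(np.mean(y), 1.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(start_params=start, method="newton", maxiter=200, disp=0)
            if not res.mle_retvals.get("converged", False):
                raise ConvergenceError("newton did not converge")
        except Exception:
            res = model.fit(start_params=start, method="bfgs", maxiter=500, disp=0)
            if not res.mle_retvals.get("converged", False):
                raise ConvergenceError(
                    "negative binomial fit failed to converge "
                    f"(last params {np.round(res.params, 4)})"
                ) from None
    alpha = float(res.params[-1])
    theta = 1.0 / alpha if alpha > 1e-10 else np.inf
    theta_se = float(res.bse[-1]) / alpha**2 if alpha > 1e-10 else np.nan
    if theta < 0.05 or not np.isfinite(theta_se):
        warnings.warn(
            f"unstable dispersion estimate (theta = {theta:.3g})", stacklevel=2
        )
    null = sm.NegativeBinomial(y, np.ones((n, 1)), loglike_method="nb2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res0 = null.fit(method="newton", maxiter=200, disp=0)
        except Exception:
            res0 = null.fit(method="bfgs", maxiter=500, disp=0)
    return GlmFit(
        spec=spec,
        params=_params_frame(terms, res.params[:-1], res.bse[:-1]),
        loglik=float(res.llf),
        loglik_null=float(res0.llf),
        n_used=n,
        converged=True,
        theta=theta,
        theta_se=theta_se,
    )


def nagelkerke_r2(fit: GlmFit) -> float:
    """Nagelkerke's pseudo R^2: the Cox-Snell likelihood-ratio R^2 rescaled
    to a [0, 1] ceiling."""
    l1, l0, n = fit.loglik, fit.loglik_null, fit.n_used
    if l1 < l0 - 1e-8:
        raise ValidationError(
            f"fitted log-likelihood ({l1:.4f}) below the null ({l0:.4f}); "
            "this signals a broken fit"
        )
    cox_snell = 1.0 - np.exp(2.0 * (l0 - l1) / n)
    ceiling = 1.0 - np.exp(2.0 * l0 / n)
    if ceiling <= 0:
        return 0.0
    return float(min(max(cox_snell / ceiling, 0.0), 1.0))


def default_characteristics(table: SpeciesTable) -> list[str]:
    """Characteristics available in the table, in screen order: origin
    dummies, range size, growth forms, continuous traits, PD indices.
    PD_wmean is excluded from modeling (collinear with PD_min by design)."""
    df = table.df
    names: list[str] = []
    for col in ORIGIN_COLUMNS:
        if col in df.columns:
            names.append(col)
    if "native_range_size" in df.columns:
        names.append("native_range_size")
    for col in GROWTH_FORM_COLUMNS:
        if col in df.columns:
            names.append(col)
    for col in ("seed_mass", "height", "sla", "pd_mean", "pd_min"):
        if col in df.columns:
            names.append(col)
    return names


def _is_dummy(df: pd.DataFrame, name: str) -> bool:
    vals = df[name].dropna().unique()
    return set(vals) <= {0, 1}


def univariate_screen(
    table: SpeciesTable,
    characteristics: Iterable[str] | None = None,
    response: str = "naturalized",
) -> dict[str, GlmFit]:
    """One binomial-logit fit per characteristic (plus suitability), the
    response being naturalization. Dummies with fewer than 5 positive
    species are skipped with a warning."""
    df = table.df
    names = list(characteristics) if characteristics is not None else (
        default_characteristics(table)
        + (["suitability"] if "suitability" in df.columns else [])
    )
    out: dict[str, GlmFit] = {}
    for name in names:
        if _is_dummy(df, name) and int((df[name] == 1).sum()) < MIN_DUMMY_POSITIVES:
            warnings.warn(
                f"skipping {name!r}: fewer than {MIN_DUMMY_POSITIVES} positives",
                stacklevel=2,
            )
            continue
        spec = ModelSpec(response=response, predictors=[name], family="binomial-logit")
        out[name] = fit_binomial(table, spec)
    return out


def suitability_screen(
    table: SpeciesTable, characteristics: Iterable[str] | None = None
) -> dict[str, GlmFit]:
    """One NB2 fit per characteristic with the raw suitability count as
    response; gates which characteristics enter the mediation analysis."""
    df = table.df
    names = (
        list(characteristics)
        if characteristics is not None
        else default_characteristics(table)
    )
    out: dict[str, GlmFit] = {}
    for name in names:
        if _is_dummy(df, name) and int((df[name] == 1).sum()) < MIN_DUMMY_POSITIVES:
            warnings.warn(
                f"skipping {name!r}: fewer than {MIN_DUMMY_POSITIVES} positives",
                stacklevel=2,
            )
            continue
        spec = ModelSpec(response="suitability", predictors=[name], family="negbin-log")
        out[name] = fit_negbin(table, spec)
    return out


class FullModels(NamedTuple):
    with_suitability: GlmFit
    without_suitability: GlmFit
    delta_r2: float
    delta_aic: float


def full_models(
    table: SpeciesTable, predictors: Iterable[str] | None = None
) -> FullModels:
    """The two multivariate binomial fits (with / without the suitability
    term) on identical complete cases, plus their Nagelkerke R^2 and AIC
    difference (exclusive minus inclusive; positive favours inclusion)."""
    preds = list(predictors) if predictors is not None else [
        name
        for name in default_characteristics(table)
        if not _is_dummy(table.df, name)
        or int((table.df[name] == 1).sum()) >= MIN_DUMMY_POSITIVES
    ]
    if "suitability" not in table.df.columns:
        raise ValidationError("table has no suitability column")
    # restrict both fits to joint complete cases (including suitability)
    keep = table.df[["naturalized", "suitability", *preds]].dropna().index
    sub = SpeciesTable(table.df.loc[keep].reset_index(drop=True), dict(table.provenance))
    spec_with = ModelSpec(
        response="naturalized",
        predictors=preds + ["suitability"],
        family="binomial-logit",
        include_suitability=True,
    )
    spec_without = ModelSpec(
        response="naturalized", predictors=list(preds), family="binomial-logit"
    )
    fit_with = fit_binomial(sub, spec_with)
    fit_without = fit_binomial(sub, spec_without)
    return FullModels(
        with_suitability=fit_with,
        without_suitability=fit_without,
        delta_r2=nagelkerke_r2(fit_with) - nagelkerke_r2(fit_without),
        delta_aic=fit_without.aic - fit_with.aic,
    )


def fits_to_frame(fits: Mapping[str, GlmFit]) -> pd.DataFrame:
    """Coefficient table across single-predictor fits (term = the
    characteristic), in CSV-export shape."""
    rows = []
    for name, fit in fits.items():
        row = {
            "characteristic": name,
            "estimate": fit.coef(name),
            "se": fit.se(name),
            "z": fit.zvalue(name),
            "p": fit.pvalue(name),
            "n_used": fit.n_used,
            "aic": fit.aic,
            "nagelkerke_r2": nagelkerke_r2(fit),
        }
        if fit.theta is not None:
            row["theta"] = fit.theta
        rows.append(row)
    return pd.DataFrame(rows)
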