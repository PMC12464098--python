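# Methods

## The inference problem

Cultivated alien plants either establish self-sustaining populations in
their introduced range (naturalize) or remain confined to cultivation.
Two kinds of explanation compete: plant characteristics may act on
naturalization *directly* (e.g. large native ranges proxy broad
ecological tolerance), or *indirectly*, because the same characteristics
make the regional climate more suitable for the species, and climatically
suitable species naturalize more often. `floranat` implements the full
chain needed to separate the two: association screens, phylogenetic
relatedness metrics, and a causal mediation estimator in which climatic
suitability — a per-species count of climatically suitable grid cells,
taken as precomputed SDM output — is the mediator.

## Models

### Association screens

Naturalization `Y ∈ {0,1}` is modelled with binomial-logit GLMs:
univariately on each characteristic, and multivariately on the full
characteristic set with and without the suitability term. The suitability
count `M` is modelled with NB2 negative-binomial GLMs (log link, variance
`μ + μ²/θ`, dispersion `θ` estimated by joint maximum likelihood) on each
characteristic. All continuous predictors are z-scored (sample sd,
denominator n−1), so estimates are per-SD log-odds (or log-mean) changes;
origin and growth-form indicators enter as 0/1 dummies, one column per
category, because a species may belong to several. The suitability count
is z-scored wherever it appears as a predictor but remains a raw count as
the NB response. Model comparison uses AIC (`2k − 2ℓ`, with θ counted for
NB fits) and Nagelkerke's pseudo-R²,

    R² = [1 − exp(2(ℓ₀ − ℓ₁)/n)] / [1 − exp(2ℓ₀/n)].

A note on links: a logit link is not defined for unbounded counts, so the
suitability models use the canonical log link.

### Natural-effect decomposition

For one exposure `X` at a time, two models are fitted on the same
complete cases:

* mediator: `M | X=x ~ NB2(μ(x) = exp(a₀ + a₁x), θ)`,
* outcome: `P(Y=1 | X=x, M=m) = expit(g₀ + gₓx + g_m s(m))`,

where `s(m)` standardizes the raw count with the estimation-sample mean
and sd. The composed counterfactual mean

    p(x_y, x_m) = Σ_m P(M=m | x_m) · expit(g₀ + gₓ x_y + g_m s(m))

is evaluated by deterministic summation over the NB pmf, truncated at the
smallest support holding mass `1 − 10⁻⁸` and renormalized — no Monte
Carlo enters the point estimate. With an exposure contrast `(x₀, x₁)`
(10th vs 90th sample percentile for continuous exposures, absence vs
presence for dummies) the natural effects on the risk-difference scale
telescope exactly:

    indirect = p(x₁, x₁) − p(x₁, x₀)      (mediator law shifts, exposure held high)
    direct   = p(x₁, x₀) − p(x₀, x₀)      (exposure moves, mediator law held low)
    total    = indirect + direct           (identity, to machine precision)

Proportion mediated is `indirect / total`. The decomposition is bivariate
by design — one characteristic at a time, mirroring how per-characteristic
mediation is usually reported — and assumes no exposure–mediator
interaction in the outcome model and no unmeasured confounding of the
three relationships; neither assumption is testable from these data.

### Inference

Nonparametric bootstrap: rows are resampled with replacement, both models
are refitted per replicate (the mediator standardization re-estimated on
the replicate), and 95% percentile intervals are taken over the replicate
effects. The contrast stays fixed at its full-sample percentiles, because
the estimand is defined on the study sample, not on each resample.
Replicate `r` draws from an independent substream keyed by `(seed, r)`,
so a dropped (non-converged) replicate cannot shift the others; more than
5% dropped replicates is an error. Defaults: 1000 replicates for
reporting; a floor of 200 is enforced.

A characteristic enters the mediation stage only if it passes a two-part
gate: univariate association with naturalization *and* association with
suitability, both at `α = 0.05` (Wald z-tests, two-sided, no
multiple-testing correction — matching how such screens are convention-
ally reported).

**Operating characteristic.** The percentile bootstrap test of the
indirect effect is known to be imperfectly calibrated in mediation
settings. The suite measures it directly (single-leg null `a₁ = 0` with a
strong mediator–outcome link, n = 1400, B = 500, 200 datasets): the
observed rejection rate is reported by the test itself; under the
complete null (both legs zero) the test is strongly conservative (~1% in
a 100-dataset check). Users reading borderline CIs should keep this
asymmetry in mind.

### Phylogenetic relatedness

For each alien species, patristic distances to all native tips give
`PD_mean` (plain average), `PD_wmean` (weighted by each native's
occurrence count across the 18 subregions, 1–18), and `PD_min` (nearest
native relative). Distances are branch-length path sums computed from
per-tip root paths (`d(a,b) = depth(a) + depth(b) − 2·depth(mrca)`) and,
for one-against-all queries, a single source-to-all-tips traversal; a
full pairwise matrix is never materialized because study trees have
thousands of tips and only alien × native pairs are needed. Tip labels
are matched after normalizing spaces/underscores and case. Missing branch
lengths are an error; zero lengths are accepted (arbitrarily resolved
polytomies do not change path sums). `PD_wmean` is computed and exported
but excluded from regression and mediation by default (it is nearly
collinear with `PD_min` in practice).

## Synthetic data and the truth oracle

The generator draws data with exactly the structure the analysis assumes.
Continuous traits are log-normal; the *standardized log-trait* (exactly
standard normal) is the model covariate, while the table stores the raw
heavy-tailed value — so the NB log-mean is exactly linear in the
covariates, and an analysis that log10-transforms before z-scoring
recovers the generative scale (z-scores of log10 and natural log are
identical). Indicators are Bernoulli. Suitability is NB2 via gamma-mixed
Poisson with the log-mean linear in the characteristics and a ceiling of
12,000 on the mean (a species cannot be suitable in more grid cells than
the region holds: ~4,000,000 km² at a 10-arc-minute grid). Naturalization
is Bernoulli with logit linear in the characteristics plus
`c · s(M)`, where `s` uses *reference moments* computed once per config
from a large fixed-seed draw — the generative law is therefore a
deterministic property of the config, identical for every data seed and
shared with the truth oracle. PD columns come from a simulated Yule tree
(dendropy birth–death simulator, death rate 0; leaf edges extended by the
exponential waiting time to the next birth so the tree is sampled between
events and stays ultrametric) through the package's own relatedness
metrics.

Default regime: 1,407 species; naturalization incidence ≈ 0.35;
standardized suitability coefficient 1.6 in the outcome logit; θ = 1
(strongly overdispersed counts, mean ≈ 200 cells); mixed positive and
negative characteristic effects (positive for native range size, height,
a Southern-American origin, short-lived herbs; negative for a European
origin and for distance to the nearest native). Characteristics are
independent by default; correlation can be induced only by sharing
coefficients, which keeps recovery tests clean.

`true_effects` is the independent oracle: it draws full covariate
vectors, sets the focal characteristic to its population contrast
(`Φ⁻¹(0.1), Φ⁻¹(0.9)` for continuous; 0/1 for dummies; empirical
percentiles for tree-derived PD), draws mediator counts from the *true*
NB law (sharing the gamma mixing variable across counterfactual arms for
variance reduction), averages the true outcome probability, and reports
Monte-Carlo SEs from the per-draw paired contrasts. Indirect + direct =
total holds exactly per draw, hence in the means.

What the generator does *not* emulate: correlated characteristics,
spatially structured SDM errors, taxonomic noise in tip matching,
missing-data mechanisms (synthetic tables are complete), and residence
time / propagule pressure. Passing recovery tests therefore show that the
estimator inverts its own assumed data-generating structure, not that the
assumptions hold in any real flora.

## Numerical choices

* GLM layer: statsmodels (IRLS for binomial; NB2 ML with joint θ).
  Convergence tolerance 1e-8, ≤ 100–200 iterations. Perfect separation is
  detected (fitted probabilities pinned at 0/1 or diverging coefficients)
  and reported with the offending predictor when a single predictor
  separates alone. Equidispersed counts (Pearson dispersion ≤ 1 under a
  Poisson pre-fit) are returned as the flagged Poisson limit (θ = ∞)
  rather than erred; θ < 0.05 triggers an instability warning.
* Mediation refits use a dedicated Newton/IRLS fitter (`_fastglm`),
  because the property suite performs ~10⁵ refits; it matches statsmodels
  to ≤ 1e-4 in coefficients (asserted in the suite), profiles θ on the
  log scale with digamma/trigamma sums evaluated through integer tail-
  count identities, and takes β standard errors from the joint (β, θ)
  observed information. Bootstrap replicates warm-start from the
  full-sample estimates (verified to reach the same optimum as cold
  starts to 1e-9).
* The NB pmf used in the composition sum is computed directly from
  log-gamma terms with an adaptive truncation bound (checked against
  scipy's pmf to 1e-10); truncation beyond 10⁷ support points aborts with
  a pathological-dispersion error.
* Percentiles use linear interpolation at rank `1 + (n−1)p`. Ties in the
  nearest-native search break deterministically on the tip label.
* Standardization uses sample sd (n−1); constant columns are an error.
  Missing trait cells are preserved and handled by complete-case analysis
  per model (rows are dropped only for models that use the missing
  variable).

## Design choices that were genuinely open

* **Effect scale.** Effects are reported as risk differences
  (probabilities), matching the verbal definition of the contrasts as
  differences of expected outcomes and the magnitude of published
  per-characteristic mediation tables against a ≈ 0.35 base rate.
* **Trait transforms.** Whether heavy-tailed traits should be
  log-transformed before z-scoring is exposed per variable
  (`ColumnMapping.transforms`), defaulting to identity; this is the
  single largest lever when reproducing published coefficients from a
  deposited table, so it is configuration, not code.
* **Full-model predictor set.** Every available characteristic with at
  least 5 positive species (for dummies) enters; the set is overridable.
* **Intercept-only NB fits** are allowed (the null model for likelihood
  ratios and the equidispersion example) even though ordinary screens
  always carry a predictor.

## Problem sizes in the default test run

The property suite runs the composition-vs-Monte-Carlo check at 10⁶
draws × 20 models, parameter recovery at n = 50,000 × 20 seeds against a
400,000-draw oracle, the bootstrap calibration at 200 datasets × 500
replicates (n = 1,400), and the end-to-end pipeline at n = 400 with 200
bootstrap replicates per gated characteristic. These sizes were chosen so
that Monte-Carlo error is small relative to the tolerances being
asserted while the whole suite stays comfortably runnable on a laptop
core.

## Known limitations

* The mediation is bivariate; co-adjusting for other characteristics is
  possible in principle (both component models accept covariates) but not
  exposed, because per-characteristic decompositions are what the report
  tables contain.
* No exposure–mediator interaction, no zero-inflated mediator variant,
  and no sensitivity analysis for unmeasured confounding.
* Percentile CIs (not BCa); the measured mild anti-conservatism under
  single-leg nulls is documented above.
* Tip-label matching is purely lexical after normalization; synonymy is
  out of scope and conflicting native/alien designations are an error,
  not a merge.
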