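# Methods

## The problem and the model

`prevmap` estimates the spatial distribution of a binomial outcome — its
motivating use is severe acute malnutrition (SAM) in children under two —
from a geolocated cluster survey: each primary sampling unit (PSU) is
represented by its household centroid and contributes one binomial
observation (cases out of children examined). The estimand is a gridded
prevalence surface and its population-weighted aggregation to administrative
units.

The model is the standard model-based-geostatistics binomial regression:

    y_i ~ Binomial(n_i, p_i)
    logit(p_i) = x_i' beta + S(s_i)
    S ~ GP(0, sigma^2 * Matern_nu(d; range))

Fixed effects are linear main effects of gridded covariates extracted at the
PSU centroid cell; the Gaussian-process residual S captures spatial
autocorrelation not explained by the covariates, interpolates between
clusters, and widens predictive uncertainty away from data.

### Matérn parameterization

The correlation at distance d is

    corr(d) = 2^(1-nu)/Gamma(nu) * (kappa d)^nu * K_nu(kappa d),
    kappa = sqrt(8 nu) / range,

the convention of the SPDE literature, under which `range` is the distance
at which correlation has decayed to roughly 0.1 regardless of nu. At
nu = 1/2 this is exactly exp(-2 d / range). Smoothness nu is fixed (not
sampled), default 1 — the once-differentiable field standard for 2-D
prevalence mapping — and exposed as a setting. All coordinates are in a
projected, km-based, equal-area system and distances are Euclidean;
great-circle geometry is out of scope at the ~1-km grid scales targeted.

### Priors

The study data rarely support informative hyperpriors, so the defaults are
weakly informative and fully configurable:

- range: 2-D penalized-complexity-style prior pi(r) = lambda r^-2 exp(-lambda/r)
  with lambda chosen so P(range < r0) = 0.1, r0 = one tenth of the data
  bounding-box diameter;
- sigma: exponential prior with P(sigma > 1) = 0.1;
- coefficients: Normal(0, 10^2) after internal standardization of each
  covariate column (the transform is stored; reported draws are
  back-transformed to the original covariate scale).

## Inference

The posterior contract — joint samples of (beta, sigma, range, S) honoring
the binomial likelihood and GP prior — is met by a Markov chain Monte Carlo
sampler built for latent-Gaussian models. The latent field is represented
exactly at the cluster locations via a dense Cholesky factorization (no mesh
or sparse approximation; exact at the few-hundred-site problems targeted).
Each iteration performs:

1. **Elliptical slice sampling (ESS)** of the whitened field v (S = sigma L v,
   L the Cholesky factor of the Matérn correlation matrix) — rejection-free,
   tuning-free, exploiting the Gaussian prior exactly.
2. **ESS of the coefficient block** under its Gaussian prior.
3. **An exact Gibbs move along the intercept/field-level ridge.** The
   likelihood is invariant under (beta0 -> beta0 + delta, S -> S - delta),
   so the two are confounded and plain componentwise updates mix very
   slowly; the conditional of delta under the two Gaussian priors is itself
   Gaussian and is sampled in closed form.
4. **Adaptive random-walk Metropolis on (log sigma, log range), interweaved**:
   one update in the whitened parameterization (v fixed, the field rescales;
   informative when the data constrain the field's look) and one in the
   centered parameterization (S fixed, acceptance driven by the GP prior
   density of the realized field; informative about sigma and range given
   the field). This ancillarity–sufficiency interweaving gives usable
   hyperparameter mixing where either update alone stalls. Proposal scales
   adapt toward ~0.3 acceptance during warmup only.

Draws are recorded after a warmup (defaults: 1000 warmup, 1000 retained).
Diagnostics (acceptance rates and autocorrelation-based effective sample
sizes for sigma, range and the intercept) are attached to every fit; a fit
whose hyperparameter moves essentially never accept raises rather than
returning garbage. Identical seeds give bit-identical posteriors.

Known property of the model, not of the sampler: when the true range is
comparable to the domain size, sigma and range are only weakly identified
from a single field realization (the domain contains few independent
patches), so their posteriors lean on the prior and widen; interval coverage
remains calibrated, which is what the recovery tests check.

## Prediction, exceedance, aggregation

For each retained posterior draw the latent field is extended to all cell
centers by an exact conditional GP draw — kriging mean plus a joint
conditional-covariance realization, not just the mean — so downstream
functionals see genuine spatial uncertainty. On a regular grid the Matérn
matrix has only O(n_cells) distinct entries (one per absolute row/column
offset), which reduces the per-draw cost to one Bessel evaluation per unique
offset plus one Cholesky factorization.

- Surfaces: per-cell posterior mean of the probability-scale draws (not the
  inverse-logit of the mean linear predictor) and equal-tailed 2.5/97.5
  percentiles with linear interpolation between order statistics; both are
  exact deterministic functions of the stored sample matrix.
- Exceedance: per cell, the fraction of draws strictly greater than the
  threshold (strictness is immaterial for continuous draws and fixed for
  determinism); defaults 2, 5, 10, 15%.
- Aggregation: draw-wise. For draw s and unit u, prevalence is the
  population-weighted mean of p over the unit's cells and the count is the
  weighted sum; summaries are taken over the aggregated draws. Aggregating
  posterior-mean surfaces instead would understate interval widths and break
  the additivity identities the tests enforce (district counts sum exactly
  to the province count, draw-wise). Cell membership is cell-center-in-
  polygon with the grid's half-open edge convention; zero-population units
  report missing prevalence and zero count. Population is taken as the
  supplied under-2 raster directly; any age–sex scaling happens upstream.

## Covariate selection

1. Univariate screen: a non-spatial binomial GLM (logit link, IRLS via
   statsmodels) per candidate; retained when its AIC beats the
   intercept-only AIC by more than 2 (a conventional cut; the screen is a
   pre-filter, not an inferential claim). Zero-variance and
   perfectly-separating covariates are excluded with a recorded reason.
2. Correlation filter: among pairs with |Pearson rho| > 0.8 over cluster
   rows — the design matrix actually fitted, not the full grid — the member
   with the worse univariate AIC is dropped; pairs are processed by
   descending |rho| with name tie-breaks, so the result is deterministic and
   invariant to column order, and the filter is idempotent.
3. Diagnostic: deviance residuals of the joint non-spatial fit (standard for
   binomial GLMs; Pearson residuals would work similarly) are examined with
   a classical Matheron semivariogram — equal-width half-open distance bins,
   empty bins reported missing rather than zero. Residual structure at short
   ranges is the empirical motivation for the spatial term.

## Cross-validation

Random folds at the cluster level (never child level), seeded; each fold's
model is refitted on the complement and the held-out clusters' prevalence is
predicted as the posterior mean of p at their locations (mean of
probability-scale draws, consistent with prediction). R² is reported under
two definitions: squared Pearson correlation of observed and predicted
cluster proportions (the default; affine-invariant) and the regression
definition 1 − SSE/SST (penalizes bias); both appear in every CV output.
Held-out responses and locations never enter the fitted latent field, a
property the suite checks by tampering with held-out responses.

## Synthetic data: what it does and does not emulate

The generator produces complete, seeded study regions: smooth standardized
covariate surfaces with distinct spatial scales (one engineered pair with
|rho| > 0.8 to exercise the filter), a latent Matérn field, cluster surveys
(uniform or clumped around district-like centers, mimicking multi-stage
sampling), a log-Gaussian population-at-risk raster conserving a specified
total, and rectangular admin units partitioning the region.

The default scenario fixes the study conditions at a realistic provincial
survey scale: a 40 × 40 km region at 1-km resolution, 6 candidate covariates
(three with true effects 0.8, −0.5, 0.3), Matérn(nu = 1) field with
sigma = 1 and 10 km range, intercept −3.2 (chosen so that marginal
prevalence is ≈ 7% with cluster-level fractions ranging from 0 up to ~77%),
123 clumped clusters of 12–15 children, and 240,000 children at risk.

What passing tests on this generator do **not** show about real data: real
covariates are not Gaussian fields (they have ridges, coastlines,
discontinuities); real PSU placement follows sampling frames, access and
security, not a uniform or Gaussian-clump process; the under-2 population
raster is itself a model output with error the pipeline treats as fixed; and
real outcomes can depart from the binomial (within-cluster overdispersion
beyond what the shared field induces). The synthetic checks validate the
statistical machinery under its own assumptions, not those assumptions
themselves.

## Numerical choices

- Jitter: 1e-8 of the mean diagonal added before every Cholesky
  factorization, escalating tenfold on failure (at most 4 attempts) before
  raising.
- Half-open cell membership [edge, edge + cell_size): a point on a shared
  edge belongs to the east/north cell; the grid's top/right outer edges are
  outside.
- Percentiles: NumPy's linear interpolation between order statistics,
  everywhere, for bit-reproducibility.
- Collinear or zero-variance design columns are rejected with the offending
  names before sampling.
- Perfect separation in the screen is detected by non-finite or runaway
  (|coef| > 50) estimates and excludes the covariate with a reason.
- All randomness flows through `numpy.random.Generator` seeds; the pipeline
  derives one named seed per stage from a base seed, and every fold fit
  derives its seed from the spec's.

## Problem sizes

Test and acceptance experiments run at desk scale, chosen to keep Monte-
Carlo error well below the tolerances being asserted while completing in
minutes: recovery uses 20 replicates of 150 clusters × 20 children on a
40 × 40 grid with 1000 retained draws; coverage/exceedance use 10 replicates
of 100 clusters on a 20 × 20 grid (1000 retained draws thinned by 2, 300
prediction draws); cross-validation ordering uses 10 replicates of 60
clusters with 10 folds. The acceptance script runs the full default scenario
(123 clusters, 40 × 40 grid, 1000 posterior samples, 10-fold CV).

## Limitations

- A single chain per fit; between-chain diagnostics (R-hat) are not
  computed. The interweaved sampler's effective sample sizes are reported
  and the recovery suite validates calibration end-to-end.
- Dense-GP cost grows as O(n^3) in clusters and grid cells per draw;
  hundreds of sites and a few thousand cells are comfortable, national
  1-km rasters are not the target without thinning draws or coarsening.
- Spatio-temporal structure, non-stationarity, interactions/nonlinear fixed
  effects, overdispersion beyond the field, and survey design weights are
  all out of scope.
- The non-spatial limit is reached by pinning sigma near zero, not by a
  separate analytic branch.
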