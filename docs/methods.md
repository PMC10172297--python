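# Methods

## Outcome model and estimation

Patient-level outcomes are modeled by a logistic regression with a single
hospital-level random intercept: `logit p_ij = a_i + x_ij' b` with
`a_i ~ N(alpha, sigma_a^2)` i.i.d.  The model is deliberately minimal — no
random slopes, no overdispersion beyond the intercept — because the
ranking statistic of interest is `a_i` itself and every downstream
quantity (true quartile membership, simulated outcomes) is defined through
it.

`RandomInterceptLogit` maximizes the integrated likelihood with adaptive
Gauss–Hermite quadrature over the scalar random effect: for each hospital
the posterior mode and curvature of the intercept are found by vectorized
Newton steps, and the Gauss–Hermite nodes (default 15) are recentred and
rescaled there.  The outer optimization runs L-BFGS-B on
`(alpha, b, log sigma_a)`; the log-SD parameterization enforces
nonnegativity, and estimates with `sigma_a < 1e-3` are reported as exact
zeros with a warning (a boundary solution, common when the data carry no
between-hospital signal).  Convergence is declared at a relative
log-likelihood tolerance of 1e-8.  Fifteen adaptive nodes are ample for a
scalar random effect; the test suite verifies the integrated likelihood
against dense fixed-grid integration on small instances (1e-4 absolute)
and the full fit against `lme4::glmer` with `nAGQ = 15`, which agrees to
about 1e-3 on every parameter and on the log-likelihood.  Standard errors
are not computed: nothing downstream consumes them.

The marginal (population-averaged) model is an ordinary logistic
regression fit by statsmodels.  Inside the Monte-Carlo loop, where the
same design is refit a thousand times with fresh outcomes, a plain
Newton–Raphson solver with warm starts is used instead; it is unit-tested
against statsmodels to 1e-6 and raises (triggering a dataset redraw) on
separation or degenerate outcomes.

### Conditional-to-marginal attenuation

The two parameterizations are linked by the cumulative-Gaussian
approximation to the logistic: every coefficient is shrunk by
`1/sqrt(c^2 sigma_a^2 + 1)` with `c = 16*sqrt(3)/(15*pi)`.  On the
probability scale the approximation is excellent (max error 0.0065 over
`|alpha| <= 4`, `sigma_a <= 1`).  On the *parameter* scale it degrades for
rare outcomes: when the event probability is a few percent the random
intercept acts almost multiplicatively, slopes barely attenuate, and the
fitted marginal intercept compensates.  The consistency test therefore
checks parameter-scale agreement (±0.05 per coefficient) on a
moderate-prevalence pool; at 3% prevalence only probability-scale and
calibration-in-the-large agreement should be expected.

## Classification accuracy engine

Given covariates and conditional parameters, each of K simulated datasets
draws fresh intercepts `a_i^(k)` and Bernoulli outcomes, refits the
marginal model (or uses externally supplied coefficients, mirroring the
use of published national baselines), computes SIRs, and flags values
strictly above the 75th percentile of each statistic.  Numerical choices:

* **Quantile rule.** Linear interpolation between order statistics
  (`numpy.percentile` default).  With 149 distinct values this flags
  exactly 37 hospitals (the 112/37 split of a 149-hospital pool); the rule
  is configurable since other conventions shift ties.
* **Strict inequality at the threshold.**  Values exactly equal to the
  percentile are *not* flagged; when all values coincide (e.g.
  `sigma_a = 0`) nothing is flagged and the affected metrics are 0/0.
* **0/0 cells** are reported as NaN, never 0 — a hospital never flagged
  across K datasets has no estimable PPV.
* **Redraws.**  A dataset whose marginal refit fails (no events, or
  separation) is redrawn from a fresh child stream and counted.  At the
  default pool's size and rate this essentially never happens; it matters
  for small test pools.
* **Reproducibility.**  One master `SeedSequence` spawns a child per
  dataset, so results are bit-for-bit reproducible and independent of
  execution order.
* **Paired designs.**  The engine can rank the same simulated datasets
  under several SIR covariate sets at once; the misspecification
  experiments use this to compare correct and misspecified risk models
  without extra Monte-Carlo noise.
* **Exclusion filter.**  A CDC-style option drops hospitals below a
  predicted-event threshold (default 1.0, off by default) from both the
  ranking and the quartile computation; default off, since the accuracy
  metrics are most informative precisely for the small hospitals the
  filter removes.

The threshold finder scans the empirical frontier: the reported minimum is
the smallest observed x-value (volume or predicted events) such that every
hospital at or above it meets the criterion, so a single failing
large-volume hospital honestly pushes the threshold up.

## Synthetic cohort generator

The generator emulates the published structure of a 149-hospital,
~39,500-patient colon-surgery SSI cohort: volumes in [2, 903] averaging
265, six risk-adjustment covariates with published coefficients and
intraclass correlations (age, male gender, ASA score, diabetes,
BMI ≥ 30, non-primary closure technique), pairwise covariate correlations
within the published range, `sigma_a = 0.5`, and an overall rate near
3.1%.  Volumes come from a discretized log-normal (log-SD 1.0) truncated
to the published range with its location solved so the truncated mean hits
265; two anchor volumes (78 and 303 — the volumes of the two hospitals
tracked through the event-rate analyses) are always present.  Covariates
use a latent-Gaussian construction: hospital-level and patient-level
multivariate-normal components share one correlation matrix, mixed as
`sqrt(ICC) * B_i + sqrt(1-ICC) * e_ij`, then transformed to each declared
marginal type.  ICCs are therefore enforced on the latent scale;
thresholding attenuates the observed-scale ICC of binary covariates
(bounded by a simulation test rather than corrected, since the published
ICCs' scale is itself unstated).

What the generator does *not* emulate: the real joint covariate
distribution beyond these published summaries.  Marginal distributions
(age N(62, 13²), prevalences 0.50/0.20/0.35/0.05, ASA category
probabilities peaked at 3), the volume-distribution shape, the correlation
matrix entries, and the seven extra covariates of the richer
"claims-plus-EHR"-style truth model used in the underfitting experiment
are plausible synthetic choices, config-overridable and labelled as such.
Passing tests on this pool show the *method* behaves as claimed under a
realistic regime; they cannot certify hospital-specific numbers for any
real dataset.

**Intercept calibration.**  The published random-intercept mean (−2.7862)
was estimated against an unpublished covariate distribution; applied to
the synthetic covariates it would imply roughly double the published event
rate.  The default config therefore keeps the published `sigma_a` and
coefficients but calibrates the intercept by Brent root-finding (against a
Gauss–Hermite evaluation of the marginal rate, tolerance well under 1e-3)
so the pool's overall rate is 3.1%; the calibrated default lands near
−3.65.  Setting `target_rate=None` restores the verbatim intercept.  The
same machinery implements the event-rate sweep (5–50%).

## Scenario studies

* **Validation:** empirical truth from 2,000 independent replications
  under the generating parameters versus 20 full Algorithm-1 runs
  (conditional refit + K = 1,000) on independently simulated "observed"
  datasets.  Desk-scale defaults; at these sizes the Monte-Carlo SD of a
  per-hospital metric estimate is ~0.016, so the mean-absolute-deviation
  acceptance bound of 0.05 leaves headroom for genuine estimation error
  (the conditional-fit noise), which dominates.
* **Event-rate sweep:** covariates resampled with replacement within each
  hospital (volumes and case-mix preserved), intercept recalibrated per
  rate, outcomes regenerated.  Arms use independent draws by default; a
  common-random-numbers flag shares streams across arms.
* **Variance sweep:** `sigma_a` in {0.5, 0.75, 1.0} with the intercept
  recalibrated per arm so the overall rate stays fixed — isolating the
  heterogeneity effect rather than letting the rate drift upward with the
  variance.
* **Misspecification:** the overfit arm generates outcomes from the
  six-covariate truth and ranks under both the six-covariate and the
  13-covariate models (the extras carry zero true effect); the underfit
  arm generates from the 13-covariate stand-in truth and ranks under both.
  Paired evaluation on shared datasets.

## Heterogeneity indices

`E(s^2) = pi(1-pi)/n_H + sigma^2` treats `sigma^2` as the variance of true
hospital-level *rates*; the simulation check draws true rates directly on
that scale.  The rankability `r = sigma_a^2/(sigma_a^2 + median(s_i^2))`
requires both variances on one scale: `sampling_variances` offers the
rate-scale estimator `p(1-p)/n` (half-event continuity correction at 0 and
n) and the logit-scale delta-method estimator
`1/(Y+0.5) + 1/(n-Y+0.5)`, the natural pairing for the GLMM's logit-scale
`sigma_a^2`.  The estimator behind the published index is not specified;
both conventions are exposed and the choice is recorded in the output.

## Known limitations

* The conditional fit assumes a normal random intercept; no diagnostics
  for misspecified random-effect distributions are provided.
* Exact quantile conventions matter near ties; only the strict-inequality
  rule is implemented (configurable interpolation, not configurable
  strictness).
* Minimum-volume thresholds derived from the synthetic pool track the
  pool's own volume distribution and rate; they are illustrative, not
  transferable criteria for real programs.
* Confidence-interval-based flagging (as used for some mortality
  measures) is out of scope; only quartile classification is supported.
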