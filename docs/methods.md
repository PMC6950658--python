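# Methods

## The model

`stcar` fits a Bayesian hierarchical Poisson model for disease counts on a
panel of N areal units observed over T years.  Observed counts are

    O_it ~ Poisson(E_it * RR_it),            i = 1..N,  t = 1..T

with expected counts from internal standardization,

    E_it = rho_it * Rbar,     Rbar = (sum_it O_it) / (sum_it rho_it),

so that `sum(E) = sum(O)` by construction and RR_it is the area-year's risk
relative to the pooled regional rate.  The log relative risk is

    log RR_it = alpha + U_i + V_i + b_thi * X~_it + b_ebf * X~_i
                + (gamma + delta_i) * t~

where

- `alpha` — intercept (improper flat prior);
- `U_i` — spatially structured effect, intrinsic CAR (ICAR) prior: each
  U_i is conditionally Normal around the mean of its graph neighbors with
  variance `sigma2_u / n_i`;
- `V_i` — unstructured heterogeneity, iid Normal(0, sigma2_v);
- `b_thi`, `b_ebf` — slopes for the space-time covariate (injury
  hospitalization rate per 100,000, lagged one year so the outcome in year y
  sees the rate from y-1) and the spatial-only covariate (excess body fat
  percent, temporally constant);
- `gamma` — mean linear time trend per year; `delta_i` — area-specific
  differential trend with its own ICAR prior; the local trend of area i is
  `gamma + delta_i`;
- `t~ = t - (T+1)/2` — model time centered at its midpoint, and `X~` are
  mean-centered covariates.

Priors (WinBUGS parameterization: `Norm(mean, precision)`): the slopes and
trend get Normal(0, precision 1e-4), i.e. variance 10,000 — essentially
flat; each random-effect precision `1/sigma2` gets Gamma(0.5, 0.0005).
Alternates wired in for sensitivity runs: Normal precision 0.1 on the
coefficients, Gamma(0.001, 0.001) on the precisions, and Uniform(0, 1000)
on the standard deviations (handled by a Metropolis step on log sigma2 with
the appropriate Jacobian, since conjugacy is lost).

Covariates are centered internally for sampler stability; centering changes
only the intercept's interpretation (it is reported on the centered scale),
never the slopes or fitted means — `test_centering_shifts_only_intercept`
checks this exactly.  Slopes are reported in raw covariate units (per
percentage point, per unit rate), not standardized.

## Sampler

Metropolis-within-Gibbs over single-parameter blocks:

- `alpha`, `b_thi`, `b_ebf`, `gamma`: scalar symmetric random-walk
  Metropolis; the likelihood change is evaluated over all N*T cells.
- `U`, `V`, `delta`: single-site random-walk Metropolis per area.  For the
  ICAR fields the areas are partitioned into independent sets by a greedy
  graph coloring; updates within one set touch disjoint likelihood cells and
  read only out-of-set neighbor values, so their accept/reject decisions can
  be vectorized while remaining exactly the single-site kernel.  The iid
  field needs no coloring.
- Precisions: conjugate Gibbs draws from Gamma(a + n*/2, b + q/2) with q the
  ICAR pairwise-difference energy (n* = N - c, c = connected components) or
  the sum of squares (n* = N).

Identification: the ICAR prior is flat along a constant shift of the whole
field, and only that global direction is confounded with a fixed effect
(alpha for U, gamma for delta; per-component levels are identified by the
likelihood).  After every sweep the field mean is subtracted and added to
the paired fixed effect, which leaves the linear predictor untouched — an
exact reparameterization, valid for any number of components.  The ICAR
degrees of freedom still use N - c.  Disconnected graphs are accepted with a
warning.

Proposal scales adapt by Robbins-Monro on the log scale during burn-in only
(step (k+1)^-0.6, target acceptance 0.44) and are frozen afterwards,
preserving ergodicity.  Initial states are overdispersed across chains:
intercept and coefficients jittered around 0, random effects iid
Normal(0, 0.01), variances near 0.01 with chain-specific log-normal jitter.
Chains are seeded independently via `SeedSequence.spawn`, so runs are
bit-reproducible under a fixed seed.  Defaults are 3 chains of 500,000
iterations with 50,000 burn-in and thinning 10 (thinning bounds draw-file
size); tests and the acceptance script use 3 x 10,000-30,000, which the
recovery experiments show is sufficient at the default problem size
(12 areas x 4 years).

Two validation-oriented run modes exist on `run_chains`: `prior_only`
switches the likelihood off (the improper-flat intercept is held fixed and
variances frozen) so prior moments can be recovered; `fix_random_effects`
pins all random effects at zero, leaving a 2-4 parameter GLM whose posterior
is checked against dense-grid integration (total variation below 2% per
marginal).

## Outputs

- Posterior summaries: pooled-chain mean, SD, equal-tailed 95% percentile
  credible interval (WinBUGS convention, not HPD), and Monte Carlo error by
  batch means with ceil(sqrt(n)) batches.  The reporting rule flags any
  parameter whose MC error reaches 5% of its SD; it is a flag, not a filter.
- Convergence: classic Brooks-Gelman-Rubin potential scale reduction factor
  per parameter (cross-checked against `arviz` in the test suite).
- DIC = Dbar + pD with pD = Dbar - D(theta_bar); D(theta_bar) plugs in the
  posterior means of every parameter on the natural scale (not the mean RR
  surface), matching WinBUGS behaviour.  The full Poisson deviance
  (including log O! terms) is used so model variants are comparable.
- Exceedance probabilities P(RR_it > 1 | data) per area-year; sign
  probabilities for coefficients with the 90% relevance flag; multiplicative
  covariate effects exp(beta * dX) with the percent change rounded to an
  integer for reporting.
- Differential trends: posterior mean and CrI of delta_i and of the local
  trend gamma + delta_i, plus a sign classification by posterior mean.
- Residual diagnostics: y_it = O_it - E_it * RRhat_it with RRhat the
  posterior-mean risk, and the space-time Moran index

      MoranSTI = (NT - N) * sum_{t>=2} z_t' W z_{t-1}
                 / ( [(T-1) sum_ij w_ij] * sum_it z_it^2 ),   z = y - ybar

  with binary, temporally invariant, non-row-standardized contiguity
  weights and ybar the grand mean over all N*T cells.  Whether the self-lag
  pair (area i at t with itself at t-1) belongs in W is genuinely ambiguous
  for a Durbin-Watson/Moran hybrid; both conventions are implemented
  (`include_self_lag`, default off = strictly neighbor-based) and the choice
  is recorded in the result.

## Synthetic data

`simulate_panel` runs the model generatively on a rook-contiguity lattice
(3x4 by default, matching the 12-unit study region): ICAR draws for U and
delta (via the Laplacian eigenbasis, covariance sigma2 * pinv(L), component
sums exactly zero), iid Normal V, uniform covariates over the study's
summary ranges (injury rate 21.0-50.5 per 100,000 including the lag-source
year, body fat 50.1-68.5%), per-area populations uniform over
376,696-1,516,887 and held constant across years (the panel and model
support per-year populations; constancy is the simulated special case), and
provisional expected counts E = population * baseline_rate with
baseline_rate = 9.2e-5, which puts E in the study's 30-140 count range with
mean ~80.

What it does not emulate: spatial autocorrelation of the covariates
themselves, population age structure, or the true contiguity geometry —
passing recovery tests therefore demonstrates correctness of the inference
machinery under the model, not robustness to real-data violations of it.

A fitter using internal standardization estimates the intercept relative to
the realized pooled rate, not the baseline rate; the truth record therefore
carries `alpha_standardized = alpha + log(baseline_rate / Rbar_hat)` — an
exact identity, used by the recovery tests so intercept coverage compares
like with like.  Slopes, trend and random effects are unaffected.

## Numerical choices and limitations

- Degenerate inputs are rejected loudly: all-zero counts (pooled rate 0),
  incomplete panels, asymmetric adjacency, T = 1 or constant residuals for
  the Moran index.  Non-finite Metropolis ratios reject the proposal and
  increment a warning counter.
- The equal-tailed CrI and the batch-means MC error are estimator choices;
  both are standard and validated against iid sampling in the tests.
- Single-site random walks mix adequately at the default problem size but
  would be slow for hundreds of areas; no gradient-based sampler is
  provided.
- Frequentist coverage of the credible intervals is exactly nominal for the
  slopes and, when the generative truth contains no random effects, for every
  fixed effect (z-score calibration checks).  When the truth holds the
  differential-trend field at a fixed nonzero draw, the interval for the mean
  trend gamma covers that fixed truth slightly below nominal (~85-90% at
  N=12, T=4): hierarchical shrinkage attributes part of the realized trend
  heterogeneity to the delta field, so the posterior spread of gamma
  understates the fixed-truth sampling spread.  This is the usual gap between
  fixed-truth and prior-averaged coverage in hierarchical Bayes, not a
  sampler artifact — the sampler itself is validated against
  grid-integration, prior-moment and conjugate-posterior oracles.
- No analytic significance test for the space-time Moran index is offered;
  the test suite uses permutation and simulation nulls instead.
- No polygon/choropleth handling: outputs are tables keyed by area and year.
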