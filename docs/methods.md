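# Methods

## Model

A meta-analysis of N studies reports effects `y_1..y_N` (log odds ratios
or mean differences) with standard errors `SE_1..SE_N`, assumed known.
The likelihood is `y_i ~ N(theta_i^B, SE_i^2)`, where the *biased study
effect* decomposes as

    theta_i^B = theta_i + I_i * beta_i .

The bias-corrected effect follows the model of interest
`theta_i ~ N(mu_theta, tau_theta^2)`; `I_i ~ Bernoulli(pi_B)` flags bias;
and `beta_i` is the study's bias.  Heterogeneity is thereby split into
diversity (`tau_theta`) and bias.  Three bias distributions define the
three fitters:

* none (`pi_B = 0`): the normal-normal random effects model;
* `beta_i ~ N(mu_beta, tau_beta^2)`: parametric bias correction;
* `beta_i ~ G`, `G ~ DP(alpha, N(mu_beta, tau_beta^2))`: the
  nonparametric model.  The DP realization is discrete,
  `G = sum_k w_k* delta(beta_k*)`, so biased studies share bias atoms and
  cluster; `E[G] = N(mu_beta, tau_beta^2)` and pointwise
  `Var G(A) = G0(A)(1 - G0(A))/(alpha + 1)`.

### Truncation calculus

The DP is truncated at K stick-breaking components
(`q_k ~ Beta(1, alpha)`, `w_k = q_k prod_{j<k}(1-q_j)`, last weight = the
leftover stick).  The expected mass beyond K-1 breaks is
`(alpha/(1+alpha))^(K-1)`; requiring it to be at most `epsilon` gives
`K = ceil(1 + log(epsilon)/log(alpha/(1+alpha)))`, and at the working
default `epsilon = 0.01` the convenient rule `K ~ 1 + 5 alpha`.  The
uniform prior `alpha ~ U(0.5, alpha_max)` is bounded above by requiring
the maximum cluster count `1 + 5 alpha_max` not to exceed the prior
expected number of biased studies `N a0/(a0+a1)`, i.e.
`alpha_max = (N a0/(a0+a1) - 1)/5`.  `alpha_min = 0.5` avoids numerically
degenerate stick weights.  K rounds half away from zero; `alpha_max` is
used unrounded when deriving K.

### Hyperpriors (defaults, and why)

| parameter | prior | default | rationale |
|---|---|---|---|
| `mu_theta` | `N(0, sigma_mu^2)` | `sigma_mu = 1e6` | locally flat on the log-OR scale |
| `mu_beta` | `U(b_lower, b_upper)` | `(-15, 15)` | bias of unknown direction; `(0, 15)` for exaggeration-only sensitivity analyses |
| `1/tau_theta^2` | scale-gamma(S, df) | `S = 0.5, df = 1` | induces half-Cauchy(0.5) on `tau_theta`: P(tau < 0.5) = 0.5, P(tau > 2) = 0.16, plausible for log-OR and mean-difference scales |
| `1/tau_beta^2` | scale-gamma(S, df) | `S = 0.5, df = 1` | same scale for the bias component |
| `pi_B` | `Beta(a0, a1)` | `(0.5, 1)` | mean 1/3 with a spike at zero: bias correction switches itself off when unnecessary |
| `alpha` | `U(0.5, alpha_max)` | from the bound above | ties model complexity to the prior bias expectation |

`elicit_beta(median, q90)` converts a quality judgement ("about m of the
studies are at risk, more than q would surprise us") into `(a0, a1)` by
two-dimensional root finding on the incomplete-beta inverse in log-shape
space, started from a normal moment match; residuals are driven below
1e-6 in quantile units.

## Sampler

A blocked Gibbs sampler over the truncated stick-breaking representation;
no external MCMC engine.  Per sweep:

1. `(I_i, L_i)` jointly: one categorical over {unbiased} and the K atoms
   with masses proportional to `(1-pi_B) N(y_i; theta_i, SE_i^2)` and
   `pi_B w_k N(y_i; theta_i + beta_k*, SE_i^2)`;
2. `theta_i`: conjugate normal;
3. atoms `beta_k*`: conjugate normal from member residuals (unoccupied
   atoms refresh from the base measure);
4. `q_k ~ Beta(1 + n_k, alpha + sum_{j>k} n_j)`; the last weight is the
   residual stick, so the weights sum to one in every draw;
5. `mu_theta` conjugate; precisions via the Huang-Wand auxiliary
   representation of the scale-gamma prior (`lam | a ~ Gamma(df/2, df/a)`,
   `a ~ InvGamma(1/2, 1/S^2)`), which keeps every update conjugate;
6. `mu_beta`: truncated-normal (uniform prior bounds) by inverse CDF;
7. `pi_B ~ Beta(a0 + m, a1 + N - m)`;
8. `alpha`: truncated `Gamma(K, -sum log(1-q_k))` on
   `[alpha_min, alpha_max]` by inverse CDF.

Chains run in lockstep as one vectorized state from a single seeded
generator, so a fit is bit-reproducible from `(data, priors, mcmc)`.
Initialization: `mu_theta` at the inverse-variance-weighted mean;
`tau_theta`, `tau_beta` at half the sample SD of `y`; initial bias flags
on studies more than 2.5 core-SDs from the *shortest-half* (shorth) core
of the effects — the shorth keeps a 50% breakdown point, so the
initializer still finds a clean core when up to half the studies are
contaminated, which an interquartile fence does not.  Initialization
affects only the starting state, not the stationary distribution.
Split-R-hat (threshold 1.05, warn-only) and effective sample size are
reported for the key hyperparameters.

Defaults are 4 chains x 50,000 iterations with 10,000 burn-in
(`McmcConfig()`); `McmcConfig.fast()` is 4 x 5,000 with 1,000 burn-in.
A full-length nonparametric fit of an 18-study table takes ~15 s on one
CPU.

## Identifiability — read before trusting a point estimate

The bias-corrected posteriors can be **weakly identified**.  Because a
biased study's likelihood is explained through `theta_i + beta_i` with a
wide uniform prior on the bias location, there is a near-flat ridge in
which (almost) every study is flagged biased and `mu_theta` and `mu_beta`
trade off over the whole prior box; with an informative Beta prior on
`pi_B` the prior probability of the all-biased state is not small (e.g.
`E[pi^18] ~ 0.13` under Beta(8.6, 1.97)).  Separately, in balanced
contamination settings (half the studies shifted) a *mirror* mode — the
shifted group treated as clean and the clean group as negatively biased —
and a *diffuse* mode (no flags, inflated `tau_theta`) compete with the
correct labelling; the stick-weight and indicator-prior costs of flagging
many studies largely cancel the likelihood gain.

Consequences for practice, all verified against an independent
JAGS implementation of the same equations during development:

* pooled-effect summaries from a single chain set are mode-lottery
  estimates; this package therefore reports medians over independent
  replicate fits where a stable number is needed (`scripts/acceptance.py`
  does this for the case-study posteriors);
* per-study bias probabilities and the occupied-cluster count are far
  more stable across modes than `E[exp(mu_theta)]`;
* restricting the bias direction (`mu_beta >= 0`) and eliciting
  `pi_B` from real quality information removes much of the degeneracy and
  is strongly recommended;
* always inspect the delta diagnostic (below), split-R-hat, and a
  sensitivity analysis over the bias priors.

## Postprocessing

* `summarize`: mean, SD, median, equal-tailed 95% interval, split-R-hat,
  ESS; transformed scales (e.g. `exp(mu_theta)`) are computed draw-wise
  and then summarized.
* `prob_bias`: `P(I_i = 1 | data)` as the mean of indicator draws.
* `cocluster`: the same-cluster probability matrix `S` (label equality
  averaged over draws; label 1 = unbiased cluster, 2..K+1 = atoms) and
  dissimilarity `D = 1 - S`; invariant under atom relabeling.
  `cluster_heatmap_order` applies complete-linkage agglomerative
  clustering to `D` for heatmap ordering.
* `occupied_clusters`: per draw, the number of distinct atoms among
  currently-flagged studies (0 if none).  This — not the truncation level
  and not the raw atom count — is the reading under which "number of bias
  clusters" has a data-driven posterior.
* `delta_diagnostic`: draws of `Delta = mu_beta - mu_theta` paired with
  `pi_B`; correction is deemed unnecessary when the 95% interval of
  `Delta` overlaps the posterior mean of `2 tau_theta` (bias
  indistinguishable from diversity).
* `forest_data`: per study, paired summaries of `theta_i^B` and
  `theta_i` plus the bias probability, for two-row forest plots.  Biased
  studies' corrected effects are wider than their raw effects — the price
  of bias correction.

## Synthetic data

`simulate_scenario` generates log-OR meta-analyses from
`theta_i ~ N(mu, tau^2)`, `y_i ~ N(theta_i, sigma^2/n_i)`,
`SE_i = sigma/sqrt(n_i)`, with sizes `n_i` resampled with replacement
from a realistic pool (the embedded 18-study COVID sizes for N = 20
runs; a packaged surrogate pool, log-uniform on [40, 1200], for N = 30
runs).  Defaults: `mu = 1`, `tau = 0.5` (fairly high heterogeneity on the
log-OR scale), `sigma = 4.95` (the within-study SD implied by the
case-study data).  A configured number of studies receives a
deterministic planted shift at mild / large / extreme outlier fences,
`Q3 + {1.5, 2.25, 3.0} x IQR` of the marginal `N(mu, tau^2 +
sigma^2/n_bar)` with `n_bar` the realized mean size.  The scenario grid
crosses N in {20, 30} with 0/10/30/50% biased studies.

What the generator does *not* emulate: non-normal within-study
likelihoods (it bypasses 2x2 tables entirely), correlated biases,
small-sample SE uncertainty, and publication bias.  Passing tests on this
generator therefore demonstrate correct inference *under the model's own
assumptions*, not robustness to real-data violations of them.

`oracle_subset` drops the studies known (by ground truth) to be biased —
the unattainable benchmark; `run_model_comparison` fits all four
comparators (random effects, oracle, parametric, nonparametric) on one
replicate.

## Scaled-down evaluation sizes

The test suite exercises the full 4 x 50,000 settings only for the
embedded 18-study case study; simulation-based checks run at 4 x 5,000
(the reduced profile) with 5 replicates per scenario and majority voting
on replicate-level properties, and the interval-coverage check uses 20
zero-bias replicates at 2 x 3,000.  These sizes are the package's chosen
trade-off between Monte-Carlo error and turnaround; the full grid
(8 scenarios x 4 models at full length) is available through
`scenario_grid` and the CLI but is not run by default.

## Known limitations

* The weak identifiability described above is a property of the model,
  not of the sampler; no MCMC scheme can make the all-biased ridge
  disappear.  Treat unrestricted-bias fits as sensitivity analyses.
* Standard errors are taken as known; very small studies violate this.
* The truncation level K is fixed per fit (no adaptive truncation).
* Effects must arrive pre-aggregated (estimate + SE); cell counts are out
  of scope.
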