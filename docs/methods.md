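# Methods

## The problem

In observational survival analysis, an unmeasured confounder that affects
both a continuous exposure `A` and the time-to-event outcome biases the
hazard ratio from a Cox proportional hazards fit. `dpgbcox` implements a
nonparametric Bayesian estimator for the setting where the unmeasured
confounding has a *latent cluster* structure: subjects fall into unknown
groups, and group membership shifts both the exposure distribution and the
baseline hazard.

## Model

For subject i with survival time `T_i`, event indicator `delta_i`, exposure
`A_i`, and covariates split into common predictors `Z_i` and within-cluster
covariates `V_i`:

- exposure: `A_i | s_i = k ~ N(alpha0_k + Z_i' alpha_z + V_i' alpha_v_k, sigma2_k)`
- outcome: `lambda_i(t) | s_i = k = lambda0_k(t) exp(A_i beta_a + Z_i' beta_z + V_i' beta_v)`

The latent labels `s_i` follow the random partition induced by a Dirichlet
process with precision `gamma` (the Chinese restaurant process): a subject
joins an existing cluster with probability proportional to its size, or opens
a new cluster with probability proportional to `gamma`. Cluster-wise
parameters are drawn from the base measure `G0` (normal / inverse-gamma
priors below). `beta_a` is the target log hazard ratio; the cluster-specific
baseline hazards `lambda0_k` absorb the confounding.

Because the baseline hazards are unspecified, the outcome contributes through
the *clustered Cox partial likelihood*: within cluster k, an event subject
contributes `exp(lp_i) / sum_{j in R_k(T_i)} exp(lp_j)` with cluster-wise
risk sets `R_k(t) = {j : s_j = k, T_j >= t}` (at-risk convention closed at t;
Breslow handling of ties). Raising this loss to a scale `eta`
(`learning_rate`, default 1) and combining it with the priors and the
exposure likelihood yields a general-Bayes (Gibbs) posterior: a coherent
belief update that never requires modelling `lambda0_k`.

## Posterior computation

One Gibbs sweep updates:

1. `alpha_z` — conjugate multivariate normal (heteroscedastic weighted
   regression of the cluster-residualized exposure on Z);
2. `(alpha0_k, alpha_v_k)` per cluster — conjugate normal;
3. `sigma2_k` — conjugate inverse gamma `IG(a + N_k/2, b + RSS_k/2)`
   (shape/scale convention, density ∝ x^(−a−1) e^(−b/x));
4. cluster assignments — sequential CRP draws with Neal's algorithm-8
   auxiliary components (`m_aux = 3` fresh `G0` draws score the new-cluster
   option; a singleton's current parameters occupy the first slot);
5. `gamma` — the Escobar–West beta-auxiliary two-component gamma mixture,
   an exact draw from `p(gamma | K, n)` under the `Ga(a_gamma, b_gamma)`
   prior (default a = b = 1);
6. `beta = (beta_a, beta_z, beta_v)` — adaptive random-walk Metropolis on
   `eta * partial log-lik + log prior`, with normal priors on `beta_a`,
   `beta_v` (mean 0, variance 100) and an independent Laplace(0, 1)
   shrinkage prior on each `beta_z` coordinate. The proposal covariance and
   scale adapt during burn-in only (Robbins–Monro toward ~30% acceptance
   plus empirical-covariance estimation), so the retained chain is a valid
   fixed-kernel Metropolis sampler.

Which of `{alpha0, alpha_v, sigma2}` are cluster-specific is configurable.
Shared components are folded into an equivalent global model: a shared
intercept becomes a column of Z, shared `alpha_v` appends V to Z, shared
`sigma2` pools all residuals into one inverse-gamma update. The
intercept-only configuration (`cluster_specific=("alpha0",)`) reproduces the
minimal clustering model.

### The assignment rule (a deliberate design choice)

Read factor-by-factor, the joint posterior suggests a full conditional for
`s_i = k` proportional to `CRP weight x l_ik(beta)^eta x phi(A_i | k)`. We
implemented that rule (`assignment_rule="own_factor"`) and the exact
alternative that uses the full change in the clustered partial likelihood
(`"exact_ratio"`, verified against brute-force recomputation). Both are
unusable as defaults: the partial likelihood of a partition is *maximized by
singleton clusters* (every factor becomes 1 when the risk set is the subject
itself), so the uncut posterior rewards ever-finer partitions. At n = 600
the reward (~thousands of nats) dominates the CRP and base-measure
penalties, the learned `gamma` rises with the cluster count, and the
partition degenerates (K drifts above 70 from any initialization, including
the true partition).

The default is therefore a *cut* (modular) rule, `"exposure_only"`: the
partition is driven by the CRP prior and the exposure likelihood — a
standard Dirichlet-process mixture of regressions — and the Cox partial
likelihood informs `beta` given each sampled partition. This keeps cluster
detection well-posed, propagates partition uncertainty into the `beta`
posterior, and matches the intended behaviour (near-infeasible point
estimates, conservative coverage). The uncut rules remain available for
study.

### Initialization and mixing

Dirichlet-process samplers merge clusters far more readily than they split
them; started from a single cluster the chain reliably stalls below the true
cluster count because new-cluster births require an auxiliary draw from the
vague base measure to land inside the data range. The sampler therefore
starts from `init_clusters = 8` exposure-quantile bins and lets burn-in
prune the surplus (set `init_clusters=1` for the single-cluster start).
Default chain: 4000 sweeps, 2000 burn-in; `n_mh_steps` Metropolis steps for
`beta` per sweep (default 1; the replication studies here use 5).

### Summaries

Point estimate = posterior mean of `beta_a`; interval = equal-tailed 95%
credible interval; the hazard ratio is `exp` applied to the log-scale
summaries (a documented convention, not the posterior mean of `exp`).
A representative clustering reduces each subject to the posterior median of
its cluster's `alpha0` and splits the sorted medians at the largest gaps;
the default is a two-group split, `n_groups="modal_k"` uses the posterior
modal cluster count (what the cluster-recovery checks use, since the
synthetic truth has three groups). Breslow cumulative-hazard post-processing
(`breslow_cumhaz`) is descriptive only: it plugs posterior draws of `beta`
into the classical estimator and carries no posterior uncertainty statement.

## Comparator estimators

All built on the same Newton partial-likelihood solver (`fit_cox_mle`:
step-halving, convergence at max |grad| < 1e-8 or relative log-lik change
< 1e-10, observed-information covariance, Wald intervals, constant columns
pinned at zero with infinite variance):

- **naive** — unstratified Cox of (a, z, v);
- **infeasible** — Cox of (a, z, v) stratified by the *true* cluster label;
- **2SLS** — OLS of A on (1, Z), then Cox with the fitted values replacing A;
- **2SRI** — same first stage, then Cox of (a, v, r-hat).

The instrument Z is excluded from the IV stage-2 models: with the OLS
identity `a = alpha0 + z alpha_z + r`, including z alongside A-hat (or
alongside a and r-hat) makes the design exactly rank-deficient. A
consequence worth knowing: with a linear homoscedastic first stage the 2SRI
coefficient on `a` is numerically the 2SLS coefficient (the control-function
and IV estimators coincide in a linear index), so the two methods track each
other here, including the weak-instrument variance explosion. Two-stage
standard errors carry no generated-regressor correction; replication metrics
are based on the empirical spread across replicates.

## Synthetic data generator

`scenario_params(setting, scenario)` fixes a versioned parameter table:

- latent label ~ Multinomial(1/2, 1/3, 1/6); Z ~ Gamma(shape 2, rate 2)
  (mean 1); V ~ Bernoulli(0.5); exposure SD 0.5; true log-HR
  `beta_a = −0.1`; `beta_z = 0` (the common predictor satisfies the
  exclusion restriction, keeping the IV comparators well-posed);
  `beta_v = 0.2`.
- common-predictor strength: `alpha_z` = 1.0 (strong: scenarios a, c) or
  0.1 (weak: b, d).
- confounder strength: cluster spread of `alpha0` = (−2.5, 0, 2.5) (strong:
  a, b) or (−0.625, 0, 0.625) (weak: c, d); `alpha_v` spread (−0.4, 0, 0.4)
  or (−0.1, 0, 0.1). The `alpha_v` spread is kept below the `alpha0` gaps
  so the six (cluster, V) exposure means group by cluster instead of
  interleaving — with the exposure SD of 0.5 the strong-confounder clusters
  sit 5 SD apart, which is what makes the latent structure identifiable.
- outcome: cluster-specific Weibull baseline hazards, shape 1.5, scales
  (1.24, 1.0, 0.825) in the "easy" setting and (0.955, 1.0, 1.04) in
  "hard". The easy scales were calibrated once so that a large-n naive Cox
  fit is biased by about +0.11 on the log-HR scale (the high-exposure
  cluster has the highest hazard); the hard scales reverse the ordering
  mildly (naive bias about −0.02), mimicking the sign pattern of the two
  settings.
- censoring: exponential, rate solved per scenario by root-finding on
  `E[1 − exp(−r T)] = 0.125` with a fixed calibration seed, yielding
  10–15% censoring everywhere.

What the generator does *not* emulate: covariate measurement error,
time-varying exposures or effects, competing risks, non-cluster (continuous)
unmeasured confounding, and exclusion-restriction violations. Passing tests
therefore speak to the latent-cluster confounding mechanism, not to these
other departures.

## Replication harness and problem sizes

`replicate_study` runs a grid of (setting, scenario, n) cells with common
random numbers across methods (per-replicate seeds derived from the base
seed via a CRC-tagged `SeedSequence`, all below 2^31) and reports bias,
empirical SD (denominator R−1), RMSE, and 95% coverage against
`beta_a = −0.1`; failed replicates are excluded and counted. The shipped
experiment sizes are chosen to keep a full run short: the infeasible-
estimator experiment uses the study's full 200 replicates at n = 600; the
proposed-sampler checks use 5 replicates of 1200 sweeps (400 burn-in) at
n = 600, and the comparator-ordering checks 50 replicates. The sampler's
per-replicate posterior-mean Monte-Carlo error at this chain length is small
relative to the acceptance bands; larger R mainly tightens the bias
estimate.

## Known limitations

- The uncut general posterior's partition degeneracy (above) is a property
  of the model as written, not of the sampler; the cut default sidesteps it.
- The 2SRI/2SLS numerical coincidence means the harness cannot reproduce a
  2SRI that is simultaneously stable under weak instruments and distinct
  from 2SLS; a frailty-based 2SRI variant would be needed.
- Wald/credible intervals only; no robust variances, no Efron ties, no left
  truncation, competing risks, or time-varying covariates.
- Label switching is handled only through the `alpha0`-median representative
  clustering; per-cluster posterior summaries beyond `alpha0` are not
  relabelled.
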