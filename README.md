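# dpgbcox

Hazard-ratio estimation for continuous exposures when an **unmeasured
confounder has a latent cluster structure**. Subjects belong to unknown
groups that shift both their exposure distribution and their baseline
hazard; ignoring the groups biases the Cox log hazard ratio. `dpgbcox`
couples a **Dirichlet-process mixture** over subject-level exposure/outcome
parameters with a **general-Bayes posterior** built from the clustered Cox
partial likelihood, so the number of clusters is learned from the data and
the baseline hazards never need to be modelled.

For subject i in latent cluster k:

```
A_i | s_i=k  ~  N(alpha0_k + Z_i' alpha_z + V_i' alpha_v_k,  sigma2_k)
lambda_i(t) | s_i=k  =  lambda0_k(t) exp(A_i beta_a + Z_i' beta_z + V_i' beta_v)
```

with `s ~ CRP(gamma)` and cluster parameters from a base measure `G0`.
The target is `beta_a`, the log hazard ratio of the exposure. Inference is a
Gibbs sampler: conjugate updates for the exposure model, Chinese-restaurant
assignment updates with algorithm-8 auxiliary components, an Escobar–West
update for `gamma`, and adaptive Metropolis for `beta` under
`exp{eta * clustered partial log-likelihood} x prior`. Frequentist
comparators (naive Cox, infeasible stratified Cox, 2SLS, 2SRI), a
confounded-survival data generator, and a Monte-Carlo replication harness
are included. See `docs/methods.md` for the model, numerical choices, and
limitations.

Intended users: biostatisticians and epidemiologists studying
exposure–outcome effects in observational cohorts (e.g., Mendelian-
randomization-style analyses) where confounding may arise from discrete
latent strata such as population structure or behavioural subgroups.

## Worked example

```python
from dpgbcox import (scenario_params, generate_dataset,
                     DPGeneralBayesCox, NaiveCox, InfeasibleCox, adjusted_rand)

cfg = scenario_params("easy", "a")          # strong predictor, strong confounder
ds, truth = generate_dataset(cfg, n=600, seed=12)

naive = NaiveCox().fit(ds)
infeasible = InfeasibleCox().fit(ds, truth.labels)
proposed = DPGeneralBayesCox(n_iter=1200, n_burn=400, seed=12,
                             n_mh_steps=5).fit(ds)

print(f"true log-HR        -0.100  (HR {0.905:.3f})")
print(f"naive Cox          {naive.coef_:+.3f}")
print(f"infeasible Cox     {infeasible.coef_:+.3f}")
print(f"proposed (DP-GB)   {proposed.coef_:+.3f}  "
      f"CI ({proposed.conf_int_[0]:+.3f}, {proposed.conf_int_[1]:+.3f})")
print(f"clusters found     {proposed.summary_['n_clusters_mode']}, "
      f"ARI vs truth {adjusted_rand(proposed.clustering_, truth.labels):.2f}")
```

Output (seed 12):

```
true log-HR        -0.100  (HR 0.905)
naive Cox          +0.010
infeasible Cox     -0.095
proposed (DP-GB)   -0.118  CI (-0.277, +0.042)
clusters found     3, ARI vs truth 0.99
```

The naive fit is pulled to ~0 by the cluster confounding (bias ≈ +0.11); the
proposed estimator recovers the three latent clusters without being told
they exist and lands near the infeasible benchmark, with a credible interval
whose width reflects partition uncertainty.

A command-line interface mirrors the library:

```bash
dpgb-cox simulate --setting easy --scenario a --n 600 --seed 1 --out data.csv
dpgb-cox fit --data data.csv --seed 1 --out fit
dpgb-cox compare --data data.csv --methods naive,2sls,2sri --out est.csv
dpgb-cox study --config study.yaml --out results/
```

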