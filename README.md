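# gutspulse

Toxicokinetic–toxicodynamic (TKTD) modelling of zebrafish-embryo toxicity
with gene-expression pulses as the damage state. The package is aimed at
ecotoxicological modellers who have fragmented time-series data — internal
concentrations, *nrf2* fold-changes and survivor counts measured in
*different* treatments — and want to calibrate a mechanistic survival model
jointly on all of them.

## The model

The core model (`guts_rna_pulse`) is a GUTS stochastic-death model in which
the abstract damage state is replaced by the *nrf2* fold-change `R`.
Internal concentration activates transcription through a threshold sigmoid;
the expression pulse drives a slow protein proxy `P*` that metabolizes the
chemical (a negative feedback that makes damage reversible under constant
exposure); and the fold-change itself drives the hazard:

    dC_i/dt = k_i C_e − k_m P* C_i
    dR/dt   = r_rt · a(C_i / C_i,max) − k_rd · max(0, R − R_0)
    dP*/dt  = k_p (R − P*)
    dH/dt   = k_k · max(0, R − z) + h_b,        S = exp(−H)

with `a(c) = 1 / (1 + exp(−v_rt (c − z_ci)))` and `R_0 = 1` (fold-change
units). Three standard comparison variants are included (`guts_reduced`,
`guts_scaled_damage`, `guts_rna`) together with:

- log-normal error models for concentrations/fold-changes and a
  conditional-binomial (≡ multinomial) survival likelihood, summed into one
  joint likelihood over arbitrarily fragmented observation tables;
- Bayesian multi-start inference (uniform-interval initializers transformed
  to log-normal prior scales; L-BFGS-B mode search; MCMC or a Gaussian
  mode approximation for draws) behind a scikit-learn-style estimator;
- parameter sharing across substances (substance-specific uptake
  `k_i, k_m, z_ci`, shared RNA/protein/death module) and BIC comparison;
- a posterior-cluster diagnostic for identifiability issues;
- a synthetic study-design generator that reproduces the fragmented,
  unbalanced multi-endpoint structure such data sets have.

See `docs/methods.md` for assumptions, priors, numerics and limitations.

## Worked example

```python
import gutspulse as gp

# a single-substance synthetic study with known ground truth
bundle = gp.make_benchmark("toy", seed=1)

model = gp.GutsModel(variant="guts_rna_pulse", sharing="specific",
                     engine="mcmc", n_starts=4, draws=600, seed=1,
                     scaling=bundle.truth.scaling)
model.fit(bundle.observations)
print(model.result_.summary().round(4))
print(f"log-likelihood {model.loglik_:.1f}, BIC {model.bic_:.1f} "
      f"(k={model.result_.k_params}, n={model.n_obs_})")
```

Output:

```
                    lower   median     upper
k_i[substance_1]   0.4965   0.5428    0.5949
k_m[substance_1]   0.3189   0.3478    0.3799
z_ci[substance_1]  0.2557   0.2976    0.3421
v_rt[substance_1]  9.5077  11.2579   14.3214
r_rt[substance_1]  5.4274  20.8594  100.8531
k_rd[substance_1]  2.0316   7.5792   39.4329
k_p[substance_1]   0.0137   0.0198    0.0337
z[substance_1]     1.8549   2.1954    2.6925
k_k[substance_1]   0.0324   0.0667    0.1418
h_b[substance_1]   0.0002   0.0010    0.0024
sigma_cint         0.0838   0.1004    0.1157
sigma_nrf2         0.0818   0.0990    0.1328
log-likelihood -23.3, BIC 102.2 (k=12, n=102)
```

The 95% credible intervals bracket the generating values (uptake
`k_i = 0.5`, hazard threshold `z = 2` fold-change, killing rate
`k_k = 0.05`). The wide, correlated intervals on `r_rt` and `k_rd` are the
model's characteristic identifiability ridge: the data pin down the pulse
equilibrium `r_rt/k_rd` (here median 20.9/7.6 ≈ 2.75 against a true ratio
of 2.5) much better than either rate alone — inspect it with
`gp.detect_posterior_clusters(model.result_)`. Credible envelopes for the
fitted trajectories (parametric uncertainty only, no residual error) come
from `model.predict_interval(scenario)`.

The same workflow is available from the shell:

```bash
gutspulse generate --preset toy --seed 1 --out bundle/
gutspulse validate bundle/observations.csv
gutspulse fit --observations bundle/observations.csv \
    --variant guts_rna_pulse --sharing independent \
    --engine variational --n-starts 100 --seed 1 --out run/
gutspulse compare run/ other_run/
```

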