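# ctsridge

Cell-type-specific differential methylation and expression analysis from
**bulk** tissue data, using nonlinear ridge regression.

## The problem

EWAS and differential-expression studies are mostly run on bulk tissue, a
mixture of cell types. Given the cell-type composition `W` of each sample
(imputed upstream from reference profiles), cell-type-specific trait effects
are classically estimated with interaction regressions:

- **full model** — `Y_i = Σ_h α_h W_hi + Σ_{h,k} β_hk W_hi X_ik + Σ_l γ_l C_il + ε_i`,
  all cell types jointly;
- **marginal model** — the same, but with interaction terms for one tested
  cell type at a time.

Two things go wrong. First, mixing is physical and happens on the **linear**
scale (beta-values, read proportions), while differential signal is
well-behaved on the **logit** (M-value) or **log** scale — a single linear
regression cannot respect both. Second, the interaction terms `W_h X` are
almost collinear whenever the coefficients of variation (CV) of the
proportions are small, which is the rule in tissues with controlled
composition:

    Cor[W_h X, W_h' X] = (Cor[W_h, W_h'] · CV_h · CV_h' + 1)
                         / (√(CV_h²+1) · √(CV_h'²+1))  →  1  as CVs → 0.

`ctsridge` addresses both. The mean model mixes on the linear scale and
models effects on the normalized scale,

    μ_i = f( Σ_h W_hi · g(α_h + Σ_k β_hk X_ik) ) + Σ_l γ_l C_il,

with `f = logit` (methylation), `log` (expression) or identity, `g = f⁻¹`;
and the cell-type-specific effects β are estimated under a ridge penalty
`RSS + λ‖β‖²`. The penalty is chosen per marker from the SVD
`∂μ/∂β = U D Vᵀ` via a bias-corrected reciprocal-penalty statistic

    κ = (1/Σ d_m²) Σ_m { d_m² (v_mᵀ β̂(0))² / σ̂² − 1 },
    λ = 1/κ  if κ > 0,  else d₁²,

and coefficients are tested with a non-exact t-type test based on a
sandwich covariance with observed- or expected-Fisher weighting. The
package also ships the linear full/marginal baselines, a hybrid
marginal×full caller, a fast linear-ridge path for QTL scans, a synthetic
data generator with known ground truth, and a benchmarking harness
(signed calls, confusion subtotals, sensitivity/specificity/precision).

## Worked example

```python
import numpy as np
import ctsridge as cr

# 2,000 CpGs x 200 samples, 7 blood cell types, 5% of CpGs affected in one
# cell type at methylation OR 1.6
cfg = cr.methylation_config(n_markers=2000, n_samples=200, seed=7)
data, truth = cr.simulate_bulk(cfg)

fit = cr.fit_marker(data, "m000287", scale="logit", use_ridge=True)
print(f"kappa = {fit.kappa:.3f}  lambda = {fit.lambda_:.3f}")
print(fit.beta_table()[["cell_type", "estimate", "se", "statistic", "p"]].round(4))
```

prints

```
kappa = 1.996  lambda = 0.501
cell_type  estimate     se  statistic      p
      Neu    0.4405 0.0728     6.0545 0.0000
     CD4T   -0.1383 0.1858    -0.7442 0.4577
     CD8T    0.1019 0.1969     0.5174 0.6055
       NK    0.0262 0.1868     0.1400 0.8888
     Mono    0.2528 0.1508     1.6767 0.0952
    Bcell   -0.0831 0.1827    -0.4550 0.6496
      Eos    0.0002 0.0010     0.1891 0.8502
```

This CpG was generated with a true up-regulation of log(1.6) ≈ 0.47 in
neutrophils; the ridge fit estimates 0.44 there (t = 6.1) and keeps every
other cell type flat. Dataset-level runs and benchmarking:

```python
res = cr.fit_dataset(data, "nls.logit.ridge")
perf = cr.performance_table(res, truth, "fixed_p", 2.4e-7)
print(perf.round(3)[["cell_type", "sensitivity", "specificity", "precision"]])
```

```
cell_type  sensitivity  specificity  precision
      Neu          0.5          1.0        1.0
     CD4T          0.0          1.0        NaN
      ...          ...          ...        ...
```

At the stringent array-wide threshold the ridge fit calls half of the
neutrophil-affected CpGs with no false positives; rarer cell types carry
too little bulk signal at this effect size (precision is undefined where
nothing is called). The same pipeline runs from the shell:

```sh
ctsridge simulate --preset methylation --n-markers 2000 --seed 7 --out-dir run/
ctsridge fit --y run/Y.tsv --w run/W.tsv --x run/X.tsv \
         --method nls.logit.ridge --out-dir run/
ctsridge evaluate --results run/results_nls_logit_ridge.tsv \
         --truth run/truth.tsv --procedure fixed_p --threshold 2.4e-7
ctsridge diagnose --w run/W.tsv --x run/X.tsv --out-dir run/
```

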