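# Methods

## Model

For one marker, sample `i` has bulk level `Y_i` (linear scale), cell-type
composition `W_hi` (nonnegative, rows ≈ 1), centered traits `X_ik` with
cell-type-specific effects and centered covariates `C_il` with
tissue-uniform effects. On a normalizing scale pair `(f, g)` — identity,
log/exp, or logit/logistic — the mean is

    μ_i = f( Σ_h W_hi · g(α_h + Σ_k β_hk X_ik) ) + Σ_l γ_l C_il ,
    f(Y_i) = μ_i + ε_i ,   ε_i ~ N(0, σ²) i.i.d.

Cell-type levels are modeled on the normalized scale, mapped to the linear
scale with `g`, mixed with the composition weights, and mapped back with
`f`; covariate effects enter additively on the normalized scale. With the
identity scale this is exactly the classical full interaction regression,
and with a single cell type (or homogeneous `α, β` across cell types and
unit row sums of `W`) `f∘g` cancels and the model reduces to a simple
regression of `f(Y)` on `X` and `C`. The marginal baseline keeps all basal
columns but only the tested cell type's interaction terms; with constant
composition its β test equals the test of the simple normalized regression
(a constant multiplier cancels from the t statistic).

No probability model is placed on cell-type-specific expression itself:
`α_h + Σ β_hk X` is a representative level, and all randomness sits in the
bulk-level error.

## Ridge estimation (per marker, eight steps)

Trait effects are assumed much smaller than basal levels, so basal levels
are fit first for numerical stability:

1. fit `α` alone by (nonlinear) OLS under `β = γ = 0`; Wald-test it;
2. estimate `σ̂² = RSS/(n − H)` from those residuals (`H` = number of cell
   types); this value is used everywhere downstream;
3. fit `(β, γ)` by OLS with `α` frozen at step 1;
4. take the SVD `∂μ/∂β = U D Vᵀ` at the OLS solution;
5. compute `κ = (Σ_m {d_m²(v_mᵀβ̂(0))²/σ̂² − 1}) / Σ_m d_m²` and set
   `λ = 1/κ` if `κ > 0`, else `λ = d₁²`;
6. refit `(β, γ)` minimizing `RSS + λ‖β‖²`, `α` still frozen, warm-started
   at step 3;
7. form `Q(λ) = JᵀJ + λ·diag(1 on β) − Σ_i r_i H_i` with `J` the `(β, γ)`
   Jacobian, `r` the residuals and `H_i` the per-sample Hessian
   (observed-Fisher mode; the expected mode `Q*` drops the Hessian term),
   and `Var = σ̂² Q⁻¹ JᵀJ Q⁻¹`;
8. test each coordinate with `estimate/√Var_ss ~ t_df` (a non-exact t-type
   test; ridge estimators are not ML estimators).

The penalty never touches `α` or `γ`. The `κ` rule is a bias-corrected
Hoerl–Kennard-type choice: each singular direction's MSE-optimal penalty is
`λ_m = σ²/(v_mᵀβ)²`, and `κ` is an unbiased, `d_m²`-weighted estimate of
the average `1/λ_m`; the `−1` term removes the upward bias of plugging in
`β̂(0)`, and is kept because effects can be small in this application. With
all `d_m` equal, true `β` plugged in and the correction removed, `1/κ`
reduces to the classical harmonic-mean rule `Mσ²/‖β‖²`. `κ ≤ 0` (typical
for null markers) falls to the `d₁²` branch, a strong but finite penalty.

The bias/variance decomposition

    MSE[β̂(λ)] = Σ_m (λ/(d_m²+λ))² (v_mᵀβ)² + (d_m²/(d_m²+λ))² (σ²/d_m²)

is exposed as a diagnostic (`mse_decomposition`) and verified by Monte
Carlo in the test suite.

### Numerical choices

- **Minimizer.** A damped Gauss–Newton (Levenberg–Marquardt) loop on the
  residual vector, with the penalty absorbed as `M` pseudo-observations
  `√λ·β_m` targeting zero — the penalized problem is then ordinary
  nonlinear least squares. Analytic Jacobians throughout; relative cost
  tolerance 1e-8, at most 200 iterations; entirely deterministic (no
  restarts). On linear problems it converges in one accepted step and
  matches closed-form OLS/ridge to 1e-6.
- **Degrees of freedom.** The t-test uses `df = n − H` by default, matching
  the σ̂² of step 2; `df_mode="total"` selects `n − (H + HK + L)` instead.
- **Degenerate markers.** `σ̂² = 0` (a constant marker) makes κ undefined;
  the fit falls back to `λ = 0` and flags the marker.
- **Singular values.** Values below `1e-10·d₁` are treated as zero in the
  MSE variance terms (they contribute only bias); in κ every direction
  keeps its `−1` term, i.e. the selection statistic is used exactly as
  defined.
- **Domains.** Logit inputs are clipped into the open unit interval by at
  most `clip_epsilon = 1e-6` (clipping counts are logged); larger
  violations are errors naming the offender. `exp` arguments are saturated
  at ±700 to avoid overflow. Log-scale input is taken as given — any
  pseudo-count is the caller's preprocessing decision.
- **Rank deficiency** in the linear baselines yields minimum-norm estimates
  plus a flag, never an exception mid-dataset (near-zero cell types such as
  eosinophils make this a practical concern).
- **Frozen α.** Because steps 3–6 keep `α` at its basal-only estimate, the
  identity-scale no-ridge fit agrees with the jointly fitted linear full
  model only up to an `O(n^{-1/2})` coupling term; the joint fit is
  available via `ridge_minimize(..., frozen_alpha=False)` and matches OLS
  exactly.

## QTL fast path

For mQTL/eQTL scans the same trait design is reused across thousands of
SNPs, so the scan is linearized: per marker, `α` and `γ` are fit once by
OLS of `f(Y)` on `[W | C]` under `β = 0` and replaced by their residuals
(`σ̂²` and the test df use `n − rank([W|C])`); per SNP, `β̂(0)` is the OLS
of the residuals on the interaction design `W·x`, the penalty comes from
the spectrum/κ rule, and `β̂(λ)` with its t-test follows in closed form in
the SVD basis. Without covariates this reproduces the main identity-scale
path essentially exactly (the tests assert 1e-4 relative agreement);
monomorphic SNPs are emitted as flagged missing rows.

## Hybrid caller

`marginal.full005` combines the sensitive-but-unstable marginal model with
the conservative full model: for each (marker, cell type, trait), if the
two models agree in effect direction **and** the full-model coefficient has
p < 0.05, the marginal Z-score (recovered from its two-sided p and effect
sign) is retained; otherwise Z = 0, reported as p = 1. Zero estimates carry
no direction and count as disagreement.

## Simulation design

Half the samples are cases (`X = +0.5`), half controls (`−0.5`), split
exactly. A fraction `frac_de = 0.05` of markers receive an effect in one
cell type: `⌊n·frac_de/(2H)⌋` markers per (cell type, direction) stratum,
the remainder null. Per marker a baseline mean `μ` and noise `σ` are drawn
on the normalized scale; per sample and cell type a level is drawn from
`N(μ, σ²)` (`N(μ ± β, σ²)` in the affected cell type of cases), converted
to the linear scale with `g`, mixed with the composition and summed.
Effect sizes are log methylation odds ratios or log fold changes. In the
marker-gene scenario all non-target cell types contribute exactly zero (in
linear scale) at affected genes, for cases and controls alike.

Composition comes from a Dirichlet whose concentration is moment-matched
on the most abundant cell type, `s = m(1−m)/SD² − 1`, `α_h = mean_h·s`.
Default targets are two blood panels: a 7-cell-type methylation panel
(neutrophils 0.59 ± 0.11 down to eosinophils 0.01 ± 0.02; CVs 0.2–0.6
except eosinophils) and a 6-cell-type expression panel (granulocytes
0.53 ± 0.037; all CVs ≈ 0.1). Only the dominant cell type's SD can be
matched exactly — a single Dirichlet concentration fixes the remaining SDs
— which reproduces the qualitative CV regime rather than every marginal SD.

Baseline distributions are synthetic stand-ins chosen to mimic real
arrays: methylation logit-scale means from an equal-weight two-component
normal mixture at ∓2.2 (sd 1.0), reproducing the bimodal beta-value
distribution, with logit-scale σ uniform on [0.1, 0.5]; expression
log-scale means N(3, 2²) with σ uniform on [0.3, 1.0]. All are
configurable. Baseline `(μ, σ)` are shared across cell types within a
marker, and simulations carry no covariates by default. The whole dataset
is a pure function of the config, seed included.

What passing simulated benchmarks does **not** show: the generator has no
probe-level artifacts, no correlation between markers, no covariate
structure, no composition-trait dependence beyond sampling noise, and
exactly one affected cell type per marker — so results speak to the
estimation machinery under the stated regime, not to any particular array
or cohort.

## Evaluation

Calls are signed by the test statistic; a truly up-regulated marker called
down is a false positive even in its own stratum. Two calling procedures:
a fixed threshold (default `P < 2.4e-7`, an array-wide level for 450k-style
methylation panels) and Benjamini–Hochberg FDR (default 5%) applied within
each tested cell type. TP/TN/FP/FN are subtotaled by the truly associated
cell type plus a Null stratum and partition the marker set for every tested
cell type; sensitivity `TP/(TP+FN)`, specificity `TN/(TN+FP)`, precision
`TP/(TP+FP)` (reported missing when nothing is called). Metrics are
averaged over trials when summarizing. The marginal-model coefficient of
determination (`marginal_r2`) measures per-marker signal strength;
`R²/(1−R²)` is the signal-to-noise ratio.

## Problem sizes

The packaged benchmark (`scripts/acceptance.py`) uses 5 trials of 10,000
markers × 200 samples (methylation, OR 1.6) and 5 trials of 2,000 genes ×
200 samples (expression, FC 3.0 / 1.7), chosen so the whole run completes
in minutes on one CPU while leaving Monte-Carlo error well inside the
bounds being checked. The test suite uses smaller versions of the same
designs.

## Known limitations

- Per-marker failures are flagged and reported as missing rows, never
  raised, so a handful of non-converged markers in a large run is normal.
- The t-type test is approximate (ridge estimators are biased and not ML);
  under the null it is conservative, which is the safe direction for
  discovery but costs power.
- Composition is taken as known; uncertainty from upstream composition
  imputation is not propagated.
- One affected cell type per marker in the generator; homogeneous
  multi-cell-type effects are better served by the marginal model on
  normalized input (see the reduction noted above).
- The dataset driver is a sequential per-marker loop; results are
  independent of processing order, so external parallelization over marker
  blocks is safe.
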