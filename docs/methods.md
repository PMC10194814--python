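# Methods

## Model and score

Let `X(1..N)` be i.i.d. observations in `R^d` with density `p0`, and let
`{q(x|θ)}` be the parametric foreground model of interest applied to a linear
projection `x_F = Vᵀx` (`V` orthonormal). The normalized kernelized Stein
discrepancy between `p` and `q` is

```
NKSD(p‖q) = E_{X,Y~p}[ (s_q−s_p)(X)ᵀ (s_q−s_p)(Y) k(X,Y) ] / E_{X,Y~p}[ k(X,Y) ]
```

with `s_q = ∇_x log q` the Stein score. By the Stein identity it can be
rewritten so that `s_p` never appears; the estimator is the ratio of two
U-statistics over `i ≠ j` pairs of the Stein u-function

```
u(x,y) = s_q(x)ᵀs_q(y) k + s_q(x)ᵀ∇_y k + s_q(y)ᵀ∇_x k + tr(∇_x∇_yᵀ k).
```

The denominator normalization makes values comparable across spaces of
different dimension, and with a product kernel the discrepancy is additive
over independent subsystems — the two properties that allow foregrounds of
different dimension to compete on one scale.

The Stein volume criterion scores a candidate foreground (or model) as

```
log K = (m_B/2) log(2π/N) + log ∫ exp(−(N/T) NKSD̂(θ)) π(θ) dθ.
```

`m_B` is the *effective dimension* of the never-specified background model;
the volume factor is all that survives of a well-specified background
asymptotically. A single observation defines `NKSD̂ = 0` (degenerate strata
warn rather than fail).

### Background-dimension policies

* `constant`: `m_B = m_const · r_B` (the toy studies use 5 per background
  dimension);
* `per_dim_sqrtN`: `m_B = c_b · r_B · √N`. The recommended default; it is
  the `α = 1/2` growth rate of the Pitman–Yor expression below, and √N
  growth is the regime with the cleanest nested-selection asymptotics;
* `pitman_yor`: `m_B = r_B · D Γ(ν+1)/(α Γ(ν+α)) · N^α`, the expected
  effective dimension of a Pitman–Yor mixture with discount `α`,
  concentration `ν` and `D`-dimensional components (fractional `D` encodes
  parameters shared across components). With `(α, ν, D) = (0.5, 1, 0.2)` the
  per-dimension multiplier is ≈ 20 at `N = 2000`, crosses 1 at `N = 5` and
  2 at `N = 20`; with `D = 100` it crosses the 798 per-gene glass-model
  parameters at `N = 13`.

### Temperature

`T` rescales the loss inside the generalized posterior
`π_N(θ) ∝ exp(−(N/T) NKSD̂) π(θ)`. Defaults: `T = 1`; the Gaussian toy
studies pin `T = 5`, the pPCA and glass applications pin `T = 0.05`.
`calibrate_temperature` picks `T` on a grid so that Laplace-approximate
credible intervals achieve a target coverage over well-specified replicates
(interval width scales as √T, so coverage is monotone over the grid; ties go
to the smaller T). The exact protocol behind the published calibration is
not specified anywhere we could consult, so this implementation —
component-wise coverage of the true parameter — is marked experimental.

## Kernels

Two radial families, both bounded, strictly positive, integrally strictly
positive definite and in the Stein class of absolutely continuous densities:

* `rbf`: `exp(−‖x−y‖²/(2h²))` (default);
* `imq`: `(1 + ‖x−y‖²/h²)^(−1/2)`.

Derivatives are closed-form per family (no autodiff); a `blocks` partition
gives a product kernel and subsystem additivity. The bandwidth default is
the median pairwise distance over a seeded subsample capped at 1000 rows;
the toy studies pin `h = 1`.

**Kernel choice for the pPCA benchmark.** The six-dimensional benchmark
shares one noise variance `v` across well-specified and misspecified
dimensions. Under the rbf kernel at unit bandwidth the minimum-NKSD fit
trades `v` between the two blocks (fitted `v ≈ 0.78` instead of 1), leaving
a population-level residual misfit on *every* dimension; at `T = 0.05` that
residual dwarfs the volume terms and the scan excludes everything. The
inverse multiquadric at unit bandwidth — the standard recommendation for
Stein-discrepancy inference, with a heavier tail that weights the bulk
mismatch differently — does not exhibit the trade-off (fitted `v ≈ 0.82–0.99`
with clean margins) and is the package's kernel for this benchmark:
leave-one-out log ratios ≈ −400..−1000 for the pPCA-distributed dimensions
versus ≈ +400..+1000 for the planted ones, balanced accuracy 1.0 at
`N = 2000` in both scenarios. The broader lesson (documented rather than
hidden): with shared nuisance parameters, partial misspecification can
contaminate the foreground fit, and the kernel controls how much.

## Computation

* **Exponential families.** `NKSD̂(θ) = θᵀAθ + Bᵀθ + C` with data-dependent
  coefficients; with a Gaussian prior the SVC integral is a closed-form
  Gaussian integral (the `exact` backend). The minimum Stein discrepancy
  estimator is the quadratic's vertex.
* **Affine scores.** Whenever `s_θ(x) = W(θ) x + m(θ)` (Gaussian location,
  pPCA), the U-statistic is a function of a handful of pairwise kernel
  moments computed once in `O(N² d)`; each subsequent evaluation costs
  `O(d³)`. This is what makes fitting, Hessians, leave-one-out scans and
  subset search fast. Pairwise passes optionally run in float32 with float64
  accumulation (≈6× faster; agreement to ~1e-5, verified in tests); the
  large-N studies use this path.
* **Laplace backend.** `−(N/T)NKSD̂(θ_N) + log π(θ_N) − ½ log det((1/T)∇²NKSD̂)
  + ((m_F+m_B)/2) log(2π/N)`. The Hessian is symmetrized; indefinite
  Hessians get up to three rounds of escalating jitter and then fall back to
  the BIC form with a flag. For over-parameterized models (the pPCA QR gauge,
  below) the determinant uses the `m_F` leading eigenvalues — the gauge
  directions carry no volume.
* **BIC backend.** Drops the prior and determinant terms; no second
  derivatives needed.
* **Variational backend.** Mean-field Gaussian in the unconstrained space,
  maximized by Adam on reparameterized gradients
  (`θ = μ + σ ∘ ε`). For quadratic fit terms with Gaussian priors the
  gradient expectations and the final bound are evaluated in closed form
  (the zero-variance limit of the same estimator); otherwise sampled
  gradients with finite-difference `∇_θ` are used. The returned score is the
  optimized bound plus the background volume term and sits below the exact
  log SVC by Jensen's inequality.
* **Optimum transfer.** Scanning many candidates re-uses the full-foreground
  optimum: `θ_j ≈ θ_0 − [∇²ℓ_0(θ_0)]^{-1} ∇ℓ_j(θ_0)`, one factorization for
  all candidates. For location families the step is exact (shared
  curvature); on the heterogeneous Gaussian toy the transferred and exactly
  re-optimized log-ratio vectors correlate at r > 0.999.
* **Subset search.** Per-dimension Bernoulli inclusion logits updated by
  leave-one-out REINFORCE (each step scores ≥ 2 sampled subsets; each
  subset's score, including the background volume of its excluded
  dimensions, is memoized since it is deterministic given the config).
  Defaults (batch 4, learning rate 0.25, 150–200 steps) were chosen on the
  4-dimensional Gaussian toy.

### Defective baselines

For the consistency studies the package also computes the scores that each
drop one ingredient: `ka` (foreground marginal likelihood + background
volume; fails data selection because foreground entropies leak in), `kb`
(no background volume; fails nested data selection), `kd` (plug-in minimum
NKSD, no foreground volume; fails nested model selection). A fourth variant
(a background-corrected empirical KL, which requires the unknown foreground
entropy) is intractable without that entropy and is documented only.

## Foreground models

* **Gaussian location** `N(x|θ, Σ)`, fixed SPD `Σ`: score `−Σ⁻¹(x−θ)`,
  exponential-family structure in the natural parameterization, conjugate
  closed-form marginal likelihood (used by `ka`). A fixed-mean variant has
  `m_F = 0`.
* **Probabilistic PCA** `x ~ N(0, U(L−vI)Uᵀ + vI)`: `U` on the Stiefel
  manifold (uniform prior), `L_ii ~ InvGamma(α/2, α/2)`,
  `v ~ InvGamma((α/2+1)(d−k)−1, (α/2)(d−k))`, default `α = 0.1`.
  Unconstrained parameterization: a free `d×k` matrix mapped to `U` by
  sign-fixed QR (a retraction; the `k(k+1)/2` gauge directions are excluded
  from `m_F` and from Laplace determinants), `L_ii = v + exp(ℓ_i)` (keeps
  `L_ii > v`), `log v`. Effective dimension
  `m_F = dk − k(k+1)/2 + k + 1`. The score `−C⁻¹x` uses the Woodbury form.
  `k` is a configuration input, not inferred.
* **Spin glass** (continuous Ising relaxation): logistic spins
  `z_j1 = σ(τ(x_j − μ))`, fields `H_j ∈ R²`, upper-triangular 2×2 coupling
  blocks `J_jj'`; `m_F = 2d + 2d(d−1) + 2` (798 per gene at d = 200).
  Priors: Normal on `H` (sd 1), Laplace on `J` entries (scale 1, sparsity),
  Normal on `μ` and on `log τ` (sd 1) — the published account names the
  families but not the scales, so these are package defaults. The bounded
  spin energy alone is not integrable on `R^d`; an isotropic Gaussian base
  measure (`base_precision`, default 1) anchors the density. The normalizer
  is intractable either way and cancels from the score, which is the point
  of using a Stein discrepancy here. The interaction energy
  `ΔE = J21 + J12 − J22 − J11` summarizes each pair: positive values raise
  the probability of *opposed* on/off states (anti-correlated spins),
  negative values favor alignment.

## Synthetic benchmarks

The generators are the package's test-input factory; each is a pure function
of (parameters, seed).

* **Bivariate toys**: `N(0, Σ0)` with `Σ0 = diag(1, ½)` (data selection; the
  unit-covariance location model is right on dimension 1 only) or `Σ0 = I`
  (nested data selection, model selection, nested model selection). Kernel
  rbf `h = 1`, `T = 5`, prior `N(0, 10 I)`, `m_B = 5` per background
  dimension.
* **pPCA benchmark** (`d = 6`): dimensions 1–4 from a two-factor pPCA with
  loadings `[[1,0],[−1,1],[0,1],[−1,−1]]` and unit noise; dimensions 5–6
  from a fair Bernoulli mixture — scenario A a variance mixture
  (`0.05^W I₂`, marginally non-Gaussian), scenario B unit-variance with
  `±0.99` correlation (marginals exactly Gaussian; only the dependence is
  wrong, the harder case). Ground truth is {5, 6} by construction, so
  balanced accuracy `(TN/N + TP/P)/2` (exclude = positive) is exact.
* **Glass samples**: per-coordinate Gaussian random-walk Metropolis on the
  unnormalized density, step size adapted toward 0.3 acceptance during
  burn-in only (then frozen, keeping the chain valid), thinned; verified
  against dense grid quadrature at `d = 2`. Desk-scale guard at `d ≤ 10`.

What the generators do **not** emulate: real scRNA-seq count structure (zero
inflation, library-size variation, overdispersion), batch effects, or
non-i.i.d. cells. Passing benchmarks therefore demonstrate the selection
machinery under its stated assumptions, not robustness to the full messiness
of expression data (the preprocessing pathway — library-size normalization,
log1p, per-gene standardization — is provided, but its adequacy is a
scientific judgment outside these tests).

## Study sizes and numerical choices

The consistency studies use `N ∈ {100, 1000, 10000}` with 20 seeds; the
estimator-rate study adds half-decade points up to `10⁴`; the pPCA benchmark
uses `N = 2000` with 5 replicates; recovery studies use `N = 2000` with 20
replicates. These sizes put the asymptotic regimes clearly on display while
each study completes in a couple of minutes on a single core.

Ties in include/exclude decisions break toward inclusion (`log K_j − log K_0
≤ 0` keeps dimension j). Comparisons across different temperatures, kernels,
sample sizes or background policies raise rather than silently mislead.
Leave-one-out `m_B` accounting charges each candidate `r_B = 1` through the
policy; an alternative mode sets `m_Bj = m_F0 − m_Fj`, which cancels the
volume terms and makes the SVC ratio directly comparable to the conventional
criticism score `log E_j − log E_0` (the fit-term change at the *full-data*
optimum). Because candidates re-optimize, the volume-matched SVC ratio
always attributes at least as much mismatch to a dropped subspace as the
criticism score — the asymmetry that makes data selection a sharper
criticism tool.

The parameter-recovery study uses factor loadings `H · diag(1, 1.5)`: the
benchmark's printed `H` has a degenerate covariance spectrum `{4, 4, 1, 1}`,
around which sorted sample eigenvalues split by ordering bias, so distinct
factor strengths are needed for a well-posed sorted-eigenvalue comparison.

## Known limitations

* No uncertainty quantification over the selected foreground, and no
  post-selection correction for downstream inference on θ.
* Search is over coordinate subsets; general linear `V` is supported in
  projection/comparison but not searched.
* The median-bandwidth and kernel-family defaults are heuristics; as the
  pPCA benchmark shows, kernel choice materially affects which mismatches
  dominate when nuisance parameters are shared.
* Linear-time/random-feature KSD approximations and V-statistic variants are
  out of scope; the pairwise pass is `O(N²)`.
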