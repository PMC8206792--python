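# Methods

## Model and assumptions

`mrexsurv` treats CpG methylation levels in a gene's promoter and body as
instrumental variables for that gene's expression and asks whether the
methylation-regulated component of expression (MReX) affects survival. The
design is a **one-sample two-stage regression**: instrument weights and the
outcome association are estimated on the same individuals. This maximizes
power at small cohort sizes at the cost of some type-I inflation relative
to a split-sample design; the inflation is small in practice and is
measured directly by the type-I simulation in the acceptance script.

Stage 1 assumes a linear instrument-exposure model G = Mw + ε with
homoscedastic Gaussian residuals on the inverse-normal-transformed
expression scale. Stage 2 assumes proportional hazards with a linear
predictor Xa + Ĝb + Mc. The random-effect term c ~ N(0, σ²c I) absorbs
direct CpG effects on survival (horizontal pleiotropy), which would
otherwise violate the exclusion-restriction assumption of instrumental
variable analysis; with σ²c = 0 the model reduces exactly to a plain Cox
regression on (X, Ĝ). First-stage weights are treated as known constants in
stage 2 (the no-measurement-error convention); no first-stage uncertainty
is propagated into var(b̂).

## Preprocessing and screening

Order of operations: median imputation per feature (features missing in
more than 10% of samples are dropped), then rank-based inverse-normal
transform of each gene's expression ((r − ½)/n offset, average ranks for
ties) and standardization of each CpG to mean 0 / unit sample variance,
then the variance-component screen. The transforms assume complete data,
which fixes the order.

The screen fits G ~ N(μ·1, σ²g · MMᵀ/p + σ²e · I) by REML with a single
intercept fixed effect, maximizing the profiled restricted likelihood over
log(σ²g/σ²e) ∈ [−12, 12] by bounded Brent search (tolerance 1e−8) after an
economy SVD of M; PVE = σ²g/(σ²g + σ²e), clipped to [0, 1]. The kernel is
scaled by 1/p so σ²g is the average per-CpG contribution. Genes are kept
when p ≥ 10 (the count refers to CpGs inside the 1-based closed window
[TSS − ext, gene end], strand-reflected, default ext = 2,000 bp — a
conventional promoter length; the window size is configurable because no
canonical value exists) and PVE > 1% (strict), i.e. a marginal
methylation–expression correlation above ~10%.

## Stage-1 estimators

* **lmm** (ridge/BLUP): ŵ = (MᵀM + λI)⁻¹MᵀG with λ = p·σ̂²e/σ̂²g from the
  REML components above, so shrinkage matches the estimated signal ratio.
  A useful consequence of BLUP shrinkage is cov(Ĝ, G) ≈ var(Ĝ), which keeps
  the stage-2 effect estimate approximately unbiased.
* **lasso / enet**: scikit-learn coordinate descent; glmnet-style penalty
  λ[α‖w‖₁ + (1−α)/2‖w‖₂²], mixing α = 0.5 by default (configurable; the
  choice is conventional, not estimated), λ selected at minimum mean CV
  error over a 100-value path with seeded 5-fold assignment (no 1-SE rule).
* Intercepts are never penalized. Cross-validated R² is computed on
  concatenated out-of-fold predictions, 1 − SSE/SST, with penalty selection
  nested inside each training fold; it may be negative.

Bayesian samplers (sparse mixed models, Dirichlet-process regression) are
not reimplemented; `PredictionFit` accepts externally computed weight
vectors and the combination step works for any number of models K ≥ 1.

## Stage-2 fitting

The Cox partial likelihood uses Efron tie handling by default (less biased
than Breslow under heavy ties; Breslow is available). For fixed σ²c the
penalized partial log-likelihood ℓ(a,b,c) − cᵀc/(2σ²c) is maximized by
Newton–Raphson with step-halving, which enforces a monotone objective;
convergence at relative tolerance 1e−8, at most 50 iterations. The gradient
and Hessian are computed in O(n·q²) by suffix aggregation over tie groups.

σ²c is chosen to maximize the Laplace approximation of the integrated
partial likelihood: the penalized maximum plus −½ log det of the
random-effect block of the penalized information minus (p/2)·log σ²c,
searched by bounded Brent on log σ²c ∈ [−10, 5] (tolerance 1e−6) with the
inner solution warm-started across outer evaluations. An optimum pinned at
the lower bound is reported as σ²c = 0 and the fit re-done as plain Cox,
so the boundary case is exact. var(b̂) is the (b,b) entry of the inverse
full penalized information at the optimum (not a sandwich), matching the
Laplace machinery. Monotone likelihood (perfect separation in risk sets)
is declared when any coefficient exceeds 15 in absolute value on
standardized inputs and is flagged rather than fatal.

## Combination and calling

ACAT with equal weights by default (weights are renormalized internally,
so callers may pass raw weights, and the weights of failed models are
simply dropped). p-values below 1e−15 use the asymptote tan{(½−p)π} ≈
1/(pπ); p-values at 1 are clipped just below 1. FDR control is
Benjamini–Hochberg (the field default); combined calling applies ACAT per
gene first, then one FDR pass across genes. A model failing on a gene
yields a missing p-value for that model only; a gene is skipped only when
every model fails.

## Synthetic data

The generator emulates the cohort the defaults describe: n = 190, three
covariates (age ~ N(47.8, 13²) clipped to [20, 81], stage 1–4 with
probabilities .574/.221/.153/.052, binary tumor status at .274),
exponential baseline hazard 0.02/month (median survival ≈ 35 months),
censoring target 0.74 (≈ 26% deaths), per-gene CpG blocks with
exchangeable correlation ρ = 0.5, sparse (5 causal CpGs) expression
architecture at PVE 0.3. Event times come from inverse-transform sampling
of the proportional-hazards model; censoring is independent uniform on
[0, τ] with τ calibrated by bisection so the expected censored fraction
hits the target. Genes and CpGs are laid out 100 kb apart on one synthetic
chromosome so block assembly reconstructs the generated blocks exactly.

What the generator does **not** emulate: beta-value compression and
boundary effects of methylation arrays, realistic CpG LD (a single
exchangeable ρ replaces it), batch effects, probe chemistry, or covariate-
dependent censoring. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated generative model, not
robustness to array artefacts.

## Validation choices and known limitations

* Simulation sizes used by the acceptance script: effect recovery at
  n = 400 with 200 replicates; type-I error and pleiotropy robustness at
  n = 300 with 500 replicate genes per arm; architecture matching with 50
  genes per architecture; PVE recovery with 100 replicates. These sizes
  give Monte-Carlo standard errors comfortably inside the tolerances
  checked.
* Under exchangeable CpG correlation the REML PVE estimate carries a small
  upward bias (≈ +0.04 at PVE 0.30, n = 300, p = 50) because the fixed
  polygenic weights of the generator do not follow the iid prior the
  kernel model assumes; with independent CpGs the estimate is unbiased.
  The screen is a filter, not an estimand, so this only shifts the
  effective threshold slightly.
* Whether published per-gene prediction R² values of this kind of analysis
  are in-sample or cross-validated is ambiguous; this package reports
  cross-validated R² and documents it as such.
* Duplicating every subject leaves the Breslow estimate exactly invariant
  (likelihood proportionality); under Efron the tied-group corrections
  break exact invariance, which is expected behaviour, not a defect.
* No frailty/clustered survival, time-varying covariates, stratified
  baselines, multi-tissue prediction, or genetic-variant instruments.
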