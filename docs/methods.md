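# Methods

## Model and estimation

The estimator minimizes, per regularization level λ,

    P_λ(β) = (1/2n) ‖y − Xβ‖₂² + λ [ τ‖β‖₁ + (1−τ) Σ_g w_g ‖β_g‖₂ ],

over the interleaved design X = (G₁, G₁×E, G₂, G₂×E, …): group g couples
one variant's main and interaction coefficients (n_g = 2, w_g = √(n_g) = √2).
τ = 1 is the lasso, τ = 0 the group lasso; intermediate τ gives the sparse
group lasso. The outcome y is the residual of the raw trait after a
training-split regression on an intercept, the normalized environment, and
any covariates; the intercept of the penalized model is then handled by
centering (r⁽⁰⁾ = y − ȳ), so X carries no constant column.

The solver is block coordinate descent over groups. Per group the partial
residual correlation ρ_g = (1/n) X_gᵀ r is tested against the group-zero
condition ‖ST_{λτ}(ρ_g)‖₂ ≤ λ(1−τ)w_g; when it fails, the 2-d sub-problem

    min_b ½ bᵀA_g b − ρ_gᵀ b + λτ‖b‖₁ + λ(1−τ)w_g‖b‖₂,   A_g = (1/n)X_gᵀX_g,

is solved by proximal gradient with the exact step 1/λ_max(A_g), iterated
to 1e-12. A scalar root-finding reduction of the 2-d problem is exact only
when A_g is a multiple of the identity; because a variant's dosage and
dosage×E columns are correlated, A_g generally is not, so the prox
iteration (whose composite prox — soft-threshold then group shrinkage — is
exact) is used instead. Sweeps alternate a full pass over all given groups
with an active-set loop, and terminate when the largest coefficient change
falls below `inner_tol` (default 1e-8). Every λ's solution is certified by
a full KKT (subgradient stationarity) residual, required ≤ `kkt_tol` ×
max(1, λ) (default 1e-6); failure raises rather than returning an
uncertified path.

The λ path is log-linear over L = 100 points (configurable) from
λ₁ = max_g (1/n)‖X_gᵀy‖₂ / (1−τ) down to λ₁/100. For τ = 1 the formula
degenerates and the lasso critical value max_j (1/n)|X_jᵀy| is used. λ₁
omits the group weight √2 and the soft-threshold shrinkage, so it
upper-bounds the exact critical value: the solution at the top of the path
is always exactly zero and the first few path points are mildly
conservative. Warm starts run down the path.

## Batch screening

The genome-scale driver processes the path in batches (default 10 λs):

* **Screening.** Groups outside the active set are ranked by
  c_g = ‖ST_{λ_prev τ}(X_gᵀ r)‖₂ with r the residual of the last certified
  solution; the top M (default 200; doubled when a batch repeatedly fails
  to certify) join the active set to form the strong set. Ties break by
  ascending group index for determinism. The feature-level strong rule is
  not used for screening — groups have only two features.
* **Fitting.** The SGL problem restricted to the strong set is solved for
  the batch, warm-started from the last certified solution.
* **Checking.** Each batch solution is verified against the full design.
  A *weak* group (outside the strong set) is certified zero when the group
  safe rule ‖ST_{λτ}(X_gᵀr)‖₂ < λ(1−τ)w_g holds at the solution's own
  residual, or, failing that, when both of its features pass the feature
  safe rule |X_jᵀr| < λτ; a zero-estimated feature inside a strong group
  must itself pass the feature rule. Each failed check is a violation
  recorded per (group-or-feature, λ). The smallest λ whose violation
  column is empty — with every larger λ in the batch also clean — becomes
  the restart point; violating groups are permanently absorbed into the
  strong set and uncertified λs are re-queued.

Because the safe-rule check at a candidate solution's own residual is
precisely the KKT zero-group condition, certification means the restricted
solution extended by zeros satisfies the full-design optimality conditions.
All rule comparisons are evaluated with a numerical slack of `kkt_tol` ×
max(1, λ), matching the solver's certificate: active groups sit exactly on
the rule boundary at an optimum, so a slack-free strict inequality would
flip on rounding noise and could deadlock the absorb-and-refit loop.

Convergence is monitored by validation R², computed by direct prediction
(1 − SSE/SST with ŷ = X_val β̂ + ȳ_train, SST about the validation mean),
not by refitting; the refitted R² is reserved for final evaluation. The
driver stops after N = 2 (configurable) consecutive decreases along the
certified λ sequence, pooled across batches, and returns the certified λ
maximizing validation R². τ is chosen on the grid {0.1, 0.3, 0.5, 0.7,
0.9} by the same criterion; τ = 0 provides the pure group-lasso mode.

## Preprocessing conventions

* Genotype and interaction columns are both standardized to mean 0, sd 1
  (denominator n−1) using training-split constants, reused verbatim on
  validation and test. Penalized regression needs a scale convention and
  this matches genome-wide lasso practice; it is a declared choice, not an
  inference.
* The environment variable is normalized to mean 0, variance 1 within each
  split separately (the method's stated convention); `train-only`
  normalization is available as a flag for the conventional alternative.
* Missing dosages are mean-imputed with the training mean. Variants
  monomorphic in training are dropped with a warning.
* Sample tables are aligned to fam order by (FID, IID); unmatched samples
  are reported and dropped.

## Evaluation

PRS_G and PRS_GEI are genotype-only weighted sums of the *standardized*
dosages; E multiplies PRS_GEI only inside the evaluation model
y ~ 1 + E + PRS_G + PRS_GEI×E (no PRS_GEI main-effect term — exactly the
model the scores are designed for). Semi-partial R²s are full-minus-reduced
R² differences; the interaction P-value is the classical homoskedastic
t-test of the PRS_GEI×E coefficient (robust errors were considered and left
non-default as there is no stated convention to match). A PRS_GEI that is
identically zero reports zero unique variance and an absent P-value.
Rank-deficient evaluation designs fall back to pseudoinverse fits with a
warning rather than failing, since near-collinearity of E with PRS_G is a
real phenomenon in sex-interaction analyses.

Stratification splits samples at median(E) (ties to the upper stratum) and
bins them by global quartiles of PRS_GEI (rank-based, computed on the whole
evaluated split — fixed quantiles, not per-stratum); each cell reports n,
mean(y), se(y), plus a per-stratum least-squares slope of the cell means
over quartile index.

The 2-df scan fits y ~ 1 + E + G + G·E per variant by OLS and F-tests
H₀: β_G = β_GEI = 0 (2 numerator df), vectorized by projecting out the
shared (1, E) block. It is plain OLS: mixed-model control of relatedness
and structure is deliberately out of scope. The thresholded baseline
filters at each of {5e-8 … 1e-3}, picks λ per threshold by five-fold CV on
training, and selects the (threshold, τ, λ) combination by validation R².

## Bagging

B bags (default 10) each draw a fraction f (default 0.30) of the training
samples without replacement, independently across bags — bags may overlap,
since 10 disjoint 30% subsets cannot exist. Each bag learns its own
standardization constants and model; the ensemble output is the mean of
per-bag *scores* on the test split, never of coefficient vectors (which
live on bag-specific scales). Per-bag seeds are seed + bag index; bag
indices are sorted so B = 1, f = 1 reproduces the non-bagged run
bit-for-bit.

## Synthetic data

The simulator emulates a two-subpopulation GWAS cohort. Genotypes come
from a latent blockwise AR(1) Gaussian copula: per sample, two independent
"haplotype" Gaussians with within-block correlation ρ are thresholded at
each variant's allele frequency (uniform on the configured MAF range, with
an FST-like per-subpopulation Gaussian perturbation of scale
`subpop_fst_like_shift`), giving Hardy–Weinberg dosages whose LD is
positive within blocks and decays with distance. This is a controllable
stand-in with the right qualitative structure, not a fit to any real LD
map or site-frequency spectrum — results on it demonstrate algorithmic
correctness and qualitative orderings, not real-data effect sizes.

The environment is Gaussian with mean 1 and variance 4. The phenotype is
y = Σ_k w_k c_k over five components — main genetic, GxE, covariate,
subpopulation, error — each standardized in the full sample before
weighting, so each contributes exactly w_k² of the unit trait variance.
Σ w_k² = 1 is enforced. Named scenarios map weak/moderate/strong to
variance shares 0.05/0.15/0.30 for the main and GxE components, with 0.05
each for covariate and subpopulation and the remainder to error; these
presets are configurable conveniences, not canonical values. The true
aggregates g_main = Σ β_G,i G_i and g_GEI = Σ β_GEI,i G_i (causal effects
drawn standard normal; by default 30 causal groups per component with 50%
overlap) are stored pre-standardization and serve as ground-truth scores.
Across replicates everything is fixed except the error draw. Splits
(default 60/20/20) are stratified by subpopulation. All randomness flows
from one seed through named substreams (genotypes, environment,
covariates, effects, split, error) so each stage is reproducible alone.
Components are standardized in the full simulated sample; per-split
standardization was the open alternative and would change R² targets only
at O(1/√n).

## Problem sizes and numerical choices

The packaged study runs at desk scale: n = 4 000 samples, p = 1 000
variants, 30 causal groups, strong-GxE weights, path length 50, screening
batch M = 100 — sizes chosen so the full replicate loop completes in
minutes while keeping >10× more variants than causal groups and a test
split large enough (n = 800) for stable R². The acceptance script uses 5
phenotype replicates; the test suite uses 20 for the recovery and
stratification properties.

Degenerate inputs are errors, not silent repairs: zero-variance
environment within a split, rank-deficient adjustment designs, empty
splits, invalid weight vectors. Solver non-convergence raises with the
worst KKT residual attached.

## Known limitations

* Quantitative traits only; no binary/survival losses.
* One environment variable; multi-environment joint modeling is future
  work (categorical E can be dummy-coded upstream).
* In-memory designs only — the bagging mode, not out-of-core streaming, is
  the memory-reduction mechanism.
* The 2-df scan's OLS ignores relatedness; its calibration statements hold
  for the simulated unrelated cohorts.
* Group size is fixed at 2 throughout the tests; the solver keeps general
  group notation but other sizes are unexercised.
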