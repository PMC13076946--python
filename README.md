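# geiprs

Polygenic risk scores that model gene–environment interaction, fitted by a
batch-screened sparse group lasso.

## The problem

Standard polygenic risk scores (PRS) weight allele dosages by per-variant
main effects and ignore genotype–environment interaction (GxE), even though
many complex traits — lung function under smoking, anthropometric traits by
sex, drug response under treatment — are shaped by both. Jointly selecting
main and interaction effects over genome-wide variants is a structured,
very high-dimensional regression problem: each variant *i* contributes a
*pair* of coefficients, a main effect β<sub>G,i</sub> on its standardized
dosage **G**<sub>i</sub> and an interaction effect β<sub>GEI,i</sub> on
**G**<sub>i</sub>×**E**, where **E** is a continuous or ordinal environment
variable. `geiprs` is for statistical geneticists who want to fit that model
at scale on individual-level data and to quantify how much trait variance
the interaction score uniquely explains.

## The model

With outcome **y** (residualized on **E** and covariates) the fit minimizes
the sparse group lasso objective

    (1/2n) ‖y − Xβ‖₂²  +  λ [ τ‖β‖₁ + (1−τ) Σ_g w_g ‖β_g‖₂ ],

where each group *g* holds one variant's coefficient pair
(β<sub>G</sub>, β<sub>GEI</sub>), w_g = √2, and τ ∈ [0,1] trades the lasso
penalty against the group penalty (τ = 0 is the group lasso). The grouped
penalty selects variants as units while the ℓ₁ part can still zero one
member of a selected pair.

Genome-scale paths are solved by an iterative batch-screening algorithm:

1. **screen** — rank inactive groups by the strong-rule score
   c_g = ‖ST<sub>λτ</sub>(X_gᵀ r)‖₂ and add the top *M* to a strong set;
2. **fit** — solve the path batch restricted to the strong set by block
   coordinate descent with warm starts;
3. **check** — certify each solution against the *full* design with safe
   rules (exact zero-coefficient certificates); any violating group is
   absorbed and the batch re-run, so certified solutions satisfy the
   full-problem KKT conditions.

The path stops after N consecutive decreases of validation R²; the selected
model maximizes validation R². From its coefficients two genotype-weighted
scores are built per sample, PRS_G = Σ β̂<sub>G,i</sub> G<sub>i</sub> and
PRS_GEI = Σ β̂<sub>GEI,i</sub> G<sub>i</sub>, and evaluated by refitting

    y ~ E + PRS_G + PRS_GEI × E,

reporting the overall R², four semi-partial R²s (the unique variance of
each term), and the t-test P-value of the PRS_GEI×E coefficient. A bagging
mode (default 10 subsamples of 30% of training) bounds memory by averaging
per-bag test-split scores, and a per-variant 2-df joint F-test (G + GxE)
supplies both a P < .01 prefilter and the thresholded (S)GLwT baseline.

## Worked example

Simulate a cohort (2 000 samples, 200 variants, moderate main and moderate
GxE effects), fit, score the test split, and evaluate:

```sh
geiprs simulate --out sim --n-samples 2000 --n-variants 200 \
    --scenario moderate-moderate --seed 42
geiprs fit      --bfile sim --pheno sim.pheno.tsv --tau 0.5 \
    --path-length 40 --m-screen 50 --out coef.tsv
geiprs score    --bfile sim --pheno sim.pheno.tsv --coefficients coef.tsv \
    --out scores.tsv
geiprs evaluate --scores scores.tsv --pheno sim.pheno.tsv --out report.json
```

which prints `wrote coef.tsv (tau=0.5, lambda=0.02908)` and writes

```json
{
  "overall_r2": 0.23274704513861477,
  "sp_r2_gei": 0.11639279542669612,
  "sp_r2_g": 0.11813470181562158,
  "sp_r2_joint": 0.22972702500049458,
  "sp_r2_env": 0.00019516076695591522,
  "p_interaction": 7.777327639964068e-14,
  "n_used": 400
}
```

Read: the refitted model explains 23.3% of test-split trait variance; the
interaction score uniquely adds 11.6% (close to the simulated 15% GxE
variance share, shrunk by estimation noise at n = 2000) and its
interaction term is decisively significant (P ≈ 8×10⁻¹⁴). The same
workflow is available programmatically via `geiprs.run_pipeline`.

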