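# Methods

## Model

`metfactor` fits a two-level factor-analytic multivariate linear mixed model
to a genotype × experiment trait matrix Y (one trait; multiple traits are
separate runs). Level 1 decomposes Y into fixed effects, a low-rank factor
term and residual traits, `Y = XB + FΛ + U_R + E_R`; level 2 treats every
factor column f_k and every residual-trait column as an independent
univariate kinship mixed model. An *experiment* is one tester family within
one location-year trial; the experiment id `<location>_<year>_<tester>` is
display-only — metadata is authoritative.

Assumptions worth stating explicitly:

- **One row per genotype.** The trait matrix carries BLUEs (adjusted means),
  not plots; `genotype_incidence` must be injective. Kinship may cover more
  genotypes than the matrix; the extras are reached only through K_no
  cross-blocks at prediction time.
- **Factor traits are zero-mean with total variance 1.** Fixed effects
  attach to the t observable columns only (B is p × t), which resolves the
  non-identifiability between column fixed effects and the factor term, and
  the unit total variance resolves the F-vs-Λ scale ambiguity (heritability
  h²_Fk partitions it; Λ absorbs scale).
- **Gaussian phenotypes, ignorable missingness.** Missing cells are imputed
  by full data augmentation each sweep, so all conditional updates see a
  complete matrix and remain exact conjugate draws.

The loading prior regresses each row of Λ on named EC design matrices
(intercept first, then e.g. one-hot state, one-hot tester, standardized
quantitative covariates) with multiplicative-gamma shrinkage: coefficient
variance σ²_l/τ_k and residual precision ψ_jk·τ_k, τ_k = Π_{h≤k} δ_h.
Higher-order factors are therefore progressively shrunk toward zero, and a
row's systematic part transfers to environments described only by their ECs.
One variance σ²_l is shared per EC term across factors (τ_k supplies the
per-factor scaling); with full one-hot coding of categorical terms the
shared variance absorbs the over-parameterization symmetrically.

## Sampler

A Gibbs sampler cycles five blocks in fixed order: genetic effects → factor
scores → loadings → loading regression → imputation.

- **Heritabilities** are sampled on a discrete grid {0, 1/m, …, (m−1)/m}
  (default m = 20) using the exact likelihood in the eigenbasis of the
  observed-genotype kinship matrix (one eigendecomposition per run). For
  residual traits the grid draw is made jointly with a conjugate
  inverse-Gamma draw of the total variance σ²_Rj (prior invGamma(2, 1),
  exposed in `SamplerConfig`), with the genetic effect marginalized.
- **Factor scores**: with augmented-complete data every row of F shares one
  k × k conditional precision, so a single Cholesky factorization serves all
  n rows per sweep.
- **Loadings** are drawn per experiment column from the conjugate normal
  combining FᵀF/σ²_eRj with the EC-regression prior mean and ψ⊙τ precisions.
- **Loading regression**: per factor, all terms' coefficients jointly
  (ridge jitter 1e-10 with one retry on a singular precision); then σ²_l
  (inverse-Gamma), ψ_jk (Gamma((ν+1)/2, (ν+τ_k ε²)/2)) and the δ_h
  conditionals with τ recomputed as the cumulative product.
- **Fixed effects** B have flat priors and conjugate normal updates.

Default hyperparameters: ν = 3; δ1 ~ Ga(2.1, 1), δ_h ~ Ga(3.1, 1) for h ≥ 2
(so E[δ] > 1 and shrinkage increases with factor index); σ²_l ~
invGamma(3, 1). All are proper and exposed. Default iteration plan: 5000
iterations, 2500 burn-in, thinning 5, k_max = 50 working factors; at the
problem sizes of the test suite a few hundred iterations already give stable
posterior means, and the suite uses chains of 150–800 iterations with
k_max 3–8 to keep runs fast. Two or more chains with different seeds are
recommended for real analyses; the contract is bitwise determinism for a
fixed seed and a single worker.

Initialization: truncated SVD of the column-standardized, mean-imputed trait
matrix for F and Λ (ties broken by descending singular value, then column
index), variance partitions at the grid point nearest 0.5, δ drawn from its
prior, missing cells at column means.

Correctness is verified three ways in the test suite: Monte-Carlo moments of
every block against hand-derived conjugate closed forms on 2×2 instances; a
no-data (all-missing) run whose marginal δ1 moments must reproduce the prior
(a Geweke-style check — with full augmentation the chain then targets the
joint prior exactly); and parameter recovery on simulated data.

## Prediction

All four prediction maps are linear in each retained draw, and summaries are
posterior means (exact for the predictive mean under linearity) with
draw-dispersion standard deviations. New-environment loadings use the
intercept plus the spec's predictor terms only; prior-only terms contribute
zero, and a categorical level unseen in training contributes a zero row with
a warning rather than an error — this is precisely the semantics that makes
an unseen state reduce `S+T::S+T` to `S+T::T`. New-environment predictions
carry no residual-trait term (a new environment has no residual trait); the
question of adding an environment-average residual is left out deliberately.
New-genotype predictions compose the kinship regression K_no K_oo⁻¹ with the
loading prediction per draw, preserving the draw-level covariance between
U_F and the regression coefficients; K_oo is inverted through its
eigendecomposition with a 1e-10 eigenvalue floor.

Constant (`::O`) prediction averages per-experiment estimates across the
training experiments of the target's cluster (ALL, by state, or by tester);
empty clusters fall back to ALL with a warning.

## Baselines and evaluation

The univariate GBLUP baseline is fitted per experiment by REML:
golden-section/bounded search on log(σ²_g/σ²_e) ∈ [−10, 10] (tolerance
1e-8) after projecting out the intercept, using one eigendecomposition of
the observed kinship submatrix; BLUPs come from the mixed-model equations at
the optimum, new genotypes by kinship regression, new environments by
cluster averaging (ALL / state / tester). "Best strategy" selection
maximizes the meta-analytic mean ability, ties broken toward fewer predictor
terms.

Cross-validation scenarios: CV1 (one genotype 5-fold partition shared by all
experiments), CV2 (same partition, fold order permuted independently per
experiment), and four new-environment constructions layered on each CV2
training set — held-out trial folds, states with ≥ 9 experiments, tester
experiment sets, and two-year blocks with train-set genotypes removed from
the test set (NewGenoNewYear). New-environment abilities are computed on the
20% CV2 holdout genotypes of each test experiment. Fold sizes differ by at
most one when n is not divisible by 5; year blocks are consecutive two-year
windows from the minimum year with a partial final window allowed.

Per-experiment predictive ability is the Pearson correlation r(y, ĝ) over
test cells, averaged across a scenario's assignments. Abilities are pooled
with a Hunter–Schmidt random-effects meta-analysis: sampling variances
(1−r̄²)²/(nᵢ−1) with r̄ the n-weighted mean, HS between-experiment variance
floored at zero (inverse-variance weights, matching metafor's `method="HS"`),
pooled mean under sample-size weights and the corresponding weighted SE; the
implementation is frozen against metafor output in the tests. Paired model
comparisons meta-analyze per-experiment ability differences; the SE of a
difference of two dependent correlations needs the correlation between the
two prediction vectors, which is accepted per experiment when available,
with an independence fallback otherwise (conservative — the exact arguments
of the original dependent-correlation test are not recoverable). CIs are
mean ± z·s/√n. The loading–EC scan regresses posterior-mean loading rows on
candidate covariates (one-hot for categorical) with overall-F p-values,
Bonferroni-adjusted across the k factors per covariate; factor importance
reports ΣΛ² per factor and the count of factors whose per-experiment
variance share exceeds 1%.

## Simulation generator

The generator emulates a MET of n = 500 lines × 500 environments (400
training, 100 evaluation) with 10 latent factors. Kinship is
K = ZZᵀ/100 + 0.5·I with Z a 500×50 iid standard-normal matrix — 50 large
and 450 small (0.5) eigenvalues, enough for moderate genomic prediction
accuracy. Λ row 1 is constant (positive covariance everywhere), row 2 is an
environmental gradient, rows 3–10 are unpredictable iid loadings; the three
parts receive fractions `main_effect_prop`, `1 − main_effect_prop −
unpredictable_prop` and `unpredictable_prop` of the loading variance (rows
standardized to unit mean square first). Defaults split the predictable
budget evenly (0.25/0.25); the study grid varies them in {0, 0.25, 0.5,
0.75} × {0, …, 0.8}.

The gradient is built in one of three EC modes: **categorical** (10 training
groups with standard-normal group values; 50 evaluation environments from
group 1 and 50 from an 11th group never seen in training; only group
identities are exposed, as one-hot over training groups so the unseen group
is an all-zero row), **univariate** (the gradient itself exposed), or
**multivariate** (a t×10 standard-normal W exposed; gradient ~
MVN(0, WWᵀ/20 + 0.5·I), so about half its variance — slightly less than
half after the ratio's Jensen correction, ≈ 0.486 in expectation — is
explainable from W).

Factor and residual columns have heritability h² = 0.8 in expectation (the
generator draws u ~ N(0, K); with the default dimensions E[diag K] = 1, so
realized per-column h² averages 0.8 — at much smaller z_cols/n the diagonal,
and hence realized h², shrinks). A single global scalar rescales the
environmental residual so the across-environment mean of var(FΛ)/var(Y)
equals `factor_share` (0.8) exactly in each realization. Missingness masks
exactly round(missing_prop · n · t) uniformly random cells. Everything is
deterministic given the seed; replicate r uses seed + r.

What the generator does *not* emulate: real marker LD (kinship is a random
Gram matrix), non-Gaussian traits, selection, unbalanced missingness
patterns (real METs are structured, not uniform), spatial field trends, or
EC measurement error. Passing tests therefore demonstrate correctness of the
machinery and the qualitative regimes (EC-informed transfer helps when the
gradient drives G×E and is predictable; not when the relevant EC level is
unseen), not field-data accuracy levels.

The study runner holds out 20% of lines per replicate as "new genotypes"
(the fraction is a package choice; any fixed holdout works for ranking
methods), fits the extended model with k = 15 factors (scaled down alongside
the other dimensions in the test suite) and per-trial GBLUP, and evaluates
eight goals (CV1, CV2, NewTrial, NewState, NewEnv and their new-genotype
counterparts), skipping goals incompatible with the EC mode.

## Preprocessing

- **Experiment splitting**: by (trial, tester), keeping partitions with at
  least 50 distinct hybrids (genotypes, not plots).
- **Outliers**: a Chauvenet-type criterion — flag v when
  m·2(1−Φ(|v−mean|/sd)) < 1 with sample mean/sd — applied within experiments
  and then to experiment means. The criterion is m-dependent by construction
  (duplicating a dataset can newly flag a borderline point). Other readings
  of "expected occurrence below one" exist; this formalization is the
  package's.
- **BLUEs**: four design cases selected by structure (two-way fixed with
  random block-in-replicate; fixed replicate; random block; hybrid-only),
  the single random variance by REML on the residual projection, and
  marginal hybrid means averaging equally over replicate levels.
- **Parent inference**: hybrid dosage 0/2 assigns both parents; dosage 1
  assigns the tester 0 if any same-tester hybrid carries 0 at the site and
  the alternate homozygote (2) otherwise — an inbred tester cannot be
  heterozygous, so the "otherwise" branch is resolved to dosage 2 and the
  P1 receives the complement; sites where a tester family shows both 0 and 2
  against a heterozygous focal hybrid are irreconcilable and set missing.
  Testers must be replicated across ≥ 2 hybrids.
- **VanRaden GRM**: G = (M−2P)(M−2P)ᵀ / (2Σp(1−p)), frequencies from the
  supplied matrix, monomorphic sites dropped, missing dosages mean-imputed
  per site.
- **Weather ECs**: corn GDD with base 50 °F and a 86 °F cap on Tmax,
  conventionally halved — `divisor=1` reproduces the unhalved variant
  (Tmax'+Tmin'−50), which cannot reach zero under the caps and roughly
  doubles AGDD; it is provided for comparison and logged as such. AGDD
  partitions the season into 23 stages (VE, V1–V18, VT, R1, R2, merged
  R3–R6). The default `StageTable` thresholds are synthetic placeholders
  with a realistic shape, **not** agronomic reference values — real analyses
  must supply their own threshold table (CSV). Per-stage means of 11 weather
  variables + GDD, plus season totals AGDD and APRE, give
  (11+1)·23 + 2 = 278 features; unreached stages yield missing features for
  downstream mean-imputation. Eigenvector EC features scale the
  eigenvectors of the trial×trial covariance (or of a PSD similarity
  matrix) by √eigenvalue, keeping by default the components explaining 95%
  of variance, capped at trials − 1.

## Known limitations

- The sampler is a single-threaded data-augmentation Gibbs sampler; very
  high missingness slows mixing (the disconnected-trial regime in the tests
  shows this), and no marginalized or variational alternative is provided.
- Heritability resolution is limited by the grid (1/m).
- The GBLUP baseline is kinship-parameterized only (no marker-effect form).
- Scenario construction assumes the metadata columns (state, tester, year)
  are complete and correct; there is no fuzzy matching.
- Pedigree kinship, multi-trait joint modeling and prediction intervals
  calibrated for selection decisions are out of scope.
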