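# Methods

## The estimation problem

A neonatal MRI scan is summarized by three morphometric features at every
vertex of a fixed-topology cortical mesh: cortical thickness (mm), sulcal
depth (mm), and the GM/WM intensity ratio. All scans in a cohort share one
mesh (same vertices and triangles, registered upstream), so a scan is a
`vertices x 3` signal on a fixed graph. The package regresses postmenstrual
age (PMA, weeks) on this signal, corrects the regression-to-the-mean bias of
the prediction, and analyzes the residual gap (BAI) against clinical
variables.

## Meshes and downsampling

Surfaces are two-hemisphere icospheres: a regular icosahedron subdivided L
times and projected to the unit sphere, mirrored and translated so the
hemisphere components are disjoint. At level L each hemisphere has
`10*4^L + 2` vertices, `20*4^L` triangles and `30*4^L` edges (Euler
characteristic 2). Level 6 (81,924 vertices, 163,840 triangles total)
represents acquisition resolution; level 3 (1,284 vertices) is the working
resolution of the regressor.

Vertex ordering is parent-first within each hemisphere: the level-(L-1)
vertices occupy the first indices of the level-L sphere at identical
positions. Subdivision midpoints are appended in first-encounter order while
iterating faces, which makes the ordering deterministic and lets a coarser
mesh's vertex i coincide with the finer mesh's vertex i. Downsampling then
has two modes: `select` (coarse vertex i takes fine vertex i; exact, useful
for equivalence tests) and `patch_mean` (uniform average over the fine
vertices nearest to each coarse vertex within its hemisphere, ties broken by
lowest coarse index; the default, because averaging suppresses vertexwise
noise). Which aggregation real pipelines use is generally unreported; both
are provided and tested.

## Spectral graph convolution

With binary mesh adjacency A and symmetric-normalized Laplacian
`L = I - D^(-1/2) A D^(-1/2)` (isolated vertices get identity rows), a
filter with coefficients theta acts as `y = sum_k theta_k T_k(Lt) x` where
`Lt = 2L/lambda_max - I` and T_k are Chebyshev polynomials. `lambda_max` is
fixed at 2 — the exact upper bound for a normalized Laplacian — avoiding
per-graph eigenvalue estimation; Lanczos estimation is available as an
option. On meshes small enough for dense eigendecomposition the Chebyshev
path agrees with exact Fourier-domain filtering to 1e-8 (a core test).

## Pooling hierarchy

Graclus-style greedy heavy-edge matching (normalized-cut weight
`w_ij (1/d_i + 1/d_j)`, vertices visited in ascending index for determinism)
coarsens the graph three times. Unmatched vertices become singletons and are
padded with "fake" disconnected vertices so every coarse vertex has exactly
two children; descending the resulting binary tree yields a vertex
permutation under which each pooling step is a stride-2 1D max-pool. Fake
vertices are replaced by a -inf sentinel before each max, so they can never
win; positions whose children are all fake output 0. Hemispheres coarsen
independently because their components are disjoint.

## Architecture and training

Three Chebyshev convolution blocks (K=3; 16/32/64 output channels, ReLU)
each followed by stride-2 max-pooling, then a flatten, one 64-unit ReLU
hidden layer, and a linear output — the raw predicted age in weeks. These
widths, K, the pool size (2) and the pooling operator (max) are configurable
defaults; published applications of this architecture family rarely report
them. Training minimizes MSE with Adam (lr 2e-3, halved every 60 epochs,
batch 128, weight decay 1e-5 on weights, at most 150 epochs) and early stops
on validation MAE with patience 20 — on the synthetic cohorts validation
error plateaus before epoch ~50, so the cap is generous. Inputs are
standardized per vertex and feature with training-set statistics stored on
the model. Parameters are float32; initialization is seeded Glorot uniform;
training and prediction are deterministic given the seed. The forward and
backward passes are written directly in NumPy (verified against numerical
differentiation); the first layer's Chebyshev stack depends only on the
inputs and is precomputed once per training set.

## Cross-validation and bias correction

Subjects (never scans) are split into 5 outer folds stratified on the PMA
quintile of their first scan: 20% test per fold, and the remaining 80% split
80/20 into training (64% of subjects) and validation (16%). All scans of a
subject stay in one set, including a repeat scan, which is stricter than
strictly necessary but removes any within-subject leakage. Per fold, the
bias correction `(alpha, beta)` is the OLS fit of raw predicted age on
chronological age over train+validation, applied to the test set as
`PBA' = (PBA - beta)/alpha`; the regression direction (predicted-on-age) is
the one under which the corrected fit has slope 1 and intercept 0 on the
fitting set. Only the linear trend is removed; quadratic age dependence is
out of scope. Pooled test predictions are scored jointly by MAE and
Pearson r.

## ComBat harmonization

Parametric empirical-Bayes location/scale harmonization per vertex:
standardize by the OLS fit (site indicators plus protected covariates — PMA
at scan and, in cohort use, sex), then shrink per-site location gamma and
scale delta^2 toward across-vertex priors (normal / inverse-gamma, moment
hyperparameters, iterated to 1e-6). The pooled SD is floored at 1e-8 and
zero-variance vertices pass through unchanged. The default fits ComBat on
the whole cohort before cross-validation — matching harmonization performed
prior to model training — which leaks site/covariate structure (not labels)
across folds; `fit_combat`/`apply_combat` can be called fold-wise where that
trade-off is unacceptable. Note an EB property the tests respect: when a
site effect is spatially constant, shrinkage pulls every vertex's gamma to
the common prior mean and the per-vertex residual site difference is of the
order of the sampling noise of a site mean; near-complete removal at every
vertex requires site effects that vary across vertices, which is also the
realistic regime.

## Synthetic cohorts

The generator emulates a two-site preterm cohort with longitudinal repeats.
Per subject: GA at birth ~ N(28.2, 1.9^2) weeks; birthweight
1080 + 100 (GA - 28.2) + N(0, 240^2) grams; first scan at PMA N(31.4, 1.9^2)
weeks; 30% of subjects rescanned 4-5 weeks later; site assignment 43%/57%
("1.5T-like" site with additive location and multiplicative scale effects /
"3T-like" reference); binary clinical factors at prevalences 14%
(postnatal steroids), 27.9% (chronic lung disease), 58.9% (hypotension),
54.2% (infection), 50.4% (PDA), 3.9% (NEC).

Each factor delays effective maturation by w_j weeks (defaults 0.8, 0.6,
0.25, 0.25, 0.2, 0.5 respectively — chosen so steroids and CLD dominate and
the total shift SD is ~0.67 weeks), plus a subject random effect
(SD 0.5 weeks). The per-vertex feature model is linear in effective age:

    value = baseline_f + b_f p_b(v) + (slope_f + a_f p_a(v)) (PMA - shift - 26)
            + site_location_f + site_scale * noise_sd_f * eps

with smooth seed-free spatial patterns p(v) built from low-order real
spherical harmonics of the vertex positions. Feature defaults (baseline,
slope/week, noise SD): thickness 1.2 mm, 0.04, 0.20; sulcal depth 2.0 mm,
0.35, 1.5; GM/WM ratio 1.10, -0.012, 0.08 — structural stand-ins with
realistic orders of magnitude, not calibrated to any cohort's measured
distributions. Outcome scores load negatively on the centered maturation
shift: cognitive 103.0 - 9.0 (shift - E shift) + N(0, 13^2), language
92.6 - 6.0 (...) + N(0, 13^2), motor 93.7 - 2.0 (...) + N(0, 13^2), giving
implied BAI-outcome correlations of roughly 0.4 / 0.3 / 0.1 and score SDs
near 15; only ~30% of subjects receive outcomes, mirroring partial
follow-up. The "spatially structured" variant quadruples the vertexwise
noise SD so that per-vertex SNR is low and only spatial averaging recovers
the signal.

Because the shift enters the features only through (PMA - shift), no
feature-based predictor can beat the noise floor
`E|shift - E shift| = sqrt(2/pi) SD(shift)` (~0.53 weeks at defaults); the
end-to-end acceptance check is therefore an MAE bound relative to this
floor plus r > 0.9, not an absolute error.

What the simulator does not contain: real gyrification geometry, nonlinear
growth curves, spatially correlated noise, missing data beyond outcome
follow-up, or any coupling between GA at birth and the clinical factors.
Passing tests demonstrate that the machinery recovers structure it is
designed to recover — they say nothing about accuracy on real cohorts.

## Baselines and ablation

The comparators consume the same flattened `scans x 3852` matrices and
byte-identical folds: a seeded 500-tree random forest, and a "GLM" read as
ridge regression with the penalty chosen on the validation set (unpenalized
least squares is rank-deficient at p >> n). The ablation harness retrains
the identical GCN on a degree-preserving double-edge-swap rewiring of the
mesh (10x edge count swaps, per connected component, so hemispheres stay
disjoint). One caveat discovered with this generator: because the synthetic
feature model is linear in age, any linear predictor is well-specified, and
the ridge GLM dominates the random forest (and interpolating minimal-norm
OLS behaves similarly via benign overparameterization). The published-style
ordering GCN < RF < GLM therefore does not emerge from a linear simulator;
the suite asserts GCN <= RF and documents the three-way ordering as a
real-data phenomenon.

## Clinical statistics

Clinical variables are dichotomized by a stated clinical threshold (e.g.
birthweight <= 1000 g codes the at-risk group) or by a median split with
ties to the lower group; factors whose minority level has fewer than 10
scans are excluded (as for NEC). Each factor's association with BAI is
tested in a linear mixed model (statsmodels MixedLM, REML) with a random
intercept per subject, correcting for PMA at scan and the other dichotomized
factors; collinear covariates are dropped with a warning. With one scan per
subject the estimates collapse to OLS. Simulated calibration at 150 subjects
with two scans each puts the type-I error at alpha=0.05 within [0.03, 0.07].
FDR uses Benjamini-Hochberg (statsmodels), verified against the brute-force
step-up definition. BAI-outcome correlations use one scan per subject (the
latest) and Pearson r with BH adjustment across outcomes.

## SEM

The SEM module is self-contained and RAM-parameterized: path matrix A,
symmetric covariance S, observed-row filter F, implied covariance
`F (I-A)^(-1) S (I-A)^(-T) F^T`. Models are written in a small DSL
(`A -> B`, `A ~~ B`, `@1` to fix the identifying loading); every variable
gets a free variance unless given explicitly. Fitting minimizes the ML
discrepancy with L-BFGS and an analytic gradient
(`dF = tr[(Sigma^-1 - Sigma^-1 C Sigma^-1) dSigma]` propagated through the
RAM algebra); start values are zero paths (0.1 for declared paths), half the
sample variance for observed variances, 1 for latent variances.
`chi^2 = (n-1) F_ML`, df = p(p+1)/2 minus free parameters; standard errors
come from the inverse numerical Hessian scaled by 2/(n-1); standardized
coefficients rescale by implied SDs. Non-positive-definite candidate
covariances get a large penalty value during optimization; Heywood cases
(negative variance estimates) are flagged on the fit, never silenced.
Indirect effects are products along a path chain with seeded nonparametric
bootstrap percentile intervals (default 2,000 resamples; bootstrap refits
start from the full-data solution). The default template has three upstream
latents (severity of preterm birth <- GA, birthweight; perinatal injuries <-
IVH/VM/PVL scores; postnatal factors <- CLD, steroids, hypotension), BAI as
a manifest mediator, and an outcome latent (cognitive/language/motor), with
free covariances among the upstream latents — 33 free parameters, df 45.
The template is configuration, not a claim about any published model's exact
indicator assignments; missing outcomes are handled by listwise deletion.

Calibration measured by the suite: fitted on its own generator at n=2,000
the recovery z-scores are standard normal (so a max over 33 parameters is
compared against a multiplicity-adjusted bound, not 3), and over 500
correct-model replicates at n=500 the mean chi-square matches df within
Monte-Carlo error.

## Problem sizes and numerical choices

The shipped test suite and acceptance script run the full pipeline at the
1,284-vertex working resolution with cohorts of 120-500 subjects, 5-seed
model comparisons, 1,000-replicate mixed-model calibration and 500-replicate
SEM calibration; unit tests use level-1/2 icospheres where the property
under test is resolution-independent. Tolerances: spectral oracle 1e-8;
bias-correction algebra 1e-8 on the fitted slope; parametric-EB convergence
1e-6; sigma floor 1e-8; statistical recoveries use 3-SE bands derived from
the corresponding estimator's sampling theory, and Monte-Carlo checks use
3x the empirical MC SE.

## Known limitations

- The GCN trains on CPU in NumPy; it is sized for the 1,284-vertex working
  resolution, not for training at acquisition resolution.
- ComBat is the parametric EB variant; no GAM-style nonlinear age trends and
  no longitudinal ComBat.
- Bias correction is linear only.
- The SEM offers ML estimation and chi-square/df/p only; no robust/ordinal
  estimators, no fit indices beyond chi-square.
- Synthetic cohorts are structural stand-ins; none of the default effect
  sizes are calibrated to real neonatal data.
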