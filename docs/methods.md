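# Methods

This note documents the statistical procedures the package implements,
the synthetic-data model used to exercise them, and the numerical and
design choices made where the procedure itself leaves room.

## Signature expression and per-study inference

A signature response is `⟨x, w⟩` over the joint valid mask (voxels
finite in both the map and the weight pattern, inside the analysis
mask), with optional cosine scaling `⟨x, w⟩ / (‖x‖₂‖w‖₂)`. Cosine is
the default: it removes per-study scanner/scaling differences and is
bounded in [−1, 1]. Dot scaling is retained because it is linear in
the map, which is what the synthetic amplitude-recovery arithmetic
assumes; both are tested.

Vectorization uses ascending linear index with the first axis fastest
(Fortran order), stated so dot products are bit-for-bit reproducible.

Per-study statistics treat each contrast-versus-baseline map as the
paired difference itself, so the baseline score is exactly 0:

- two-tailed one-sample *t* test of the scores against 0;
- `d_a = mean / SD` of the scores;
- forced-choice accuracy = fraction of strictly positive scores (a
  score of exactly 0 counts as incorrect — the conservative
  convention);
- 95% CI for `d_a` from the Hedges–Olkin large-sample two-group
  variance `var(d) = (n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))` with
  `n₁ = n₂ = N` and a normal quantile (1.96). The two-group form with
  both sizes set to the study N, and the normal (not *t*) quantile,
  are deliberate: this is the convention that reproduces published
  interval bounds for one-sample contrast designs to three decimals.

Spatial similarity is a Pearson correlation of voxel vectors; with a
binary parcel as reference it is the point-biserial correlation. Group
inference on correlations is performed on the Fisher-z scale
(`z = atanh r`), with the mean reported back on the r scale. The
repeated-measures comparison across signatures is a one-way
within-subject ANOVA (`df₁ = k−1`, `df₂ = (k−1)(n−1)`, error = the
subject × signature interaction) with Bonferroni-corrected paired *t*
tests against the reference signature.

FDR control is Benjamini–Hochberg step-up, applied separately per
contrast map; the attained p-threshold is reported (0 when nothing
survives).

## Classification

**Single-interval (pain / no-pain).** The cutoff maximizes overall
accuracy on the data it is given (in-sample, as is conventional when a
single validation set is used); ties take the lowest such cutoff, and
candidate cutoffs are midpoints between adjacent distinct scores plus
the two outer boundaries. Reported alongside: empirical AUROC
(Mann–Whitney U with ties counted ½), the binormal ROC fitted from
class means and SDs without an equal-variance assumption
(`AUC = Φ((μ₁−μ₀)/√(σ₀²+σ₁²))`), the discriminability index `d_a`
(so `AUC = Φ(d_a/√2)` under equal variances), and binomial proportion
SEs `√(p(1−p)/n)`. The balanced-accuracy SE combines the class-wise
proportion SEs as `½√(SE_sens² + SE_spec²)`.

**Network classifier.** Features are the seven Fisher-z point-biserial
correlations of a map with the atlas parcels, in fixed atlas order.
The model is unregularized maximum-likelihood logistic regression
(somatic coded 1), fitted by IRLS/Newton with deviance tolerance 1e−8
and at most 100 iterations. Complete or quasi-separation is detected
(deviance collapsing toward 0, or coefficient growth without deviance
improvement), surfaced as a warning with iterations capped and the
last iterate returned — never silently regularized. Wald SEs and
normal two-tailed p-values accompany the coefficients.

Cross-validation is stratified k-fold (default 10) with a mandatory
seed; each subject's probability comes from the model not trained on
its fold; the deployable model is the unweighted mean of the fold
coefficient vectors. The decision threshold defaults to probability
0.5; the accuracy-maximizing threshold on the CV probabilities is also
computed and stored, since published pipelines do not always state
which is applied prospectively. Stability assessment repeats the
whole k-fold procedure with fresh fold randomizations and summarizes
the SD of classification error and the mean pairwise Pearson
correlation of coefficient vectors.

Generalization tests report the proportion of a held-out study
classified somatic with its binomial SE, and a two-sided exact
binomial test against a configurable reference rate (default 0.6249).
The two-sided convention is the doubled smaller tail capped at 1; the
minimum-likelihood convention is deliberately not used (the two can
differ materially, e.g. 0.083 vs 0.0625 for 13/15 against 0.6249).
For some inputs (e.g. 10/15 against 0.6249) the doubled-tail p of
0.965 is close to but not identical with values reported elsewhere as
0.97; no convention we examined reproduces that value exactly.

## Group-level GLM, conjunction, masked differences

Per voxel of the joint valid mask, ordinary least squares with design
columns: one indicator per modality (cell means) plus study nuisance
dummies centered within modality, one reference study per modality
dropped to keep the design full rank. Contrasts (somatic, visceral,
their average, and the two differences) give `t = c'β̂ / √(c'(X'X)⁻¹c σ̂²)`
with `df = n − rank(X)` and two-tailed p. Rank-deficient designs are
rejected with the offending columns named.

Conjunction follows the minimum-statistic logic applied to
already-thresholded maps: a voxel is jointly significant only when
significant with the same sign in both inputs (the literal
intersection reading). Difference maps are inclusively masked: for
"activation stronger in A", positive difference voxels are kept only
where A-versus-baseline is itself significantly positive; for
"deactivation stronger in A", negative difference voxels where
A-versus-baseline is significantly negative.

## Robust brain–behavior regression

Ratings are regressed on signature scores with study dummies by IRLS
under a Tukey bisquare loss, tuning constant 4.685 (the 95% Gaussian
efficiency value), residual scale MAD/0.6745, convergence 1e−8 on the
coefficients, at most 50 iterations (statsmodels RLM provides the
solver). Inference on the slope uses the robust-fit covariance with a
two-tailed *t* reference at `df = n − p`; several robust-covariance
conventions exist in the wild, so this one is fixed, documented, and
tested against its own oracles rather than against any published SE.
The final IRLS weights feed a weighted correlation: both variables are
residualized against the covariates by weighted least squares, then
`r_w = Σw e_x e_y / √(Σw e_x² · Σw e_y²)`. An exactly linear relation
(zero residual scale) short-circuits to the least-squares fit with
unit weights, since the IRLS scale estimate is then ill-defined.

## Synthetic cohort generator

The generator produces multi-study cohorts of smooth 3-D contrast
maps with the structure the analysis stages assume. Per subject:

    x_i = study_offset + a_i · W + Σ_k g_k(modality) · parcel_k + ε_i

- **Grid and mask.** Default 16×16×16 voxels; the analysis mask is a
  centered ellipsoid (~2100 voxels), a brain stand-in.
- **Atlas.** Seven parcels as the cores of Voronoi cells around random
  seed voxels (the closest 60% of each cell). The union deliberately
  does not cover the mask — like real network atlases — which keeps
  the seven parcel-indicator features linearly independent; with
  exactly tiling parcels the feature covariance acquires a
  near-degenerate direction that makes in-sample separation trivial
  and classifier coefficients meaningless.
- **Signature W.** Unit-norm smoothed Gaussian field, exactly
  orthogonalized against every parcel indicator (mean removed within
  each parcel and the leftover region). Real signatures are
  fine-grained within-region weightings nearly uncorrelated with
  coarse network masks; orthogonality also prevents the subject
  amplitude channel from leaking into the network features.
- **Noise.** White Gaussian noise smoothed with a periodic-boundary
  Gaussian kernel (FWHM default 2 voxels) and scaled to unit marginal
  SD; periodic boundaries make the field stationary so the SD of its
  projection onto W, σ_proj = σ_noise·‖k∗W‖/‖k‖, is available in
  closed form. Spatial autocorrelation matters: without it the
  voxel-wise FDR/conjunction stages behave unrealistically.
- **Amplitudes and calibration.** a_i ~ Normal(d_true·σ_total, τ) with
  σ_total = √(τ² + σ_proj²) and τ = σ_proj by default. This makes the
  population standardized mean of the score distribution equal d_true
  exactly, so the sample `d_a` of the scores is an unbiased estimate
  of the planted effect and forced-choice accuracy tends to Φ(d_true).
  Between-subject amplitude variability of the order of the scan-noise
  projection is also what lets ratings (coupled to a_i) correlate with
  scores, as they do in real data.
- **Network loadings.** Somatic stimulation loads positively on the
  somatomotor and attention parcels and negatively on frontoparietal/
  default; visceral the reverse — the double dissociation the
  classifier is meant to recover. The loading scale is calibrated so a
  two-study training cohort (15 visceral + 33 somatic) has
  feature-space discriminability of about d = 2, the regime where
  cross-validated AUROC lands near 0.9; stronger loadings drive every
  fold into complete separation, weaker ones drop AUROC below the
  range of interest.
- **Ratings.** rating_i = b·a_i + Normal(0, σ_r) on a VAS-like 0–100
  scale (b = 20 per amplitude unit, σ_r = 8 by default); baseline
  ratings are 0 by construction, mirroring designs where rest is not
  rated. Control (no-pain) studies have NaN ratings. Optional gross
  outliers (fraction, ±shift) exercise the robust stage.

Fixed seed ⇒ byte-identical cohorts.

**What the generator does not emulate:** anatomy, hemodynamics,
inter-voxel structure beyond stationary Gaussian smoothness,
non-Gaussian noise, registration/resampling error, or any spatial
correspondence to real networks. Passing recovery tests therefore
demonstrates the correctness and calibration of the *statistical*
machinery under its stated assumptions, not performance on real fMRI.

## Problem sizes in the test and acceptance suites

Simulation-based checks use 12³–16³ grids, study sizes of 15–89
subjects, 10–50 replicates for recovery means and 100 replicates for
sign-recovery frequencies — sizes chosen so Monte-Carlo error is well
inside the asserted margins while the whole suite stays quick on one
core. Oracle-parity checks (AUROC vs pair counting, BH vs its
definition, GLM vs per-voxel OLS refits, conjunction vs the voxelwise
rule) run on 100 random instances each.

## Known limitations

- No resampling: all volumes entering a joint computation must share a
  grid; real-data users must pre-align inputs.
- The GLM assumes homoscedastic Gaussian residuals per voxel; no
  robust/permutation variant and no cluster-extent inference.
- The binormal ROC is a method-of-moments Gaussian fit, not a
  maximum-likelihood binormal fit to rating categories.
- With strongly separable training data the logistic coefficients are
  unstable in absolute size (separation is flagged); their signs, CV
  probabilities and fold-averaged predictions remain usable, which is
  what the pipeline relies on.
- The cohort loader expects the layout written by `write_cohort`;
  arbitrary external datasets need their own metadata assembly.
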