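# Methods

## Overview

`morphoscore` implements a single-cell morphological-profiling pipeline
for case/control fibroblast cohorts: segmentation of nuclei and
per-cell cytoplasm from five-channel fields, extraction of 124
morphological features per cell, per-run normalization to negative
controls, per-cell logistic-regression probability scoring,
individual-level group statistics (t-test, ROC/AUC, fold difference),
and transfer of a frozen classifier to drug-treated cells with an
ANOVA/Tukey rescue call. All statistics operate on per-cell feature
tables; the imaging stages exist so the whole chain can be exercised on
rendered synthetic fields with known ground truth.

## The feature set

Commercial high-content platforms compute proprietary feature
catalogues; this package fixes an open, analytically testable set of
31 features per marker × 4 markers = 124 per cell. Markers map to
(mask, channel) pairs: nucleus → (nucleus mask, nucleus stain);
mitochondria and acetylated α-tubulin → (cytoplasm mask, their
channels); cell → (cytoplasm mask, phase contrast). Per marker:

| family      | n | definition |
|-------------|---|------------|
| morph       | 4 | area (px²·pixel_size²); length/width = full extents on the principal axes of the mask pixel covariance (+1 px for pixel width); roundness = 4πA/P², clipped to (0,1] |
| intensity   | 5 | mean, population SD, min, max, sum of in-mask intensities |
| symmetry    | 8 | s_XY = \|Σ w e^{iYθ}\| / Σ w about the intensity-weighted centroid, w = I·g_X(r), g₀=1, g₁=exp(−r/r̄), Y ∈ {2,3,4,5} |
| compactness | 4 | for the brightest fraction q ∈ {.1,.2,.3,.4} of in-mask pixels S_q: √(\|S_q\|/π) / (√2·R_g), R_g the RMS radius of S_q about its centroid; a solid disc scores 1 |
| axial       | 2 | from eigenvalues λ₁ ≥ λ₂ of the mask covariance: length = 4√λ₁, ratio = √(λ₂/λ₁) |
| radial      | 2 | intensity-weighted mean radius r̄ = ΣIr/ΣI and its relative deviation |
| profile     | 2 | with d = distance-transform depth scaled to [0,1]: inner = intensity fraction at d ≥ 0.5; depth = ΣId/ΣI |
| texture     | 4 | Hessian/gradient filters at scale σ (default 1 px), below |

Numerical choices worth knowing:

* **Perimeter.** The marching-squares contour of a raw binary mask
  overestimates curved boundaries by ~7% (staircase effect), which
  would push a disc's roundness to 0.87. The contour is therefore taken
  on the mask smoothed with a 1-px Gaussian; a rasterised disc of
  radius 20 then scores roundness 0.993 and a square 0.82 (analytic
  π/4 ≈ 0.785).
* **Compactness ties.** A uniform object makes "the brightest fraction
  q" ill-defined; ties are broken centre-outwards, so a uniform disc
  selects a concentric disc and scores exactly 1, and results are
  deterministic.
* **Texture (SER-style).** With h₁ ≤ h₂ the Hessian eigenvalues of the
  σ-smoothed channel: spot = mean max(0, −h₂) (both principal
  curvatures negative — a strict bright-blob test); hole =
  mean max(0, h₁); edge = mean gradient magnitude; valley =
  mean max(0, −h₁ − \|h₂\| − \|∇I\|/σ). The valley penalties matter: the
  skirt of any radially symmetric blob has tangential curvature −I/σ²
  everywhere, so a bare −h₁ filter reads blobs as ridges; subtracting
  \|h₂\| removes isotropic curvature and the gradient term removes
  slopes (a true crest has ∇I ≈ 0). All four are averaged over the mask
  eroded by ⌈2σ⌉ px and divided by mean region intensity, making them
  gain-invariant.

Invariance properties (tested): translation exactly; 90° rotation to
discretization tolerance; intensity features scale linearly with
channel gain while symmetry, compactness, axial ratio, roundness,
radial relative deviation, profile and texture are gain-invariant.

## Segmentation

Nuclei: Otsu threshold of the Gaussian-smoothed (σ = 2 px) nucleus
channel, small components removed, touching nuclei split by watershed
on the negated distance transform seeded at its local maxima
(min peak distance 5 px). Cytoplasm: marker-controlled watershed over
the thresholded whole-cell channel seeded at the nucleus labels, so
cytoplasm k ⊇ nucleus k and labels partition the foreground; a nucleus
with no surrounding signal keeps its own region. 4-connectivity
throughout; 0-based (row, col) coordinates. This is a functional
stand-in for proprietary instrument software, not a replica; on the
package's rendered fields it recovers the planted cell count exactly
for non-touching configurations and ≥ 0.9 per-cell Jaccard.

## Scoring model

Features of the chosen marker subset are standardized to the training
cells' mean/SD *inside* the model (stored, so a frozen model transfers
to new data unchanged). The fit is unpenalized maximum-likelihood
logistic regression (Newton-Raphson); quasi-separation or a singular
Hessian triggers one fallback refit with ridge penalty 1e-6 and a
logged warning. The unpenalized in-sample fit satisfies Σ p̂ = n₁
(tested at 1e-6 relative), and scores are invariant to affine
rescaling of any input feature.

**In-sample vs held-out scoring.** The default workflow scores the
training cells themselves, reproducing the original SPSS-style
procedure. This is fine for describing a fitted separation, but it is
*structurally incapable of a negative result at the individual level*:
the mass-balance identity puts class-1 cells above class-0 on average
in-sample, and averaging hundreds of cells per individual removes the
noise, so even a signal-free cohort yields AUC ≈ 1. The package
therefore also provides `cross_validated_scores`, which scores every
cell with a model that never saw it. Folds hold out whole individuals
(cells of one person share that person's random effect, so cell-level
folds still leak identity) and are stratified by group (otherwise a
fold rich in one class trains on a class-poor set whose intercept
shifts every score in the fold, biasing the null AUC below 0.5 —
measured at ≈ 0.40 unstratified vs 0.49 stratified). Null calibration
(mean individual-level AUC ≈ 0.5) holds only for held-out scores, and
that is how the package computes it.

## Individual-level statistics

Every inference uses one number per individual — the mean of their
cells' probabilities. Groups are compared with Student's equal-variance
t-test (Welch by flag); degenerate zero-variance cases return t = 0,
p = 1 for equal means and an underflow-safe minimum p (1e-300)
otherwise. ROC is computed over individuals; AUC uses the Mann-Whitney
rank identity with ties counted ½, which equals the trapezoidal
integral of the threshold-sweep curve to 1e-12 (tested, including
ties). Fold difference = group-1 mean probability / group-0 mean
probability. The conventional single-feature baseline aggregates one
named raw feature to per-individual means and runs the same t-test —
the comparator that multivariate scoring is meant to beat. No
multiple-testing correction across marker sets by default (raw
p-values are reported); a Bonferroni flag exists.

## Normalization and reproducibility

Features are z-scored against negative-control (group-0, untreated)
cells per (run, feature): x' = (x − μ_ctrl,run)/σ_ctrl,run, with a
configurable floor of 30 control cells per run. Near-zero-variance
features (σ < 1e-12) are flagged and passed through unscaled to keep
the 124-column contract. This removes any per-run affine batch effect
(tested by planting run offsets of 1.5 SD and verifying removal) and is
idempotent on already-normalized controls. The cross-run
reproducibility check fits run-A-vs-run-B logistic regression and
reports per-individual mean probabilities per run, scored held-out by
cell-level CV (in-sample fits separate even exchangeable runs by the
mass-balance identity); runs are "reproducible" when every individual's
run means differ by less than 0.05.

## Treatment transfer and rescue

The case-vs-control model is frozen (coefficients and standardization
byte-identical before and after) and applied to drug-treated patient
cells; a guard refuses to score cells whose (individual, treatment)
pairs were in the training data. Individual means of the three groups —
untreated control, untreated patient, treated patient — enter one-way
ANOVA with Tukey HSD. Rescue status at level α (default 0.05):
`rescued` iff treated differs from untreated patients (p < α) and not
from controls (p ≥ α); `partial` iff it differs from neither but its
mean lies strictly between theirs; `not_rescued` otherwise. Both Tukey
p-values are reported verbatim because near-threshold calls flip with
α. By default the untreated means entering the ANOVA are themselves
held-out (CV-by-individual) scores: in-sample scoring depresses class-0
means relative to the honestly transferred treated scores, a
systematic offset Tukey would misread as a drug effect
(`untreated_scoring="insample"` restores the naive workflow).

## The synthetic generator

Feature-table mode (the primary test vehicle) draws each cell's
124-vector as

x = μ + Δ·[group 1] + b_ind + ε (+ run offset),

with μ = 0, Δ = effect_size·√(1 + individual_sd²) on `affected_count`
features chosen reproducibly from the seed (so a pooled-SD
standardized difference recovers `effect_size`); b_ind ~ N(0,
individual_sd²) per feature, shared by all of an individual's cells —
this makes individuals, not cells, the unit of replication;
ε unit-variance Gaussian, equicorrelated (default ρ = 0.3) within each
(marker, family) block so the classifier faces collinear inputs; and
optional per-(run, feature) offsets for batch-effect studies. A
treated copy of each patient multiplies Δ by (1 − reversion), globally
or per marker — mirroring a drug that reverts, say, tubulin morphology
but not mitochondrial. Identical configuration ⇒ bit-identical tables.

Default cohort geometry follows the study design being emulated: 9
controls vs 10 patients, 500 cells per individual, individual-effect
SD 0.3, shift 1.5 pooled-SD on 40 of 124 features. Per-feature effect
sizes of the real genotypes are unknown; these are free parameters of
the artifact, not biological estimates.

Image mode renders five channels (smoothed nucleus ellipses,
star-shaped cell bodies, elongated mitochondrial blobs, tubulin
filament strokes, textured phase contrast) with Poisson/Gaussian noise
and returns ground-truth label masks and per-cell geometry. It is a
geometric phantom, not a microscopy simulation: no PSF, no z-structure,
no staining variability. Passing segmentation/feature tests on it shows
the chain is self-consistent, not that it matches a real instrument.

What the generator does *not* emulate: heavy-tailed and skewed feature
distributions, cell-cycle and density covariates, plate-position
effects, segmentation errors correlated with phenotype. Passing tests
on it validates the statistical machinery under its stated model, not
performance on real fibroblast images.

## Problem sizes and regimes used in the checks

* Strong-effect anchor: 10 vs 9 individuals × 500 cells, shift 1.5 SD
  on 40 features — combined-marker individual-level AUC = 1.00
  (in-sample, as in the original workflow).
* Null calibration: 200 replicate cohorts of 15 vs 15 × 200 cells,
  effect 0, held-out scoring — mean AUC ≈ 0.5 (seed-to-seed SE of the
  200-replicate mean ≈ 0.011).
* Rescue recovery: effect 0.5 SD × 40 features with individual SD 0.1.
  Two regimes fail for instructive reasons and are avoided: at shift
  1.5 SD × 40 features the per-cell probabilities saturate at exactly
  0/1, within-group variances collapse and Tukey contrasts become
  erratic; at weak shifts with large individual effects the transferred
  scores track individual identity (treated cells share their untreated
  counterparts' random effects) rather than treatment. The chosen
  regime is strong at the individual level, unsaturated per cell, and
  genotype-dominated.

## Known limitations

* The feature definitions are open reconstructions of the families a
  proprietary platform computes; absolute values are not comparable to
  instrument exports.
* In-sample probability scoring is reported because it reproduces the
  published workflow, but its individual-level AUC is optimistically
  biased whenever between-individual variation exists; use the CV
  scores for any claim about discrimination.
* ANOVA/Tukey on 5-per-group individual means assumes approximate
  normality of the means; saturated probability scores violate it.
* No confidence intervals on AUC; no dose-response modelling; no
  plate-position correction.
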