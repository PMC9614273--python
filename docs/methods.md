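# Methods

This note documents the models, conventions and numerical choices behind
`robustrad`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Reliability model

Feature and model robustness are both one-way random, single-rater
intraclass correlations, ICC(1,1): patients are subjects, perturbations are
raters,

    ICC(1,1) = (MS_R − MS_W) / (MS_R + (k − 1) MS_W),

with MS_R the between-subject and MS_W the within-subject (residual) mean
square of the one-way ANOVA and k the number of raters. Negative estimates
are reported raw, never clipped: the filtering thresholds (0, 0.75, 0.95)
make clipping irrelevant and raw values aid diagnostics. A matrix with zero
total variance has no defined ICC; per-feature tables flag such features as
missing and the robustness filter treats them as non-robust. The optional
95% confidence interval uses the standard F-distribution interval and is
for reporting only. Model robustness applies the same estimator to the
matrix of continuous classifier scores (decision function or positive-class
probability) of the test patients across perturbation replicates — hard
labels would make the ICC degenerate.

Generalizability is AUC_test − AUC_train (negative when the model degrades
on unseen data); group comparisons use two-sided paired t-tests across CV
splits with raw p-values (no multiplicity correction), pairing by split.

## Perturbation chain

Each sampled perturbation applies, in order: rigid transform → noise field
→ contour randomization. The order is a convention (the constraint must be
checked on the final mask); whether noise precedes or follows resampling is
not identifiable from the protocol this emulates, and is documented here as
our choice.

* **Rigid**: rotation about the SI axis through the mask centroid (axis
  choice is a convention), translation in mm; image resampled with cubic
  B-spline, mask with linear interpolation + 0.5 threshold
  (binary-preserving). Output grid equals input grid.
* **Noise**: zero-mean Gaussian field with sd = level × sigma_base. The
  levels 0–3 carry no physical units in the source protocol; sigma_base
  defaults to 10 HU per level (monotone, zero-preserving, configurable).
* **Contours**: a 3-channel white-noise field smoothed with a 5 mm Gaussian
  kernel, scaled to a mean surface displacement (default 2 mm), used to
  warp the mask; candidates are rejection-sampled (default 100 attempts)
  until Dice ≥ 0.75 and Hausdorff ≤ 5 mm versus the pre-randomization mask.
  Failure raises an error naming the violated constraint. Hausdorff is the
  classical 100th-percentile surface distance in mm, no percentile
  relaxation.
* **Grid**: translations are taken literally as non-negative shifts 0–3 mm
  per axis (16 values/axis → 4,096 vectors), preserving the published
  factorial of 4,423,680; symmetric negative shifts are not added. Per
  patient, draws are a pure function of (seed, patient id) via hashing, so
  any patient's perturbation stream can be replayed independently.

## Preprocessing and features

Images are resampled to 1 mm isotropic (B-spline; masks binary-preserving),
re-segmented to the soft-tissue window [−150, 180] HU (an empty result is a
flagged warning state, downstream features go missing rather than failing),
and discretized per ROI with fixed bin counts {50..350} spanning the ROI
min–max, upper-edge-inclusive bins. The filter bank is the original image,
Laplacian-of-Gaussian at σ ∈ {1, 3, 6} mm (implemented as the discrete
Laplacian of the Gaussian-smoothed image, σ²-normalized, so constants map
exactly to zero) and a single-level undecimated coiflet-1 wavelet transform
(8 sub-bands LLL..HHH on the image grid, mirror boundary). The wavelet is
implemented directly from the published 6-tap coiflet-1 filters because no
wavelet library is assumed present.

Feature families: first-order (population moments; entropy/uniformity on the
per-bin-count histogram; kurtosis is the raw, non-excess form), 3-D shape,
and GLCM/GLRLM/GLSZM textures with the standard reference formulas — 13
unique distance-1 directions, symmetric co-occurrence, features averaged
over directions (not matrix-merged); size zones use 26-connectivity.
Feature-count parity with any specific extractor configuration is a
non-goal; names follow `{image}_{bins}_{class}_{feature}`.

**Surface area.** Marching-cubes meshes of binary masks systematically
overestimate smooth surfaces (staircase bevels, ~+9% on a digital sphere)
and underestimate polyhedra (chamfered corners, ~−6% on a cube), so neither
phantom class is measured faithfully. We instead use the convex hull of the
surface-voxel corner points, isotropically rescaled so the hull volume
matches the voxel volume. This removes the half-voxel dilation bias: a
digital cube measures its exact face area and a digital 20 mm sphere its
analytic area to well under 1%. Known limitation: strongly concave masks
are underestimated; tumor-like blobs are convex enough for this trade-off.
Degenerate (flat) masks fall back to exposed-face counting.

## Selection and modeling

Per training set: (1) bootstrap-ANOVA ranking — 100 class-balancing
downsample bootstraps (majority sampled without replacement to the minority
size), one-way ANOVA p per feature, hits at p < 0.1, top 10% of the
post-filter candidate pool by hit frequency (ties: mean p, then name);
(2) correlation pruning — among pairs with |Pearson r| > 0.6, remove the
member with the higher mean absolute correlation to the remaining features,
iterate, cap at 10 by rank. The alternative mRMR selector uses greedy
forward selection with relevance mapped to the correlation scale,
√(F/(F+dof)) (point-biserial |r|), minus mean |r| redundancy — raw F would
make the redundancy term negligible.

Classifiers (ridge, RBF-SVC, kNN, decision tree, MLP) run inside a pipeline
that standardizes on training statistics; hyperparameters come from small
documented grids (ridge α and MLP α log-spaced, SVC C log-spaced, kNN
neighbors {3,5,7,9}, tree depth {2,3,5,∞}) tuned by stratified inner 3-fold
CV maximizing AUC (falling back to defaults when the minority class is too
small to fold). Feature ICC is always computed from training-side patients
only; the test suite asserts this with an engineered feature whose
robustness differs between the two sides of a split.

## Synthetic worlds

The phantom-image generator produces soft-tissue backgrounds (~40 ± 10 HU)
with one ellipsoidal object per patient (radii 8–14 mm) whose interior is
60 HU plus two zero-mean heterogeneity components: spatially smoothed noise
(correlation length ~4 mm — robust to perturbation) and voxel-scale white
noise (fragile). Event cases scale both components by (1 + texture_effect),
so outcome signal exists at both robustness scales. It emulates: single
lesions, HU-range intensities, strong class imbalance. It does not emulate:
anatomy, partial-volume effects, scanner spectra, multi-lesion disease —
a green test on phantoms establishes pipeline correctness and directional
behavior, not clinical performance.

The feature-table generator is calibrated in closed form: replicate r of
subject i is x_ij + e_ijr with Var(e) solved from ρ = σ_b²/(σ_b² + σ_w²),
σ_b² = 1 + p(1−p)d² (d the class effect, p the event rate). A target ICC of
0 yields pure rater noise. Two modeling-relevant conventions: the
unperturbed table is itself one measurement draw (a fragile feature is
noisy in every acquisition, which is what couples robustness to
generalizability), and informative features can share latent "texture
family" factors (radiomic signal is redundant across features of differing
robustness; that redundancy is why filtering fragile features need not cost
held-out discrimination).

**Canonical benchmark world** (`generate_benchmark_tables`): 200 patients,
50 events, 300 features; the 276 null features draw target ICCs from
Beta(4.24, 1.29) quantiles, chosen so the survivor fractions match those
published for real head-and-neck CT cohorts (~60% above 0.75, ~11% above
0.95, median ~0.8); 24 informative features split evenly across ICC tiers
0.98/0.85/0.40 with standardized effect 0.6 (moderate held-out
discrimination, not saturated) over four latent families at within-family
r ≈ 0.6. These values are this package's own conventions — no synthetic
benchmark exists in the literature this emulates — and were frozen before
the acceptance thresholds were finalized; the weak link of the directional
effect is the 0 → 0.75 generalizability step, which is also the step that
real-data reports show as marginal or occasionally reversed.

## Numerical and degenerate-input conventions

* Identical seeds give bit-identical cohorts, tables, perturbation draws and
  experiment records; all randomness flows from `numpy` SeedSequences keyed
  by (seed, purpose, patient).
* Constant discretization input → single bin with a warning; constant ROI →
  zero variance/entropy, uniformity 1, skewness/kurtosis defined as 0.
* Balanced classes in the downsample bootstrap break the minority/majority
  tie deterministically (first class is "minority").
* AUC uses midranks (ties count ½); both classes required.
* Paired t-tests refuse zero-variance differences rather than returning
  infinities.
* NIfTI is the supported volume format (spacing from the affine; masks
  binarized at > 0); NRRD is not supported in this build.

## Limitations

* The image-space route (perturb + re-extract per patient) is intended for
  phantoms and method studies; at clinical scale (hundreds of patients × 60
  perturbations × thousands of features) it needs batch parallelism that
  this package deliberately leaves to the caller.
* Surface area is hull-based (see above) and will underestimate strongly
  concave segmentations.
* The synthetic benchmark reproduces directions and rough magnitudes of the
  real-data findings, not their exact values, which depend on cohorts that
  are out of scope here.
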