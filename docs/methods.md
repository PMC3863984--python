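# Methods

## The classification model

`hearmri` fits a two-layer discriminative model to a cohort of spatially
normalized brain images, one structural volume and three functional
contrast maps per subject, with a binary group label (HI = hearing
impaired, positive class; NH = normal hearing) and a 3-level sedation
covariate. The model assumes:

* all volumes live on a common voxel grid (spatial normalization has
  already happened; registration error appears only as feature jitter);
* group differences manifest as blob-like structural components detectable
  by SIFT on 2D slices, and as spatially coherent activation or
  deactivation regions in the contrast maps;
* the positive class is rare enough that per-class error rates matter,
  hence thresholds are set by balancing false-positive and false-negative
  rates rather than raw error.

### Structural arm

SIFT keypoints are extracted per cube (default side 20 voxels) and slice
orientation, giving 133-number features (3D center, scale, orientation,
unit-normalized 128-number descriptor). Similarity between features uses
four strict inequalities with defaults ε_x = 0.5 (center distance in units
of the query scale), ε_σ = 2/3 (absolute log scale ratio), ε_o = π/2
(circular orientation difference, radians) and ε_a = 0.45 (descriptor
Euclidean distance). The likelihood score is the log ratio of similar-set
occurrence frequencies in patient vs healthy brains; features with
|L| > ε_l = 0.9 become patient/healthy exemplars, the rest are noise.
Per-group linear 3-class SVMs (one-vs-rest, standardized inputs) reproduce
those labels so new subjects need no pairwise comparisons. The subject
score Csum sums predicted labels; the decision threshold ε_s is the
smallest candidate (midpoints of sorted unique training scores plus
sentinels) minimizing |FPR − FNR| on the training cohort.

Numerical choices:

* **Scale similarity is symmetric.** The signed log ratio ln(σ_j/σ_i)
  under a one-sided positive threshold would accept every smaller-scale
  candidate; we use |ln(σ_j/σ_i)|.
* **Support condition.** A likelihood is only awarded when
  |S_i| ≥ support_min, default N_P + N_C (about one similar feature per
  training brain). This makes the arm blind to markers carried by only a
  minority of one group — a real property of the method, not an
  implementation artifact.
* **Additive smoothing.** Empty intersections are handled by a pseudocount
  α = 1 added to both intersection counts and both brain counts; α = 0
  reproduces the raw ratio with ±∞ capped at 50. The smoothing is
  symmetric, so swapping the group labels negates every nonzero score.
* **Degenerate groups.** A (cube, orientation) group whose training
  features carry a single label class gets a constant predictor; groups
  absent from training are skipped at prediction time (contribute 0).
* **Detector settings.** 20 × 20 slices of smooth volumes carry little
  contrast, so the DoG threshold defaults to 0.004 (library default 0.013)
  with 2× upsampling; slices that are constant, too small for the scale
  pyramid, or yield no keypoints contribute no features.
* **Axis convention.** Volume axes (i, j, k); sagittal fixes axis 0,
  coronal axis 1, axial axis 2; slices are the 2D arrays over the two
  remaining axes in ascending order. Any fixed convention works as long as
  training and prediction share it.

An optional grid-search helper is *not* run by default: the shipped
defaults are the published operating point (ε_o ∈ {π/4, π/2, 3π/4},
ε_a ∈ {0.3 … 0.5}, ε_l ∈ {0.1 … 1.2} were the historical search ranges).

### Functional arm

Per contrast map the top ⌈0.05·n⌉ voxels of each sign class (over non-zero
voxels, optionally masked; ties at the cutoff broken by voxel index) are
componentized under 26-connectivity, separately per sign so activation and
deactivation never mix. All components from all subjects form the
dictionary (ordered by contrast, then subject, then component), and each
subject becomes the vector of mean contrast values over every dictionary
ROI — including ROIs discovered in other subjects.

**Column merging.** Redundant ROI columns are merged by average-linkage
hierarchical clustering (Euclidean distance across subjects) cut at an
inconsistency coefficient of 0.01 (depth 2), replacing each cluster by its
member mean. The textbook inconsistency statistic is 0 for any link whose
depth-neighborhood has zero height spread — notably every leaf-pair link —
so a literal cutoff would merge all mutual-nearest-neighbour column pairs
no matter how distant. Degenerate links therefore qualify only at height 0
(duplicate columns); all others use the classic coefficient. This keeps
the cut's stated purpose (merge redundant ROIs, leave distinct ones) and
makes merging idempotent.

**Selection and scoring.** CFS merit uses absolute Pearson correlations
(labels encoded ±1; a Spearman variant is available via config;
zero-variance features count as correlation 0). The best-first search
starts from the empty set, expands single-feature flips, keeps an open
list ordered by merit as its backtracking facility, and stops after 5
consecutive expansions without improving the best merit. If no subset
achieves positive merit, the single best-correlated feature is used. The
final classifier is a linear SVM (C = 1) on the selected features,
standardized with training statistics; the decision value is the
fMRI_score, HI iff ≥ ε_f = 0 (boundary inclusive). Feature importance
accumulates |SVM weight| over the folds that selected the feature; merged
ROIs inherit their joint feature's importance.

### Fusion and evaluation

The second layer is a linear SVM with C = 1 on the raw 2D
(Csum, fMRI_score) training pairs — no standardization, as the space is
two-dimensional and C is part of the method definition. First-layer scores
for second-layer training are in-sample (each arm scores the subjects it
was trained on); an out-of-fold variant is deliberately not the default,
matching the protocol this package reproduces.

Leave-one-out evaluation trains everything on N−1 subjects and scores the
held-out one. Reported metrics: specificity/sensitivity/accuracy apply the
training-derived thresholds (ε_s balanced on training scores; ε_f = ε_i =
0) to held-out scores; AUC is the trapezoidal area under the ROC of pooled
held-out scores; the EER accuracy re-thresholds the pooled held-out scores
where |FPR − FNR| is minimal (candidates are midpoints of sorted unique
scores plus sentinels; ties pick the lower threshold; with completely
uninformative scores the all-positive sentinel wins, so the value
degenerates to the HI prevalence). Selection stability is the mean
pairwise Jaccard similarity of per-fold selected sets, with two empty
selections counting as identical.

By default the ROI dictionary is built from **all** subjects including the
held-out one (`dictionary_scope="all_subjects"`), reproducing the
small-sample protocol of the original study; `"train_only"` rebuilds the
dictionary and merging per fold from training subjects only, at the price
of a fold-dependent feature space (stability and importance are then
undefined across folds).

## The synthetic cohort generator

No suitable infant cohort is publicly deposited, so the generator emulates
the *statistical role* of the inputs:

* **Anatomy**: a smooth ellipsoidal background (amplitude ≈ 1, arbitrary
  units) plus fixed-location Gaussian blobs (radius 2.5 voxels) — shared
  anatomy blobs in everyone, and discriminative blobs whose amplitude
  differs between groups by `blob_effect` at sites that alternate which
  group they favor (producing both patient- and healthy-type features).
  Blobs are mildly anisotropic so the SIFT orientation assignment is
  stable across subjects; perfectly isotropic blobs get noise-driven
  orientations that defeat the ε_o gate. I.i.d. Gaussian noise of sd
  `noise_sd` is added.
* **Contrast maps**: spatially smoothed noise inside an ellipsoidal brain
  mask (fMRI has spatial autocorrelation; smoothing also keeps the top-5%
  voxel set in a manageable number of connected components), plus
  activation/deactivation sites with group-dependent amplitude
  (base 0.5 ± `activation_effect` for the favored group) and per-subject
  random nuisance blobs.
* **Covariates**: sedation ∈ {1, 2, 3} uniform and group-independent by
  default; a `sedation_confounded` flag couples it to group for studying
  the sedation features.
* Site placement is deterministic given the grid (centers, then
  quarter-points, of interior 20-blocks), so planted structure survives
  cube partitioning and identical specs give voxel-identical cohorts.
* Per-site, per-subject response gains are N(1, `subject_variability`)
  clipped below at 0.15, so moderate effects yield imperfect,
  subject-dependent arms. A `modality_balance` option lets alternating
  subjects express predominantly the structural or the functional marker;
  note the likelihood support condition makes the structural arm
  intrinsically insensitive to markers carried by only half a group.

Defaults (9 HI + 10 NH, 60 × 60 × 40 grid, effects 0.75, noise 0.08,
variability 0.5) give single-arm performance around 0.85–0.95 AUC —
informative but imperfect, the regime the method was designed for. The
generator does **not** emulate MR physics, motion or ghosting artifacts,
template construction, realistic pediatric anatomy, or correlated
anatomical/functional noise; passing tests therefore demonstrate the
correctness and calibration of the pipeline, not clinical performance.

## Problem sizes

Test and report computations use scaled-down grids so the whole suite runs
comfortably on one CPU: 40 × 40 × 20 (4 cubes) for null calibration (10
zero-effect cohorts of 4+4 subjects) and the overwhelming-effect check
(3+3 subjects, effects 2.5), and 60 × 60 × 40 (18 cubes) with 9+10
subjects and effects 1.2 for the two-marker fusion cohort. The full
157 × 189 × 136 grid is supported throughout and used for the structural
partition constants.

## Known limitations

* In-sample first-layer scores make the second layer optimistic: when one
  arm separates its training set perfectly with margin 1 (common for the
  fMRI SVM at small N), the max-margin fusion can lean almost entirely on
  that arm. Pooled-score AUC also mixes fold-specific affine score scales.
  Both are properties of the reproduced protocol; the out-of-fold stacking
  option exists for users who want unbiased fusion.
* The likelihood support condition (|S_i| ≥ N_P + N_C) requires candidate
  structures in essentially every training brain; rare-subgroup structural
  markers are invisible to the sMRI arm.
* 2D SIFT on 20-voxel slices detects blobs of roughly 1.5–6 voxel scale;
  structures much larger than a cube are only seen through their edges.
* CFS with continuous Pearson correlations is a deliberate choice; the
  original CFS literature used discretized measures.
* Csum is an unnormalized count: subjects with more detected features get
  larger magnitudes, which ε_s absorbs only partially.
* On null (zero-effect) cohorts of a handful of subjects, leave-one-out
  AUC is mildly pessimistic (below 0.5 on average): removing a subject
  tilts the training class balance against its own class, a well-known
  small-sample LOOCV artifact. The null-calibration check averages over
  cohorts and tolerates this within sampling error.
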