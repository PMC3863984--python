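# hearmri

Two-layer classification of infant hearing impairment from structural and
functional MR images.

Congenital sensori-neural hearing loss (SNHL) alters both brain structure
and the cortical response to sound. `hearmri` implements a stacked
classifier that separates hearing-impaired (HI) from normal-hearing (NH)
infants using spatially normalized T1 volumes and per-condition functional
contrast maps (speech vs. silence, speech vs. tones, tones vs. silence),
together with the full leave-one-out evaluation protocol and a synthetic
cohort generator so the whole pipeline can be exercised without clinical
data. It is aimed at neuroimaging methods researchers studying multimodal
classifier fusion and high-level (non-voxelwise) MR feature extraction.

## Method

**Structural arm (SIFT likelihood scoring).** The normalized volume
(157 × 189 × 136, or any scaled-down grid) is tiled into 20³ cubes — 560 on
the full grid — and each cube is sliced along the axial, coronal and
sagittal orientations. A 2D SIFT detector turns every slice into keypoints,
each a 133-number vector (3D center x, scale σ, orientation o, 128-number
appearance descriptor a). Within each (cube, orientation) group, the
similar feature set of feature *i* is

    S_i = { f_j : ‖x_i − x_j‖₂/σ_i < ε_x  ∧  |ln(σ_j/σ_i)| < ε_σ
                   ∧  Δo(i,j) < ε_o  ∧  ‖a_i − a_j‖₂ < ε_a }

with defaults ε_x = 0.5, ε_σ = 2/3, ε_o = π/2, ε_a = 0.45. Its likelihood
score contrasts occurrence frequencies in patient (P) vs healthy (C)
training brains,

    L_i = ln[ (|S_i ∩ P| / N_P) / (|S_i ∩ C| / N_C) ]   if |S_i| ≥ N_P + N_C, else 0,

and features are labeled patient (+1) if L_i > ε_l (= 0.9), healthy (−1) if
L_i < −ε_l, noise (0) otherwise. A linear 3-class SVM per (cube,
orientation) group learns these labels, so a new subject is scored as
Csum = Σ ĈL_i without any pairwise comparisons; the subject is HI iff
Csum > ε_s, with ε_s balancing training FPR and FNR.

**Functional arm (bag-of-words + CFS).** Per contrast map, the top 5% most
positive and most negative voxels are kept, componentized under
26-connectivity (signs never merge), and every component becomes a
dictionary "word". Each subject is the vector of mean contrast values over
all dictionary ROIs; duplicate columns are merged by average-linkage
clustering with an inconsistency cut at 0.01, and a 3-level one-hot
sedation encoding is appended. Features are selected by CFS merit

    M_S = k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)

via best-first search with backtracking (stop after 5 non-improving
expansions), and a linear SVM gives the fMRI_score (HI iff ≥ 0).

**Fusion.** A linear SVM with C = 1 in the 2D (Csum, fMRI_score) space
yields y = w₁·Csum + w₂·fMRI_score + bias, HI iff y ≥ 0. Evaluation is
leave-one-out: per-fold thresholds from the training subjects, pooled
held-out scores for accuracy/AUC/EER, plus the mean pairwise Jaccard
stability of the per-fold CFS selections.

## Worked example

```python
from hearmri import CohortSpec, generate_cohort, TwoLayerModel, loocv

spec = CohortSpec(n_hi=3, n_nh=3, grid_shape=(40, 40, 20), seed=0,
                  blob_effect=2.5, activation_effect=2.5,
                  noise_sd=0.05, subject_variability=0.2)
model = TwoLayerModel(generate_cohort(spec))
print(model.fit().summary())

results = loocv(model)
print(results.summary().round(2))
print(f"stability index: {results.stability_index():.3f}")
```

prints

```
Two-layer sMRI + fMRI classifier
================================================
subjects: 6 (HI 3, NH 3)
sMRI: 12 (cube, orientation) feature classifiers, eps_s = -10.500
fMRI: 4 CFS-selected features of 117, eps_f = 0
second layer: y = +0.0121*Csum +0.0001*fMRI_score +0.1273, HI iff y >= 0

             Specificity  Sensitivity  Accuracy  AUC  EER
sMRI                 1.0          1.0       1.0  1.0  1.0
fMRI                 1.0          1.0       1.0  1.0  1.0
sMRI + fMRI          1.0          1.0       1.0  1.0  1.0

stability index: 0.117
```

The planted group effect (2.5 intensity units against 0.05 noise) is
overwhelming, so all three classifiers separate the six subjects perfectly
in leave-one-out; the low stability index reflects that with many redundant
ROI features, different folds pick interchangeable selections.

The same pipeline is available from the shell:

```bash
hearmri simulate --n-hi 9 --n-nh 10 --seed 0 --out cohort/
hearmri evaluate --cohort cohort/manifest.csv --out results/ --roc-plot
```

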