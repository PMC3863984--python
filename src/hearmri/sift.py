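"""SIFT-feature likelihood scoring for structural MR volumes.

Every 2D slice of every cube is run through a standard 2D SIFT detector.
Each keypoint becomes a 133-number feature: 3 global voxel coordinates of
the center, a scale, an orientation and a unit-normalized 128-number
appearance descriptor.  Features are evaluated within their
(cube, slice-orientation) group only:

* the *similar feature set* ``S_i`` of feature ``i`` collects every
  candidate ``j`` with ``Δx(i,j) < ε_x``, ``Δσ(i,j) < ε_σ``,
  ``Δo(i,j) < ε_o`` and ``Δa(i,j) < ε_a`` (strict inequalities), where
  ``Δx = ‖x_i − x_j‖₂ / σ_i`` (note: normalized by the *query* scale, so
  similarity is asymmetric), ``Δσ = |ln(σ_j/σ_i)|``, ``Δo`` is the circular
  orientation difference and ``Δa`` the Euclidean descriptor distance;
* the *likelihood score* contrasts how often similar features occur in
  patient vs healthy training brains,
  ``L_i = ln[(|S_i∩P|/N_P) / (|S_i∩C|/N_C)]`` when ``|S_i|`` reaches a
  minimum support (default ``N_P + N_C``), else 0.  Additive smoothing
  (pseudocount ``alpha``, default 1) guards empty intersections;
* features are labeled patient (+1) when ``L_i > ε_l``, healthy (−1) when
  ``L_i < −ε_l``, noise (0) otherwise.

A linear 3-class SVM per (cube, orientation) group learns to reproduce
these labels from the 133-number vectors, so new subjects are scored
without recomputing similar sets: a subject's structural score ``Csum`` is
the sum of its features' predicted labels, and the subject is called HI
when ``Csum`` exceeds a threshold ``ε_s`` chosen on the training cohort so
that training false-positive and false-negative rates balance.

Default thresholds: ``ε_x = 0.5``, ``ε_σ = 2/3``, ``ε_o = π/2``,
``ε_a = 0.45``, ``ε_l = 0.9``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import SIFT as _SkimageSIFT
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .grid import (
    GeometryError,
    SliceStack,
    local_to_global,
    partition_cubes,
    slice_cube,
)

TWO_PI = 2.0 * np.pi
#: cap on |L_i| when smoothing is disabled and an intersection is empty
LIKELIHOOD_CAP = 50.0


class DomainError(ValueError):
    pass


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimilarityThresholds:
    """Strict upper bounds for the four similarity criteria."""

    eps_x: float = 0.5
    eps_sigma: float = 2.0 / 3.0
    eps_o: float = np.pi / 2.0
    eps_a: float = 0.45

    def __post_init__(self):
        if min(self.eps_x, self.eps_sigma, self.eps_o, self.eps_a) <= 0:
            raise ValueError("similarity thresholds must be positive")
        if self.eps_o > np.pi:
            raise ValueError("eps_o cannot exceed pi (circular difference range)")


@dataclass(frozen=True)
class SiftConfig:
    """Detector, similarity and labeling parameters of the sMRI arm.

    The detector contrast threshold ``c_dog`` defaults well below the
    library default because 20 x 20 slices of smooth volumes carry little
    contrast.
    """

    cube_side: int = 20
    upsampling: int = 2
    c_dog: float = 0.004
    c_edge: float = 10.0
    thresholds: SimilarityThresholds = field(default_factory=SimilarityThresholds)
    eps_l: float = 0.9
    support_min: int | None = None  # None -> N_P + N_C
    alpha: float = 1.0
    svm_C: float = 1.0


@dataclass
class SiftFeature:
    """One keypoint in 133-number vector form plus provenance."""

    x: np.ndarray  # (3,) global voxel coordinates
    sigma: float
    orient: float  # radians in [0, 2pi)
    appearance: np.ndarray  # (128,) unit Euclidean norm
    subject_id: str = ""
    group: str = "unknown"
    cube_index: tuple[int, int, int] = (0, 0, 0)
    orientation: str = ""

    def as_vector(self) -> np.ndarray:
        """The 133-number form: center (3), scale, orientation, appearance (128)."""
        return np.concatenate(
            [np.asarray(self.x, dtype=float), [self.sigma, self.orient], self.appearance]
        )


# ---------------------------------------------------------------------------
# extraction


def extract_sift(
    stack: SliceStack,
    subject_id: str = "",
    group: str = "unknown",
    config: SiftConfig | None = None,
) -> list[SiftFeature]:
    """Detect SIFT keypoints on every slice of a stack.

    Slices without detectable structure (constant intensity, too small for
    the scale pyramid) simply contribute no features.
    """
    config = config or SiftConfig()
    features: list[SiftFeature] = []
    for slice_index, image in enumerate(stack.slices):
        img = np.ascontiguousarray(image, dtype=np.float32)
        if min(img.shape) < 8 or np.ptp(img) == 0:
            continue
        det = _SkimageSIFT(
            upsampling=config.upsampling, c_dog=config.c_dog, c_edge=config.c_edge
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                det.detect_and_extract(img)
        except (RuntimeError, IndexError, ValueError):
            continue  # no detectable features on this slice
        positions = getattr(det, "positions", det.keypoints)
        for p, sigma, orient, desc in zip(
            positions, det.sigmas, det.orientations, det.descriptors
        ):
            row = min(max(float(p[0]), 0.0), img.shape[0] - 1e-9)
            col = min(max(float(p[1]), 0.0), img.shape[1] - 1e-9)
            try:
                x = local_to_global(stack.cube, stack.orientation, slice_index, (row, col))
            except GeometryError:
                continue
            a = np.asarray(desc, dtype=float)
            norm = np.linalg.norm(a)
            if norm > 0:
                a = a / norm
            features.append(
                SiftFeature(
                    x=np.asarray(x, dtype=float),
                    sigma=float(sigma),
                    orient=float(orient) % TWO_PI,
                    appearance=a,
                    subject_id=subject_id,
                    group=group,
                    cube_index=stack.cube.cube_index,
                    orientation=stack.orientation,
                )
            )
    return features


def extract_subject_features(
    volume: np.ndarray,
    subject_id: str = "",
    group: str = "unknown",
    config: SiftConfig | None = None,
) -> list[SiftFeature]:
    """Extract SIFT features from every cube and orientation of a volume."""
    config = config or SiftConfig()
    features: list[SiftFeature] = []
    for cube in partition_cubes(volume.shape, config.cube_side):
        for stack in slice_cube(volume, cube).values():
            features.extend(extract_sift(stack, subject_id, group, config))
    return features


# ---------------------------------------------------------------------------
# similarity metrics (Δx, Δσ, Δo, Δa)


def delta_x(fi: SiftFeature, fj: SiftFeature) -> float:
    """Center distance in units of the query feature's scale."""
    if fi.sigma <= 0:
        raise DomainError("query feature has non-positive scale")
    return float(np.linalg.norm(np.asarray(fi.x, float) - np.asarray(fj.x, float)) / fi.sigma)


def delta_sigma(fi: SiftFeature, fj: SiftFeature) -> float:
    """Scale difference |ln(sigma_j / sigma_i)| (scale-symmetric)."""
    if fi.sigma <= 0 or fj.sigma <= 0:
        raise DomainError("features must have positive scale")
    return float(abs(np.log(fj.sigma / fi.sigma)))


def delta_o(fi: SiftFeature, fj: SiftFeature) -> float:
    """Circular orientation difference in [0, pi]."""
    d = abs(fi.orient - fj.orient)
    return float(min(d, TWO_PI - d))


def delta_a(fi: SiftFeature, fj: SiftFeature) -> float:
    """Euclidean distance between unit-normalized appearance descriptors."""
    return float(np.linalg.norm(fi.appearance - fj.appearance))


def similar_set(
    fi: SiftFeature,
    candidates: list[SiftFeature],
    thresholds: SimilarityThresholds | None = None,
) -> list[SiftFeature]:
    """All candidates similar to ``fi`` (all four deltas strictly below threshold)."""
    thr = thresholds or SimilarityThresholds()
    if fi.sigma <= 0:
        raise DomainError("query feature has non-positive scale")
    out = []
    for fj in candidates:
        if (
            delta_x(fi, fj) < thr.eps_x
            and delta_sigma(fi, fj) < thr.eps_sigma
            and delta_o(fi, fj) < thr.eps_o
            and delta_a(fi, fj) < thr.eps_a
        ):
            out.append(fj)
    return out


def pairwise_similarity(
    X: np.ndarray,
    sigma: np.ndarray,
    orient: np.ndarray,
    A: np.ndarray,
    thresholds: SimilarityThresholds,
) -> np.ndarray:
    """Boolean similarity matrix, rows = query features (vectorized ``similar_set``).

    Asymmetric because Δx and Δσ are normalized by the query feature.
    """
    d = X[:, None, :] - X[None, :, :]
    dx = np.sqrt((d ** 2).sum(-1)) / sigma[:, None]
    dsig = np.abs(np.log(sigma[None, :] / sigma[:, None]))
    do = np.abs(orient[:, None] - orient[None, :])
    do = np.minimum(do, TWO_PI - do)
    g = A @ A.T
    sq = np.clip(np.diag(g)[:, None] + np.diag(g)[None, :] - 2 * g, 0, None)
    da = np.sqrt(sq)
    t = thresholds
    return (dx < t.eps_x) & (dsig < t.eps_sigma) & (do < t.eps_o) & (da < t.eps_a)


# ---------------------------------------------------------------------------
# feature bank and likelihood scoring


class FeatureBank:
    """Training features grouped by (cube_index, orientation).

    ``N_P`` / ``N_C`` are the numbers of distinct patient (HI) and healthy
    (NH) brains contributing features.
    """

    def __init__(self, features: list[SiftFeature]):
        if not features:
            raise DomainError("empty feature bank")
        self.features = features
        self.groups: dict[tuple, list[int]] = {}
        for idx, f in enumerate(features):
            self.groups.setdefault((f.cube_index, f.orientation), []).append(idx)
        subjects = {f.subject_id: f.group for f in features}
        self.N_P = sum(1 for g in subjects.values() if g == "HI")
        self.N_C = sum(1 for g in subjects.values() if g == "NH")

    def group_arrays(self, key):
        idx = self.groups[key]
        feats = [self.features[i] for i in idx]
        return (
            np.array(idx),
            np.stack([f.x for f in feats]),
            np.array([f.sigma for f in feats]),
            np.array([f.orient for f in feats]),
            np.stack([f.appearance for f in feats]),
            np.array([f.group == "HI" for f in feats]),
            np.array([f.group == "NH" for f in feats]),
        )


def likelihood_score(
    S_i: list[SiftFeature],
    bank: FeatureBank,
    support_min: int | None = None,
    alpha: float = 1.0,
) -> float:
    """Log patient-vs-healthy occurrence ratio of the similar feature set."""
    if bank.N_P < 1 or bank.N_C < 1:
        raise DomainError("bank needs at least one brain per group")
    if support_min is None:
        support_min = bank.N_P + bank.N_C
    n_p = sum(1 for f in S_i if f.group == "HI")
    n_c = sum(1 for f in S_i if f.group == "NH")
    return _likelihood_from_counts(
        len(S_i), n_p, n_c, bank.N_P, bank.N_C, support_min, alpha
    )


def _likelihood_from_counts(n_s, n_p, n_c, N_P, N_C, support_min, alpha):
    if n_s < support_min:
        return 0.0
    if alpha == 0.0:
        if n_p == 0 and n_c == 0:
            return 0.0
        if n_c == 0:
            return LIKELIHOOD_CAP
        if n_p == 0:
            return -LIKELIHOOD_CAP
        return float(np.log((n_p / N_P) / (n_c / N_C)))
    return float(
        np.log(((n_p + alpha) / (N_P + alpha)) / ((n_c + alpha) / (N_C + alpha)))
    )


def label_feature(L_i: float, eps_l: float = 0.9) -> int:
    """Patient (+1) / healthy (−1) / noise (0) label from the likelihood score."""
    if eps_l <= 0:
        raise ValueError("eps_l must be positive")
    if L_i > eps_l:
        return 1
    if L_i < -eps_l:
        return -1
    return 0


def score_bank(bank: FeatureBank, config: SiftConfig | None = None) -> np.ndarray:
    """Likelihood score of every bank feature against the bank itself.

    Similar sets are computed within the feature's own (cube, orientation)
    group only.
    """
    config = config or SiftConfig()
    support = (
        config.support_min if config.support_min is not None else bank.N_P + bank.N_C
    )
    L = np.zeros(len(bank.features))
    for key in bank.groups:
        idx, X, sig, ori, A, is_p, is_c = bank.group_arrays(key)
        sim = pairwise_similarity(X, sig, ori, A, config.thresholds)
        n_s = sim.sum(axis=1)
        n_p = (sim & is_p[None, :]).sum(axis=1)
        n_c = (sim & is_c[None, :]).sum(axis=1)
        for r, i in enumerate(idx):
            L[i] = _likelihood_from_counts(
                int(n_s[r]), int(n_p[r]), int(n_c[r]),
                bank.N_P, bank.N_C, support, config.alpha,
            )
    return L


# ---------------------------------------------------------------------------
# per-(cube, orientation) feature classifiers


class _ConstantPredictor:
    def __init__(self, label: int):
        self.label = label

    def predict(self, V):
        return np.full(len(V), self.label, dtype=int)


@dataclass
class SmriModel:
    """Trained sMRI arm: per-group 3-class feature classifiers + thresholds."""

    classifiers: dict[tuple, object]
    scalers: dict[tuple, object]
    config: SiftConfig
    eps_s: float = 0.0

    def predict_labels(self, features: list[SiftFeature]) -> np.ndarray:
        """Predicted class label of each feature; untrained groups predict 0."""
        labels = np.zeros(len(features), dtype=int)
        by_group: dict[tuple, list[int]] = {}
        for i, f in enumerate(features):
            by_group.setdefault((f.cube_index, f.orientation), []).append(i)
        for key, idx in by_group.items():
            clf = self.classifiers.get(key)
            if clf is None:
                continue  # group not seen in training: skip its features
            V = np.stack([features[i].as_vector() for i in idx])
            scaler = self.scalers.get(key)
            if scaler is not None:
                V = scaler.transform(V)
            labels[idx] = clf.predict(V)
        return labels

    def csum(self, features: list[SiftFeature]) -> float:
        """Structural score: sum of predicted labels (noise contributes 0)."""
        if not features:
            return 0.0
        return float(self.predict_labels(features).sum())

    def classify(self, csum_value: float) -> str:
        return "HI" if csum_value > self.eps_s else "NH"


def train_feature_classifiers(
    bank: FeatureBank, labels: np.ndarray, config: SiftConfig | None = None
) -> SmriModel:
    """Fit one linear 3-class SVM per (cube, orientation) group.

    Inputs are the 133-number vectors, standardized with training
    statistics; groups whose features carry a single label class get a
    constant predictor instead.
    """
    config = config or SiftConfig()
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(bank.features):
        raise TrainingError("labels must align with bank features")
    classifiers: dict[tuple, object] = {}
    scalers: dict[tuple, object] = {}
    for key, idx in bank.groups.items():
        y = labels[np.array(idx)]
        present = np.unique(y)
        if len(present) == 1:
            classifiers[key] = _ConstantPredictor(int(present[0]))
            scalers[key] = None
            continue
        V = np.stack([bank.features[i].as_vector() for i in idx])
        scaler = StandardScaler().fit(V)
        clf = LinearSVC(C=config.svm_C, multi_class="ovr", max_iter=5000, random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(scaler.transform(V), y)
        classifiers[key] = clf
        scalers[key] = scaler
    return SmriModel(classifiers=classifiers, scalers=scalers, config=config)


def select_eps_s(csums: np.ndarray, labels_hi: np.ndarray) -> float:
    """Smallest Csum threshold balancing training FPR and FNR.

    Decision rule is ``HI iff Csum > eps_s``; candidates are sentinels plus
    midpoints between consecutive sorted unique training scores.
    """
    csums = np.asarray(csums, dtype=float)
    labels_hi = np.asarray(labels_hi, dtype=bool)
    uniq = np.unique(csums)
    candidates = [uniq[0] - 1.0]
    candidates += [0.5 * (a + b) for a, b in zip(uniq[:-1], uniq[1:])]
    candidates += [uniq[-1] + 1.0]
    n_pos = labels_hi.sum()
    n_neg = (~labels_hi).sum()
    best, best_gap = candidates[0], np.inf
    for t in candidates:
        pred = csums > t
        fpr = (pred & ~labels_hi).sum() / max(n_neg, 1)
        fnr = (~pred & labels_hi).sum() / max(n_pos, 1)
        gap = abs(fpr - fnr)
        if gap < best_gap - 1e-12:
            best, best_gap = t, gap
    return float(best)


def train_smri(
    features: list[SiftFeature], config: SiftConfig | None = None
) -> tuple[SmriModel, np.ndarray]:
    """Full sMRI training: likelihoods, labels, classifiers.

    Returns the model (``eps_s`` not yet set) and the per-feature labels.
    """
    config = config or SiftConfig()
    bank = FeatureBank(features)
    L = score_bank(bank, config)
    labels = np.array([label_feature(v, config.eps_l) for v in L], dtype=int)
    model = train_feature_classifiers(bank, labels, config)
    return model, labels
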