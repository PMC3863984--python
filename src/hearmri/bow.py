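"""Bag-of-words vectorization of functional contrast maps, CFS and the fMRI arm.

Per contrast map, the top 5% most positive and top 5% most negative voxels
(ranked within their sign class) are kept and merged into 26-connected
components; each sign-pure component is a region of interest (ROI), a
"word".  The words from all subjects and all three contrasts form a
dictionary, and every subject is represented by the mean contrast value
over each dictionary ROI's voxels (the word's "frequency").  Near-duplicate
ROIs detected in several subjects are merged by average-linkage
hierarchical clustering of the feature columns (Euclidean distance across
subjects) cut at an inconsistency coefficient of 0.01, averaging the member
columns.  A 3-level one-hot sedation encoding is appended.

Feature selection uses the CFS merit

    M_S = k * mean|r_cf| / sqrt(k + k (k-1) * mean|r_ff|)

(feature-class vs feature-feature Pearson correlations) explored by
best-first search with single-feature flips and a backtracking open list,
stopping after 5 consecutive non-improving expansions.  A linear SVM on the
selected, standardized features yields the per-subject ``fMRI_score``; a
subject is called HI when the score is >= eps_f (default 0).
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, inconsistent, linkage
from scipy.ndimage import label as cc_label
from sklearn.svm import SVC

from .synthetic import CONTRASTS

_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


class InputError(ValueError):
    pass


@dataclass
class Roi:
    """A sign-pure, 26-connected voxel set from one subject's contrast map."""

    voxels: np.ndarray  # (n, 3) int voxel indices
    contrast: str
    source_subject: str
    sign: int  # +1 or -1


@dataclass
class RoiDictionary:
    """All ROIs across subjects, in a fixed recorded order (grouped by contrast)."""

    rois: list[Roi]
    per_contrast: dict[str, int]
    grid_shape: tuple[int, int, int]

    @property
    def size(self) -> int:
        return len(self.rois)


@dataclass
class ColumnInfo:
    """Provenance of one feature-matrix column."""

    kind: str  # "roi" | "merged" | "sedation"
    members: list[int] = field(default_factory=list)  # dictionary ROI indices
    contrast: str = ""
    name: str = ""


@dataclass
class FeatureMatrix:
    """Subjects x features matrix with per-column provenance."""

    values: np.ndarray
    columns: list[ColumnInfo]
    subject_ids: list[str]


@dataclass(frozen=True)
class ClusterConfig:
    linkage: str = "average"
    inconsistency_cutoff: float = 0.01
    depth: int = 2

    def __post_init__(self):
        if self.inconsistency_cutoff <= 0:
            raise ValueError("inconsistency cutoff must be positive")


# ---------------------------------------------------------------------------
# ROI extraction


def select_extreme_voxels(
    contrast_map: np.ndarray,
    fraction: float = 0.05,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Top-``fraction`` positive and negative voxels of a contrast map.

    Positive voxels are ranked decreasingly, negative voxels increasingly,
    each within the map's non-zero (or masked) support; ``ceil(fraction*n)``
    voxels per sign class are kept, ties at the cutoff broken by voxel index
    order.  Returns (positive, negative) arrays of shape (k, 3).
    """
    if not (0 < fraction < 1):
        raise InputError(f"fraction must be in (0, 1), got {fraction}")
    flat = contrast_map.ravel()
    support = np.flatnonzero(mask.ravel() if mask is not None else flat != 0)

    def top(sign):
        vals = flat[support]
        cand = support[vals > 0] if sign > 0 else support[vals < 0]
        if len(cand) == 0:
            return np.empty((0, 3), dtype=np.intp)
        k = int(np.ceil(fraction * len(cand)))
        order = np.lexsort((cand, -sign * flat[cand]))
        chosen = np.sort(cand[order[:k]])
        return np.stack(np.unravel_index(chosen, contrast_map.shape), axis=1)

    return top(+1), top(-1)


def connected_rois(
    positive: np.ndarray,
    negative: np.ndarray,
    grid_shape,
    contrast: str = "",
    source_subject: str = "",
) -> list[Roi]:
    """Componentize selected voxels under 26-connectivity, one sign at a time.

    Positive and negative voxels are never merged into the same ROI.
    """
    rois = []
    for sign, vox in ((1, positive), (-1, negative)):
        if len(vox) == 0:
            continue
        m = np.zeros(grid_shape, dtype=bool)
        m[tuple(vox.T)] = True
        lab, n = cc_label(m, structure=_CONNECTIVITY_26)
        for comp in range(1, n + 1):
            ids = np.argwhere(lab == comp)
            rois.append(
                Roi(voxels=ids, contrast=contrast, source_subject=source_subject, sign=sign)
            )
    return rois


def extract_subject_rois(
    contrasts: dict[str, np.ndarray],
    subject_id: str,
    fraction: float = 0.05,
    mask: np.ndarray | None = None,
) -> list[Roi]:
    """All ROIs of one subject, over the three contrast maps."""
    rois = []
    for contrast in CONTRASTS:
        pos, neg = select_extreme_voxels(contrasts[contrast], fraction, mask)
        rois.extend(
            connected_rois(pos, neg, contrasts[contrast].shape, contrast, subject_id)
        )
    return rois


def build_dictionary(
    per_subject_rois: dict[str, list[Roi]], grid_shape
) -> RoiDictionary:
    """Concatenate all subjects' ROIs in a deterministic order.

    Order: contrast (fixed condition order), then subject (input order),
    then component order within the subject's map.
    """
    if not per_subject_rois:
        raise InputError("dictionary needs ROIs from at least one subject")
    ordered: list[Roi] = []
    per_contrast: dict[str, int] = {}
    for contrast in CONTRASTS:
        n0 = len(ordered)
        for sid, rois in per_subject_rois.items():
            ordered.extend(r for r in rois if r.contrast == contrast)
        per_contrast[contrast] = len(ordered) - n0
    return RoiDictionary(rois=ordered, per_contrast=per_contrast, grid_shape=tuple(grid_shape))


def vectorize(
    contrasts: dict[str, np.ndarray], dictionary: RoiDictionary
) -> np.ndarray:
    """One subject's bag-of-words row: mean contrast value inside each ROI."""
    for c, m in contrasts.items():
        if tuple(m.shape) != dictionary.grid_shape:
            raise InputError(
                f"contrast {c} shape {m.shape} does not match dictionary grid "
                f"{dictionary.grid_shape}"
            )
    row = np.empty(dictionary.size)
    for j, roi in enumerate(dictionary.rois):
        vals = contrasts[roi.contrast][tuple(roi.voxels.T)]
        row[j] = vals.mean()
    return row


def build_feature_matrix(
    subjects, dictionary: RoiDictionary
) -> FeatureMatrix:
    """Stack bag-of-words rows for a list of subjects."""
    values = np.stack([vectorize(s.contrasts, dictionary) for s in subjects])
    columns = [
        ColumnInfo(kind="roi", members=[j], contrast=r.contrast, name=f"roi{j:04d}")
        for j, r in enumerate(dictionary.rois)
    ]
    return FeatureMatrix(values, columns, [s.subject_id for s in subjects])


# ---------------------------------------------------------------------------
# redundant-ROI merging


def _subtree_max(Z: np.ndarray, coeff: np.ndarray) -> np.ndarray:
    """Running maximum of a per-link statistic over each link's subtree."""
    n = Z.shape[0] + 1
    out = coeff.copy()
    for i in range(Z.shape[0]):  # links are ordered child-before-parent
        for child in (int(Z[i, 0]), int(Z[i, 1])):
            if child >= n:
                out[i] = max(out[i], out[child - n])
    return out


def merge_rois(matrix: FeatureMatrix, cfg: ClusterConfig | None = None) -> FeatureMatrix:
    """Merge near-duplicate ROI columns by average-linkage clustering.

    Columns are points in subject space (Euclidean distance); the dendrogram
    is cut where the inconsistency coefficient stays below the cutoff, and
    each cluster is replaced by the mean of its member columns.  Only very
    similar columns sit below an inconsistency of 0.01, so distinct ROIs
    survive unmerged.
    """
    cfg = cfg or ClusterConfig()
    p = matrix.values.shape[1]
    if p < 2:
        return matrix
    Z = linkage(matrix.values.T, method=cfg.linkage, metric="euclidean")
    # The textbook inconsistency statistic is 0 for any link whose depth
    # neighborhood has zero height spread -- notably every leaf-pair link --
    # so a raw cutoff would merge all mutual nearest neighbours no matter how
    # far apart they are.  Degenerate links therefore only qualify at height
    # 0 (duplicate columns); all other links use the classic coefficient.
    # This keeps the cut's intent (merge redundant ROIs, leave distinct ones)
    # and makes merging idempotent.
    R = inconsistent(Z, cfg.depth)
    coeff = R[:, 3].copy()
    heights = Z[:, 2]
    degenerate = R[:, 1] == 0
    coeff[degenerate] = np.where(heights[degenerate] <= 0.0, 0.0, np.inf)
    assignment = fcluster(
        Z, t=cfg.inconsistency_cutoff, criterion="monocrit",
        monocrit=_subtree_max(Z, coeff),
    )
    clusters: dict[int, list[int]] = {}
    for col, c in enumerate(assignment):
        clusters.setdefault(int(c), []).append(col)
    ordered = sorted(clusters.values(), key=lambda cols: cols[0])
    out_vals = np.empty((matrix.values.shape[0], len(ordered)))
    out_cols = []
    for j, cols in enumerate(ordered):
        out_vals[:, j] = matrix.values[:, cols].mean(axis=1)
        members = sorted({m for c in cols for m in matrix.columns[c].members})
        contrasts = {matrix.columns[c].contrast for c in cols}
        out_cols.append(
            ColumnInfo(
                kind="merged" if len(cols) > 1 else matrix.columns[cols[0]].kind,
                members=members,
                contrast=contrasts.pop() if len(contrasts) == 1 else "mixed",
                name=f"m{j:04d}",
            )
        )
    return FeatureMatrix(out_vals, out_cols, matrix.subject_ids)


def encode_sedation(method: int) -> np.ndarray:
    """One-hot encoding of the 3-level sedation covariate."""
    if method not in (1, 2, 3):
        raise InputError(f"unknown sedation method {method}")
    v = np.zeros(3)
    v[method - 1] = 1.0
    return v


def append_sedation(matrix: FeatureMatrix, sedations: list[int]) -> FeatureMatrix:
    """Append the three sedation indicator columns to a feature matrix."""
    if len(sedations) != matrix.values.shape[0]:
        raise InputError("one sedation method per subject required")
    sed = np.stack([encode_sedation(m) for m in sedations])
    cols = matrix.columns + [
        ColumnInfo(kind="sedation", name=f"sedation{m}") for m in (1, 2, 3)
    ]
    return FeatureMatrix(np.hstack([matrix.values, sed]), cols, matrix.subject_ids)


# ---------------------------------------------------------------------------
# correlation-based feature selection (CFS)


def _abs_corr_with_class(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|Pearson r| of each column with the +/-1 class labels; 0 if degenerate."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    return np.abs(np.nan_to_num(r, nan=0.0))


def _abs_corr_matrix(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    s = np.sqrt((Xc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ Xc) / np.outer(s, s)
    return np.abs(np.nan_to_num(r, nan=0.0))


class CfsScorer:
    """Caches the correlations entering the CFS merit for one training set."""

    def __init__(self, X: np.ndarray, y: np.ndarray, correlation: str = "pearson"):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if correlation == "spearman":
            from scipy.stats import rankdata

            X = np.apply_along_axis(rankdata, 0, X)
            y = rankdata(y)
        elif correlation != "pearson":
            raise ValueError(f"unknown correlation measure {correlation!r}")
        self.n_features = X.shape[1]
        self.rcf = _abs_corr_with_class(X, y)
        self.rff = _abs_corr_matrix(X)

    def merit(self, subset) -> float:
        """M_S = sum|r_cf| / sqrt(k + 2 * sum of pairwise |r_ff|)."""
        ids = np.fromiter(subset, dtype=int)
        k = len(ids)
        if k == 0:
            return 0.0
        s_cf = self.rcf[ids].sum()
        s_ff = 0.0
        if k > 1:
            sub = self.rff[np.ix_(ids, ids)]
            s_ff = (sub.sum() - np.trace(sub)) / 2.0
        return float(s_cf / np.sqrt(k + 2.0 * s_ff))


def cfs_merit(subset, labels, X, correlation: str = "pearson") -> float:
    """CFS merit of a feature subset (labels encoded +/-1)."""
    if len(subset) == 0:
        raise InputError("subset must be non-empty")
    return CfsScorer(X, labels, correlation).merit(subset)


def cfs_search(
    X: np.ndarray,
    y: np.ndarray,
    stop_after: int = 5,
    correlation: str = "pearson",
    scorer: CfsScorer | None = None,
) -> list[int]:
    """Best-first subset search over single-feature flips.

    Maintains an open list ordered by merit (the backtracking facility),
    starting from the empty set; stops after ``stop_after`` consecutive
    expansions that fail to improve the best merit found.  Returns the best
    subset as a sorted list of column indices.
    """
    scorer = scorer or CfsScorer(X, y, correlation)
    n = scorer.n_features
    root = frozenset()
    heap: list[tuple[float, int, frozenset]] = [(0.0, 0, root)]
    seen = {root}
    best_state, best_merit = root, 0.0
    counter = 1
    non_improving = 0
    while heap and non_improving < stop_after:
        _, _, state = heapq.heappop(heap)
        ids = sorted(state)
        improved = False
        # additions, vectorized via incremental sums
        s_cf = scorer.rcf[ids].sum() if ids else 0.0
        if ids:
            sub = scorer.rff[np.ix_(ids, ids)]
            s_ff = (sub.sum() - np.trace(sub)) / 2.0
            add_ff = scorer.rff[:, ids].sum(axis=1)
        else:
            s_ff = 0.0
            add_ff = np.zeros(n)
        k = len(ids)
        add_merit = (s_cf + scorer.rcf) / np.sqrt((k + 1) + 2.0 * (s_ff + add_ff))
        successors: list[tuple[frozenset, float]] = []
        for f in range(n):
            if f in state:
                continue
            successors.append((state | {f}, float(add_merit[f])))
        for f in ids:  # removals (backtracking moves)
            new = state - {f}
            successors.append((new, scorer.merit(new)))
        for new, m in successors:
            if new in seen:
                continue
            seen.add(new)
            heapq.heappush(heap, (-m, counter, new))
            counter += 1
            if m > best_merit + 1e-12:
                best_state, best_merit = new, m
                improved = True
        non_improving = 0 if improved else non_improving + 1
    return sorted(best_state)


# ---------------------------------------------------------------------------
# fMRI classifier


@dataclass
class FmriModel:
    """Linear SVM on the CFS-selected, standardized bag-of-words features."""

    selected: list[int]
    mean: np.ndarray
    sd: np.ndarray
    svm: SVC
    eps_f: float = 0.0
    n_features: int = 0

    def score(self, row: np.ndarray) -> float:
        return float(self.score_many(np.atleast_2d(row))[0])

    def score_many(self, rows: np.ndarray) -> np.ndarray:
        rows = np.asarray(rows, dtype=float)
        if rows.shape[1] != self.n_features:
            raise InputError(
                f"row has {rows.shape[1]} features, model expects {self.n_features}"
            )
        Z = (rows[:, self.selected] - self.mean) / self.sd
        return self.svm.decision_function(Z)

    def classify(self, score: float) -> str:
        return "HI" if score >= self.eps_f else "NH"

    def weights(self) -> np.ndarray:
        """SVM weight per selected feature (standardized space)."""
        return self.svm.coef_.ravel()


def train_fmri(
    X: np.ndarray,
    y_hi: np.ndarray,
    selected: list[int] | None = None,
    C: float = 1.0,
    stop_after: int = 5,
    correlation: str = "pearson",
) -> FmriModel:
    """CFS selection (unless ``selected`` given) + linear SVM with parameter C."""
    X = np.asarray(X, dtype=float)
    y = np.where(np.asarray(y_hi, dtype=bool), 1.0, -1.0)
    if selected is None:
        selected = cfs_search(X, y, stop_after=stop_after, correlation=correlation)
    if not selected:  # merit never positive: fall back to the single best feature
        selected = [int(np.argmax(_abs_corr_with_class(X, y)))]
    sub = X[:, selected]
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    svm = SVC(kernel="linear", C=C)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        svm.fit((sub - mean) / sd, y)
    return FmriModel(
        selected=list(selected), mean=mean, sd=sd, svm=svm, n_features=X.shape[1]
    )


def feature_importance(
    selections: list[list[int]], weights: list[np.ndarray], n_features: int
) -> np.ndarray:
    """Importance I_f = sum over folds of |SVM weight| where the feature was selected.

    A merged ROI inherits the importance of its joint feature.
    """
    I = np.zeros(n_features)
    for sel, w in zip(selections, weights):
        for f, wf in zip(sel, np.asarray(w, dtype=float)):
            I[f] += abs(wf)
    return I
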