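"""Leave-one-out cross-validation, EER/AUC metrics and selection stability.

In each of the N folds the held-out subject is scored by the sMRI arm
(threshold ``eps_s`` chosen so the training false-positive and
false-negative rates balance), the fMRI arm (``eps_f = 0``) and the fused
second layer (``eps_i = 0``), all trained on the other N-1 subjects.  The
accuracy column applies those training-derived thresholds to the held-out
scores; the EER column instead picks the threshold on the pooled held-out
scores where false-positive and false-negative rates are equal.  AUC is the
area under the ROC of the pooled held-out scores.  The stability of the
fMRI feature selection is the mean pairwise Jaccard similarity of the
per-fold selected feature sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from . import bow, stacking
from .model import TwoLayerModel

CLASSIFIERS = ("sMRI", "fMRI", "sMRI + fMRI")


class DomainError(ValueError):
    pass


@dataclass
class FoldResult:
    fold: int
    subject_id: str
    true_group: str
    csum: float
    fmri_score: float
    y: float
    predicted: dict[str, str]
    selected: list[int]
    eps_s: float


@dataclass
class LoocvResults:
    """Fold-by-fold scores plus the aggregate performance table."""

    folds: list[FoldResult]
    n_features: int

    def scores(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [f.subject_id for f in self.folds],
                "group": [f.true_group for f in self.folds],
                "Csum": [f.csum for f in self.folds],
                "fMRI_score": [f.fmri_score for f in self.folds],
                "y": [f.y for f in self.folds],
                "smri_pred": [f.predicted["sMRI"] for f in self.folds],
                "fmri_pred": [f.predicted["fMRI"] for f in self.folds],
                "combined_pred": [f.predicted["sMRI + fMRI"] for f in self.folds],
            }
        )

    def _scores_for(self, name: str) -> np.ndarray:
        key = {"sMRI": "csum", "fMRI": "fmri_score", "sMRI + fMRI": "y"}[name]
        return np.array([getattr(f, key) for f in self.folds])

    def _truth(self) -> np.ndarray:
        return np.array([f.true_group == "HI" for f in self.folds])

    def summary(self) -> pd.DataFrame:
        """Performance table: specificity, sensitivity, accuracy, AUC, EER."""
        truth = self._truth()
        rows = {}
        for name in CLASSIFIERS:
            pred = np.array([f.predicted[name] == "HI" for f in self.folds])
            tp = (pred & truth).sum()
            tn = (~pred & ~truth).sum()
            scores = self._scores_for(name)
            _, eer_acc = compute_eer(scores, truth)
            rows[name] = {
                "Specificity": tn / max((~truth).sum(), 1),
                "Sensitivity": tp / max(truth.sum(), 1),
                "Accuracy": (tp + tn) / len(truth),
                "AUC": compute_auc(scores, truth),
                "EER": eer_acc,
            }
        return pd.DataFrame(rows).T.loc[list(CLASSIFIERS)]

    def auc(self, name: str = "sMRI + fMRI") -> float:
        return compute_auc(self._scores_for(name), self._truth())

    def stability_index(self) -> float:
        return stability_index([f.selected for f in self.folds])

    def feature_importance(self) -> np.ndarray | None:
        """Per-feature importance I_f = sum of |fold SVM weight| over folds
        where the feature was selected.  None when the feature space differs
        across folds (``dictionary_scope = train_only``)."""
        return self._importance


def loocv(model: TwoLayerModel) -> LoocvResults:
    """Run the full leave-one-out protocol on a cohort model."""
    cfg = model.config
    ids = model.subject_ids
    if model.labels_hi.sum() < 2 or (~model.labels_hi).sum() < 2:
        raise DomainError("LOOCV needs at least two subjects per class")
    folds = []
    importances_sel: list[list[int]] = []
    importances_w: list[np.ndarray] = []
    n_features = None
    for n, test_id in enumerate(ids):
        train_ids = [s for s in ids if s != test_id]
        truth_hi = np.array(
            [model.smri_cache.group_of[s] == "HI" for s in train_ids]
        )
        smri_model = model.smri_cache.train_fold(train_ids)
        csums_train = np.array(
            [model.smri_cache.csum(smri_model, s) for s in train_ids]
        )
        csum_test = model.smri_cache.csum(smri_model, test_id)

        tr, te, _ = model.fmri_cache.fold_matrices(train_ids, test_id)
        n_features = tr.shape[1] if n_features is None else n_features
        fmri_model = bow.train_fmri(
            tr, truth_hi, C=cfg.fmri_C,
            stop_after=cfg.cfs_stop_after, correlation=cfg.correlation,
        )
        fmri_model.eps_f = cfg.eps_f
        fscores_train = fmri_model.score_many(tr)
        fscore_test = fmri_model.score(te)

        second = stacking.train_second_layer(
            np.column_stack([csums_train, fscores_train]), truth_hi,
            C=cfg.second_layer_C, eps_i=cfg.eps_i,
        )
        y_test = second.score(csum_test, fscore_test)

        folds.append(
            FoldResult(
                fold=n,
                subject_id=test_id,
                true_group="HI" if model.labels_hi[n] else "NH",
                csum=csum_test,
                fmri_score=fscore_test,
                y=y_test,
                predicted={
                    "sMRI": smri_model.classify(csum_test),
                    "fMRI": fmri_model.classify(fscore_test),
                    "sMRI + fMRI": second.classify(y_test),
                },
                selected=list(fmri_model.selected),
                eps_s=smri_model.eps_s,
            )
        )
        importances_sel.append(list(fmri_model.selected))
        importances_w.append(fmri_model.weights())
    results = LoocvResults(folds=folds, n_features=int(n_features))
    if cfg.dictionary_scope == "all_subjects":
        results._importance = bow.feature_importance(
            importances_sel, importances_w, int(n_features)
        )
    else:  # feature spaces differ across folds; importance is undefined
        results._importance = None
    return results


# ---------------------------------------------------------------------------
# metrics


def _candidate_thresholds(scores: np.ndarray) -> list[float]:
    uniq = np.unique(scores)
    cands = [uniq[0] - 1.0]
    cands += [0.5 * (a + b) for a, b in zip(uniq[:-1], uniq[1:])]
    cands += [uniq[-1] + 1.0]
    return cands


def compute_eer(scores, labels_hi) -> tuple[float, float]:
    """Equal-error-rate threshold and accuracy.

    Candidate thresholds are midpoints between consecutive sorted unique
    scores plus sentinels below and above all scores; the threshold
    minimizing |FPR - FNR| wins (ties: the lower threshold), with the
    decision rule HI iff score >= threshold.  The EER accuracy is
    ``1 - (FPR + FNR)/2`` at that threshold.  With completely
    uninformative (identical) scores the all-positive sentinel wins, so the
    reported accuracy is the HI prevalence — a documented degenerate edge.
    """
    scores = np.asarray(scores, dtype=float)
    labels_hi = np.asarray(labels_hi, dtype=bool)
    n_pos, n_neg = labels_hi.sum(), (~labels_hi).sum()
    if n_pos == 0 or n_neg == 0:
        raise DomainError("EER needs both classes")
    best_t, best_gap, best_acc = None, np.inf, 0.0
    for t in _candidate_thresholds(scores):
        pred = scores >= t
        fpr = (pred & ~labels_hi).sum() / n_neg
        fnr = (~pred & labels_hi).sum() / n_pos
        gap = abs(fpr - fnr)
        if gap < best_gap - 1e-12:
            best_t, best_gap, best_acc = t, gap, 1.0 - (fpr + fnr) / 2.0
    return float(best_t), float(best_acc)


def compute_auc(scores, labels_hi) -> float:
    """Area under the ROC (trapezoidal; equals the pairwise-ranking probability)."""
    scores = np.asarray(scores, dtype=float)
    labels_hi = np.asarray(labels_hi, dtype=bool)
    if labels_hi.all() or not labels_hi.any():
        raise DomainError("AUC needs both classes")
    fpr, tpr, _ = roc_curve(labels_hi.astype(int), scores)
    return float(_trapezoid_auc(fpr, tpr))


def stability_index(selected_sets: list) -> float:
    """Mean pairwise Jaccard similarity of the per-fold selected feature sets.

    Two empty selections count as identical (similarity 1).
    """
    sets = [set(s) for s in selected_sets]
    c = len(sets)
    if c < 2:
        raise DomainError("stability index needs at least two selection rounds")
    total = 0.0
    for i in range(c - 1):
        for j in range(i + 1, c):
            union = sets[i] | sets[j]
            total += 1.0 if not union else len(sets[i] & sets[j]) / len(union)
    return 2.0 * total / (c * (c - 1))
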