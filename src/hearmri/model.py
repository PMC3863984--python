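"""Model/Results interface tying the two arms and the fusion layer together.

:class:`TwoLayerModel` is constructed from a cohort (in-memory subjects or a
manifest file) and a :class:`PipelineConfig`; ``fit()`` trains the sMRI
likelihood arm, the fMRI bag-of-words arm and the second-layer fusion SVM
on the full cohort and returns a :class:`TwoLayerResults` carrying the
fitted parameters, the training score table and ``summary()``.
Leave-one-out evaluation lives in :mod:`hearmri.evaluate` and reuses the
expensive cohort-level caches (SIFT features, pairwise similarity, the ROI
dictionary) held by the model object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bow, sift, stacking
from .synthetic import SyntheticSubject, read_cohort


@dataclass(frozen=True)
class PipelineConfig:
    """Everything tunable about the two-layer pipeline."""

    sift: sift.SiftConfig = field(default_factory=sift.SiftConfig)
    cluster: bow.ClusterConfig = field(default_factory=bow.ClusterConfig)
    top_fraction: float = 0.05
    dictionary_scope: str = "all_subjects"  # or "train_only"
    correlation: str = "pearson"
    fmri_C: float = 1.0
    second_layer_C: float = 1.0
    cfs_stop_after: int = 5
    eps_f: float = 0.0
    eps_i: float = 0.0

    def __post_init__(self):
        if self.dictionary_scope not in ("all_subjects", "train_only"):
            raise ValueError(f"unknown dictionary_scope {self.dictionary_scope!r}")


class _SmriCache:
    """Cohort-level SIFT features and pairwise similarity, shared across folds.

    Similarity of a feature pair does not depend on the training split, so
    the boolean similarity matrix per (cube, orientation) group is computed
    once over all subjects and subset per fold.
    """

    def __init__(self, subjects: list[SyntheticSubject], config: sift.SiftConfig):
        self.config = config
        self.features_by_subject = {
            s.subject_id: sift.extract_subject_features(
                s.anatomical, s.subject_id, s.group, config
            )
            for s in subjects
        }
        self.group_of = {s.subject_id: s.group for s in subjects}
        self._groups: dict[tuple, dict] = {}
        for sid, feats in self.features_by_subject.items():
            for f in feats:
                g = self._groups.setdefault(
                    (f.cube_index, f.orientation), {"features": [], "subjects": []}
                )
                g["features"].append(f)
                g["subjects"].append(sid)
        for g in self._groups.values():
            feats = g["features"]
            g["sim"] = sift.pairwise_similarity(
                np.stack([f.x for f in feats]),
                np.array([f.sigma for f in feats]),
                np.array([f.orient for f in feats]),
                np.stack([f.appearance for f in feats]),
                config.thresholds,
            )
            g["subjects"] = np.array(g["subjects"])
            g["is_hi"] = np.array([f.group == "HI" for f in feats])

    def train_fold(self, train_ids: list[str]) -> sift.SmriModel:
        """Train the sMRI arm on a subset of subjects, eps_s included."""
        train_set = set(train_ids)
        N_P = sum(1 for sid in train_ids if self.group_of[sid] == "HI")
        N_C = sum(1 for sid in train_ids if self.group_of[sid] == "NH")
        if N_P < 1 or N_C < 1:
            raise sift.TrainingError("training fold lacks a class")
        support = (
            self.config.support_min
            if self.config.support_min is not None
            else N_P + N_C
        )
        train_features: list[sift.SiftFeature] = []
        labels: list[int] = []
        for g in self._groups.values():
            in_train = np.array([s in train_set for s in g["subjects"]])
            if not in_train.any():
                continue
            sim = g["sim"][np.ix_(in_train, in_train)]
            is_hi = g["is_hi"][in_train]
            n_s = sim.sum(axis=1)
            n_p = (sim & is_hi[None, :]).sum(axis=1)
            n_c = n_s - n_p
            feats = [f for f, t in zip(g["features"], in_train) if t]
            for r, f in enumerate(feats):
                L = sift._likelihood_from_counts(
                    int(n_s[r]), int(n_p[r]), int(n_c[r]),
                    N_P, N_C, support, self.config.alpha,
                )
                train_features.append(f)
                labels.append(sift.label_feature(L, self.config.eps_l))
        bank = sift.FeatureBank(train_features)
        model = sift.train_feature_classifiers(bank, np.array(labels), self.config)
        csums = np.array([self.csum(model, sid) for sid in train_ids])
        is_hi = np.array([self.group_of[sid] == "HI" for sid in train_ids])
        model.eps_s = sift.select_eps_s(csums, is_hi)
        return model

    def csum(self, model: sift.SmriModel, subject_id: str) -> float:
        return model.csum(self.features_by_subject[subject_id])


class _FmriCache:
    """Per-subject ROIs plus (for all_subjects scope) the pooled feature matrix."""

    def __init__(self, subjects: list[SyntheticSubject], config: PipelineConfig):
        self.config = config
        self.subjects = subjects
        self.ids = [s.subject_id for s in subjects]
        self.rois_by_subject = {
            s.subject_id: bow.extract_subject_rois(
                s.contrasts, s.subject_id, config.top_fraction
            )
            for s in subjects
        }
        self.dictionary = None
        self.full_matrix = None  # merged + sedation, all subjects
        if config.dictionary_scope == "all_subjects":
            self.dictionary = bow.build_dictionary(
                self.rois_by_subject, subjects[0].anatomical.shape
            )
            raw = bow.build_feature_matrix(subjects, self.dictionary)
            merged = bow.merge_rois(raw, config.cluster)
            self.full_matrix = bow.append_sedation(
                merged, [s.sedation for s in subjects]
            )

    def fold_matrices(self, train_ids: list[str], test_id: str | None):
        """(train matrix, test row, column info) for one fold."""
        if self.config.dictionary_scope == "all_subjects":
            F = self.full_matrix
            rows = {sid: i for i, sid in enumerate(F.subject_ids)}
            tr = F.values[[rows[s] for s in train_ids]]
            te = F.values[rows[test_id]] if test_id is not None else None
            return tr, te, F.columns
        # train_only: rebuild dictionary and merging from the training subjects
        train_subjects = [s for s in self.subjects if s.subject_id in set(train_ids)]
        per_subject = {
            s.subject_id: self.rois_by_subject[s.subject_id] for s in train_subjects
        }
        dictionary = bow.build_dictionary(
            per_subject, train_subjects[0].anatomical.shape
        )
        raw = bow.build_feature_matrix(train_subjects, dictionary)
        merged = bow.merge_rois(raw, self.config.cluster)
        tr = bow.append_sedation(merged, [s.sedation for s in train_subjects])
        te = None
        if test_id is not None:
            test_subject = next(s for s in self.subjects if s.subject_id == test_id)
            raw_row = bow.vectorize(test_subject.contrasts, dictionary)
            merged_row = np.array(
                [raw_row[c.members].mean() for c in merged.columns]
            )
            te = np.concatenate([merged_row, bow.encode_sedation(test_subject.sedation)])
        return tr.values, te, tr.columns


class TwoLayerModel:
    """Two-layer sMRI + fMRI hearing-impairment classifier for a cohort."""

    def __init__(
        self, subjects: list[SyntheticSubject], config: PipelineConfig | None = None
    ):
        if len(subjects) < 2:
            raise ValueError("need at least two subjects")
        self.subjects = list(subjects)
        self.config = config or PipelineConfig()
        self.subject_ids = [s.subject_id for s in self.subjects]
        self.labels_hi = np.array([s.group == "HI" for s in self.subjects])
        self._smri_cache: _SmriCache | None = None
        self._fmri_cache: _FmriCache | None = None

    @classmethod
    def from_manifest(cls, manifest_path, config: PipelineConfig | None = None):
        return cls(read_cohort(manifest_path), config)

    # caches are built lazily so cheap operations stay cheap
    @property
    def smri_cache(self) -> _SmriCache:
        if self._smri_cache is None:
            self._smri_cache = _SmriCache(self.subjects, self.config.sift)
        return self._smri_cache

    @property
    def fmri_cache(self) -> _FmriCache:
        if self._fmri_cache is None:
            self._fmri_cache = _FmriCache(self.subjects, self.config)
        return self._fmri_cache

    def fit(self) -> "TwoLayerResults":
        """Train both arms and the fusion layer on the full cohort."""
        cfg = self.config
        smri_model = self.smri_cache.train_fold(self.subject_ids)
        csums = np.array(
            [self.smri_cache.csum(smri_model, sid) for sid in self.subject_ids]
        )
        tr, _, columns = self.fmri_cache.fold_matrices(self.subject_ids, None)
        scorer = bow.CfsScorer(
            tr, np.where(self.labels_hi, 1.0, -1.0), cfg.correlation
        )
        selected = bow.cfs_search(
            tr, self.labels_hi, stop_after=cfg.cfs_stop_after, scorer=scorer
        )
        fmri_model = bow.train_fmri(tr, self.labels_hi, selected=selected, C=cfg.fmri_C)
        fmri_model.eps_f = cfg.eps_f
        fscores = fmri_model.score_many(tr)
        second = stacking.train_second_layer(
            np.column_stack([csums, fscores]),
            self.labels_hi,
            C=cfg.second_layer_C,
            eps_i=cfg.eps_i,
        )
        return TwoLayerResults(
            model=self,
            smri_model=smri_model,
            fmri_model=fmri_model,
            second_layer=second,
            train_csums=csums,
            train_fscores=fscores,
            columns=columns,
        )


@dataclass
class TwoLayerResults:
    """Fitted two-layer classifier with training-set scores."""

    model: TwoLayerModel
    smri_model: sift.SmriModel
    fmri_model: bow.FmriModel
    second_layer: stacking.SecondLayerModel
    train_csums: np.ndarray
    train_fscores: np.ndarray
    columns: list[bow.ColumnInfo]

    def score_table(self) -> pd.DataFrame:
        y = np.array(
            [
                self.second_layer.score(c, f)
                for c, f in zip(self.train_csums, self.train_fscores)
            ]
        )
        return pd.DataFrame(
            {
                "subject_id": self.model.subject_ids,
                "group": ["HI" if h else "NH" for h in self.model.labels_hi],
                "Csum": self.train_csums,
                "fMRI_score": self.train_fscores,
                "y": y,
            }
        )

    def predict(self, subjects: list[SyntheticSubject]) -> pd.DataFrame:
        """Score and classify new subjects on the trained model."""
        if self.model.config.dictionary_scope == "train_only":
            raise NotImplementedError(
                "out-of-cohort prediction is only supported with the "
                "all_subjects dictionary; rebuild the model including the "
                "new subjects or use the LOOCV driver"
            )
        rows = []
        for s in subjects:
            feats = sift.extract_subject_features(
                s.anatomical, s.subject_id, "unknown", self.model.config.sift
            )
            csum = self.smri_model.csum(feats)
            raw = bow.vectorize(s.contrasts, self.model.fmri_cache.dictionary)
            merged = np.array(
                [raw[c.members].mean() for c in self.columns if c.kind != "sedation"]
            )
            row = np.concatenate([merged, bow.encode_sedation(s.sedation)])
            fscore = self.fmri_model.score(row)
            y = self.second_layer.score(csum, fscore)
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "Csum": csum,
                    "fMRI_score": fscore,
                    "y": y,
                    "smri_label": self.smri_model.classify(csum),
                    "fmri_label": self.fmri_model.classify(fscore),
                    "combined_label": self.second_layer.classify(y),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        n_sel = len(self.fmri_model.selected)
        lines = [
            "Two-layer sMRI + fMRI classifier",
            "=" * 48,
            f"subjects: {len(self.model.subject_ids)} "
            f"(HI {int(self.model.labels_hi.sum())}, "
            f"NH {int((~self.model.labels_hi).sum())})",
            f"sMRI: {len(self.smri_model.classifiers)} (cube, orientation) "
            f"feature classifiers, eps_s = {self.smri_model.eps_s:.3f}",
            f"fMRI: {n_sel} CFS-selected features of "
            f"{self.fmri_model.n_features}, eps_f = {self.fmri_model.eps_f:g}",
            "second layer: y = "
            f"{self.second_layer.w1:+.4f}*Csum "
            f"{self.second_layer.w2:+.4f}*fMRI_score "
            f"{self.second_layer.bias:+.4f}, "
            f"HI iff y >= {self.second_layer.eps_i:g}",
        ]
        return "\n".join(lines)
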