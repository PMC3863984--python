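import itertools

import numpy as np
import pytest

from hearmri.bow import (
    CfsScorer,
    ColumnInfo,
    FeatureMatrix,
    InputError,
    build_dictionary,
    build_feature_matrix,
    cfs_merit,
    cfs_search,
    connected_rois,
    encode_sedation,
    extract_subject_rois,
    feature_importance,
    merge_rois,
    select_extreme_voxels,
    train_fmri,
    vectorize,
)
from hearmri.synthetic import CONTRASTS, CohortSpec, generate_cohort


class TestExtremeVoxels:
    def test_top_fraction_count_rule(self, rng):
        vol = np.zeros((10, 10, 1))
        vals = rng.permutation(np.arange(1.0, 41.0))
        vol.flat[:40] = vals  # 40 positive voxels -> ceil(0.05*40) = 2
        pos, neg = select_extreme_voxels(vol, 0.05)
        assert len(pos) == 2 and len(neg) == 0
        chosen = {vol[tuple(v)] for v in pos}
        assert chosen == {39.0, 40.0}

    def test_negation_swaps_signs_not_selection(self, rng):
        vol = rng.normal(0, 1, (8, 8, 4))
        pos, neg = select_extreme_voxels(vol, 0.1)
        pos2, neg2 = select_extreme_voxels(-vol, 0.1)
        assert np.array_equal(pos, neg2) and np.array_equal(neg, pos2)

    def test_matches_brute_force_sort(self, rng):
        vol = rng.normal(0, 1, (10, 10, 10))
        vol[rng.random(vol.shape) < 0.3] = 0.0
        pos, _ = select_extreme_voxels(vol, 0.05)
        flat = vol.ravel()
        cand = np.flatnonzero(flat > 0)
        k = int(np.ceil(0.05 * len(cand)))
        expected = set(cand[np.argsort(-flat[cand], kind="stable")][:k])
        got = {np.ravel_multi_index(tuple(v), vol.shape) for v in pos}
        assert got == expected

    def test_all_zero_map_gives_empty_sets(self):
        pos, neg = select_extreme_voxels(np.zeros((5, 5, 5)), 0.05)
        assert len(pos) == 0 and len(neg) == 0

    def test_invalid_fraction_rejected(self):
        with pytest.raises(InputError):
            select_extreme_voxels(np.ones((3, 3, 3)), 1.5)


class TestConnectedRois:
    def test_separated_clusters_form_two_rois(self):
        pos = np.array([[1, 1, 1], [1, 1, 2], [6, 6, 6]])
        rois = connected_rois(pos, np.empty((0, 3), dtype=int), (8, 8, 8))
        assert len(rois) == 2

    def test_corner_touching_voxels_join_under_26_connectivity(self):
        pos = np.array([[1, 1, 1], [2, 2, 2]])  # touch only diagonally
        rois = connected_rois(pos, np.empty((0, 3), dtype=int), (5, 5, 5))
        assert len(rois) == 1 and len(rois[0].voxels) == 2

    def test_signs_never_merge(self):
        pos = np.array([[1, 1, 1]])
        neg = np.array([[1, 1, 2]])  # face-adjacent but opposite sign
        rois = connected_rois(pos, neg, (4, 4, 4))
        assert len(rois) == 2
        assert sorted(r.sign for r in rois) == [-1, 1]


def _roi_fixture(rng, n_subjects=3):
    """Small synthetic per-subject ROI sets over the three contrasts."""
    per_subject = {}
    for i in range(n_subjects):
        maps = {
            c: np.zeros((8, 8, 4)) for c in CONTRASTS
        }
        for c in CONTRASTS:
            maps[c][2 + i % 3, 2, 1] = 5.0
            maps[c][6, 6, 2] = -4.0
        per_subject[f"s{i}"] = (
            maps,
            extract_subject_rois(maps, f"s{i}", fraction=0.5),
        )
    return per_subject


class TestDictionary:
    def test_single_subject_single_roi_per_contrast(self):
        maps = {c: np.zeros((6, 6, 3)) for c in CONTRASTS}
        for c in CONTRASTS:
            maps[c][1, 1, 1] = 1.0
        rois = extract_subject_rois(maps, "s0", fraction=0.5)
        d = build_dictionary({"s0": rois}, (6, 6, 3))
        assert d.size == 3
        assert all(n == 1 for n in d.per_contrast.values())

    def test_deterministic_order(self, rng):
        per = {sid: rois for sid, (_, rois) in _roi_fixture(rng).items()}
        d1 = build_dictionary(per, (8, 8, 4))
        d2 = build_dictionary(per, (8, 8, 4))
        for a, b in zip(d1.rois, d2.rois):
            assert a.contrast == b.contrast and a.source_subject == b.source_subject
            assert np.array_equal(a.voxels, b.voxels)

    def test_grouped_by_contrast_and_counts_sum(self, rng):
        per = {sid: rois for sid, (_, rois) in _roi_fixture(rng).items()}
        d = build_dictionary(per, (8, 8, 4))
        assert sum(d.per_contrast.values()) == d.size
        contrasts_in_order = [r.contrast for r in d.rois]
        expected = [
            c for c in CONTRASTS for _ in range(d.per_contrast[c])
        ]
        assert contrasts_in_order == expected


class TestVectorize:
    def test_mean_of_roi_voxels(self):
        maps = {c: np.zeros((6, 6, 3)) for c in CONTRASTS}
        maps[CONTRASTS[0]][1, 1, 1] = 1.0
        maps[CONTRASTS[0]][1, 1, 2] = 3.0
        rois = extract_subject_rois(maps, "s0", fraction=0.99)
        d = build_dictionary({"s0": rois}, (6, 6, 3))
        row = vectorize(maps, d)
        assert row[0] == pytest.approx(2.0)

    def test_all_zero_subject_gives_zero_row(self, rng):
        per = {sid: rois for sid, (_, rois) in _roi_fixture(rng).items()}
        d = build_dictionary(per, (8, 8, 4))
        zeros = {c: np.zeros((8, 8, 4)) for c in CONTRASTS}
        assert (vectorize(zeros, d) == 0).all()

    def test_source_subject_reproduces_selected_mean(self, rng):
        fixture = _roi_fixture(rng)
        per = {sid: rois for sid, (_, rois) in fixture.items()}
        d = build_dictionary(per, (8, 8, 4))
        for sid, (maps, _) in fixture.items():
            row = vectorize(maps, d)
            for j, roi in enumerate(d.rois):
                if roi.source_subject == sid:
                    expected = maps[roi.contrast][tuple(roi.voxels.T)].mean()
                    assert row[j] == pytest.approx(expected)

    def test_grid_mismatch_rejected(self, rng):
        per = {sid: rois for sid, (_, rois) in _roi_fixture(rng).items()}
        d = build_dictionary(per, (8, 8, 4))
        bad = {c: np.zeros((5, 5, 5)) for c in CONTRASTS}
        with pytest.raises(InputError):
            vectorize(bad, d)


def _matrix(values, contrast="speech_vs_silence"):
    values = np.asarray(values, dtype=float)
    cols = [
        ColumnInfo(kind="roi", members=[j], contrast=contrast, name=f"roi{j}")
        for j in range(values.shape[1])
    ]
    return FeatureMatrix(values, cols, [f"s{i}" for i in range(values.shape[0])])


class TestMergeRois:
    def test_duplicate_columns_collapse_to_distinct_ones(self, rng):
        a = rng.normal(0, 1, 6)
        b = rng.normal(10, 1, 6)
        c = rng.normal(-10, 1, 6)
        m = _matrix(np.column_stack([a, a, b, b, c]))
        merged = merge_rois(m)
        assert merged.values.shape[1] == 3
        assert np.allclose(merged.values, np.column_stack([a, b, c]))
        assert merged.columns[0].members == [0, 1]

    def test_distant_columns_survive_unmerged(self, rng):
        cols = [rng.normal(20 * j, 1, 8) for j in range(5)]
        merged = merge_rois(_matrix(np.column_stack(cols)))
        assert merged.values.shape[1] == 5

    def test_merging_is_idempotent(self, rng):
        a = rng.normal(0, 1, 6)
        b = rng.normal(8, 1, 6)
        m = _matrix(np.column_stack([a, a, b, a, b]))
        once = merge_rois(m)
        twice = merge_rois(once)
        assert np.allclose(once.values, twice.values)
        assert [c.members for c in once.columns] == [c.members for c in twice.columns]

    def test_single_column_passthrough(self, rng):
        m = _matrix(rng.normal(0, 1, (4, 1)))
        assert merge_rois(m) is m


class TestSedation:
    @pytest.mark.parametrize(
        "method, expected", [(1, (1, 0, 0)), (2, (0, 1, 0)), (3, (0, 0, 1))]
    )
    def test_one_hot_rows(self, method, expected):
        assert tuple(encode_sedation(method)) == expected
        assert encode_sedation(method).sum() == 1.0

    def test_unknown_method_rejected(self):
        with pytest.raises(InputError):
            encode_sedation(4)


class TestCfsMerit:
    def test_singleton_merit_is_class_correlation(self):
        y = np.array([1.0, 1.0, -1.0, -1.0])
        X = np.column_stack([y, [1.0, -1.0, 1.0, -1.0]])
        assert cfs_merit([0], y, X) == pytest.approx(1.0)
        assert cfs_merit([1], y, X) == pytest.approx(0.0)

    def test_pairs_follow_closed_form(self):
        y = np.array([1.0, 1.0, -1.0, -1.0])
        x_orth = np.array([1.0, -1.0, 1.0, -1.0])  # r_cf = 0, r_ff = 0 vs y-copy
        X = np.column_stack([y, x_orth, y])
        # duplicate informative features: rcf = 1 each, rff = 1 -> 2/sqrt(4)
        assert cfs_merit([0, 2], y, X) == pytest.approx(1.0)
        # informative + orthogonal noise: (1+0)/sqrt(2)
        assert cfs_merit([0, 1], y, X) == pytest.approx(1 / np.sqrt(2))

    def test_zero_variance_feature_counts_zero_correlation(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        X = np.column_stack([np.ones(4), y])
        assert cfs_merit([0], y, X) == pytest.approx(0.0)

    def test_empty_subset_rejected(self):
        with pytest.raises(InputError):
            cfs_merit([], np.array([1.0, -1.0]), np.zeros((2, 1)))


class TestCfsSearch:
    def test_matches_exhaustive_search_on_four_features(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            y = np.where(r.random(16) < 0.5, 1.0, -1.0)
            X = np.column_stack(
                [y + r.normal(0, s, 16) for s in (0.5, 1.0, 2.0)]
                + [r.normal(0, 1, 16)]
            )
            scorer = CfsScorer(X, y)
            best = max(
                (
                    frozenset(s)
                    for k in range(1, 5)
                    for s in itertools.combinations(range(4), k)
                ),
                key=scorer.merit,
            )
            got = cfs_search(X, y)
            assert scorer.merit(got) == pytest.approx(scorer.merit(best))

    def test_planted_informative_feature_selected(self):
        for seed in range(10):
            r = np.random.default_rng(seed)
            y = np.where(r.random(20) < 0.5, 1.0, -1.0)
            X = np.column_stack([y] + [r.normal(0, 1, 20) for _ in range(8)])
            selected = cfs_search(X, y)
            assert 0 in selected

    def test_selected_merit_beats_every_singleton(self, rng):
        y = np.where(rng.random(18) < 0.5, 1.0, -1.0)
        X = rng.normal(0, 1, (18, 10))
        scorer = CfsScorer(X, y)
        selected = cfs_search(X, y, scorer=scorer)
        best_single = max(scorer.merit([f]) for f in range(10))
        assert scorer.merit(selected) >= best_single - 1e-12

    def test_terminates_on_identical_features(self, rng):
        col = rng.normal(0, 1, 12)
        X = np.tile(col[:, None], (1, 6))
        y = np.where(rng.random(12) < 0.5, 1.0, -1.0)
        selected = cfs_search(X, y)
        assert len(selected) <= 1


class TestFmriModel:
    def test_separable_training_is_perfect_and_symmetric(self, rng):
        y = np.array([True] * 6 + [False] * 6)
        X = np.column_stack(
            [np.where(y, 1.0, -1.0) + rng.normal(0, 0.1, 12), rng.normal(0, 1, 12)]
        )
        m = train_fmri(X, y)
        scores = m.score_many(X)
        assert ((scores >= 0) == y).all()
        m_flipped = train_fmri(X, ~y)
        assert np.allclose(m_flipped.score_many(X), -scores, atol=1e-6)

    def test_boundary_score_classifies_hi(self):
        y = np.array([True, True, False, False])
        X = np.array([[1.0], [2.0], [-1.0], [-2.0]])
        m = train_fmri(X, y)
        assert m.classify(0.0) == "HI"  # inclusive >=
        assert m.classify(-1e-9) == "NH"

    def test_wrong_width_row_rejected(self):
        y = np.array([True, True, False, False])
        X = np.array([[1.0, 0.0], [2.0, 1.0], [-1.0, 0.0], [-2.0, 1.0]])
        m = train_fmri(X, y)
        with pytest.raises(InputError):
            m.score(np.zeros(5))


class TestImportance:
    def test_sums_absolute_weights_over_selecting_folds(self):
        # feature 7: selected in folds 0 and 1 with weights 0.5 and -0.5
        selections = [[7], [7], [3]]
        weights = [np.array([0.5]), np.array([-0.5]), np.array([0.9])]
        I = feature_importance(selections, weights, 10)
        assert I[7] == pytest.approx(1.0)
        assert I[3] == pytest.approx(0.9)
        assert I[0] == 0.0

    def test_planted_strong_feature_ranks_first(self, rng):
        n_feat = 12
        selections, weights = [], []
        for fold in range(6):
            sel = [0, int(rng.integers(1, n_feat))]
            w = np.array([2.0 + rng.normal(0, 0.1), rng.normal(0, 0.3)])
            selections.append(sel)
            weights.append(w)
        I = feature_importance(selections, weights, n_feat)
        assert int(np.argmax(I)) == 0


class TestEndToEndMatrix:
    def test_dataset_dimensions_consistent(self):
        spec = CohortSpec(n_hi=2, n_nh=2, grid_shape=(40, 40, 20), seed=4)
        subjects = generate_cohort(spec)
        per = {
            s.subject_id: extract_subject_rois(s.contrasts, s.subject_id)
            for s in subjects
        }
        d = build_dictionary(per, spec.grid_shape)
        raw = build_feature_matrix(subjects, d)
        assert raw.values.shape == (4, d.size)
        merged = merge_rois(raw)
        assert merged.values.shape[1] <= d.size
        from hearmri.bow import append_sedation

        full = append_sedation(merged, [s.sedation for s in subjects])
        assert full.values.shape[1] == merged.values.shape[1] + 3
        assert not np.isnan(full.values).any()
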