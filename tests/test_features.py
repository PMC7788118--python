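"""Window features, feature selection, voxel classifiers, view fusion."""

import numpy as np
import pandas as pd
import pytest

from petseg import (BinaryMask, ProbabilityMap, SuvVolume, fuse_views,
                    select_features, train_voxel_classifier)
from petseg.errors import AlignmentError, InputError, StateError
from petseg.features import (FEATURE_NAMES, N_LEVELS, SUV_RANGE,
                             extract_window_features, quantize)


def _vol(values, spacing=(4, 4, 4)):
    return SuvVolume(np.asarray(values, dtype=np.float32), spacing)


class TestWindowFeatures:
    def test_window_mean_matches_hand_arithmetic(self):
        # hand-written 3x3 axial patch around voxel (1, 1, 1)
        vals = np.zeros((3, 3, 3), dtype=np.float32)
        vals[1] = np.array([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        df = extract_window_features(_vol(vals), "axial", window=3,
                                     voxels=[(1, 1, 1)])
        assert df["mean"].iloc[0] == pytest.approx(5.0)
        assert df["median"].iloc[0] == pytest.approx(5.0)
        assert df["min"].iloc[0] == 1.0 and df["max"].iloc[0] == 9.0
        assert df["energy"].iloc[0] == pytest.approx(
            sum(v * v for v in range(1, 10)) / 9)

    def test_constant_window_degenerate_texture(self):
        df = extract_window_features(_vol(np.full((5, 5, 5), 3.0)), "axial",
                                     window=3, voxels=[(2, 2, 2)])
        assert df["sd"].iloc[0] == 0.0
        assert df["entropy"].iloc[0] == 0.0
        assert df["glcm_contrast"].iloc[0] == 0.0
        assert df["skewness"].iloc[0] == 0.0

    def test_first_order_permutation_invariance(self):
        rng = np.random.default_rng(0)
        patch = rng.uniform(0, 10, 9)
        v1 = np.zeros((3, 3, 3), dtype=np.float32)
        v2 = np.zeros((3, 3, 3), dtype=np.float32)
        v1[1] = patch.reshape(3, 3)
        v2[1] = rng.permutation(patch).reshape(3, 3)
        d1 = extract_window_features(_vol(v1), "axial", 3, voxels=[(1, 1, 1)])
        d2 = extract_window_features(_vol(v2), "axial", 3, voxels=[(1, 1, 1)])
        for col in ("mean", "sd", "min", "max", "median", "skewness",
                    "kurtosis", "energy", "entropy"):
            assert d1[col].iloc[0] == pytest.approx(d2[col].iloc[0], abs=1e-5)

    def test_even_window_rejected(self):
        with pytest.raises(InputError):
            extract_window_features(_vol(np.zeros((4, 4, 4))), "axial", 4)

    def test_views_differ_on_anisotropic_structure(self):
        # a bright axial plane: axial windows are constant inside the plane,
        # sagittal/coronal windows straddle it
        vals = np.ones((7, 7, 7), dtype=np.float32)
        vals[3] = 10.0
        ax = extract_window_features(_vol(vals), "axial", 3, voxels=[(3, 3, 3)])
        sg = extract_window_features(_vol(vals), "sagittal", 3, voxels=[(3, 3, 3)])
        assert ax["sd"].iloc[0] == pytest.approx(0.0)
        assert sg["sd"].iloc[0] > 0

    def test_cooccurrence_matches_skimage_oracle(self):
        skimage_feature = pytest.importorskip("skimage.feature")
        rng = np.random.default_rng(7)
        vals = rng.uniform(0, 12, (1, 7, 7)).astype(np.float32)
        df = extract_window_features(_vol(vals), "axial", 7, voxels=[(0, 3, 3)])
        q = quantize(vals[0])
        glcm = skimage_feature.graycomatrix(
            q.astype(np.uint8), distances=[1],
            angles=[0, np.pi / 2], levels=N_LEVELS, symmetric=True,
            normed=False).sum(axis=3, keepdims=True).astype(float)
        glcm /= glcm.sum()
        for mine, theirs in (("glcm_contrast", "contrast"),
                             ("glcm_dissimilarity", "dissimilarity"),
                             ("glcm_homogeneity", "homogeneity"),
                             ("glcm_correlation", "correlation")):
            ref = skimage_feature.graycoprops(glcm, theirs)[0, 0]
            assert df[mine].iloc[0] == pytest.approx(ref, abs=1e-5), mine


def _separable_table(rng, n=300, extra_noise_cols=4, duplicate=False):
    informative = np.concatenate([rng.normal(0, 1, n // 2),
                                  rng.normal(4, 1, n // 2)])
    cols = {"informative": informative}
    for c in range(extra_noise_cols):
        cols[f"noise{c}"] = rng.normal(0, 1, n)
    if duplicate:
        cols["noise_dup"] = cols["noise0"].copy()
    table = pd.DataFrame(cols)
    table["label"] = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
    return table


class TestFeatureSelection:
    def test_informative_feature_ranked_first_across_seeds(self):
        rng = np.random.default_rng(1)
        hits = 0
        for seed in range(20):
            table = _separable_table(rng)
            feats = [c for c in table.columns if c != "label"]
            top = select_features(table, 1, seed=seed, features=feats)
            hits += top[0] == "informative"
        assert hits >= 19

    def test_k_equals_all_is_identity_as_set(self):
        table = _separable_table(np.random.default_rng(2))
        feats = [c for c in table.columns if c != "label"]
        assert set(select_features(table, len(feats), seed=0, features=feats)) \
            == set(feats)

    def test_duplicated_column_stays_behind_informative(self):
        table = _separable_table(np.random.default_rng(3), duplicate=True)
        feats = [c for c in table.columns if c != "label"]
        ranked = select_features(table, len(feats), seed=0, features=feats)
        assert ranked[0] == "informative"

    def test_single_class_rejected(self):
        table = _separable_table(np.random.default_rng(4))
        table["label"] = 1
        with pytest.raises(InputError):
            select_features(table, 2, features=[c for c in table.columns
                                                if c != "label"])


class TestVoxelClassifier:
    def test_separable_training_accuracy(self):
        table = _separable_table(np.random.default_rng(5))
        clf = train_voxel_classifier(table, ["informative"], seed=0)
        acc = clf.score(table[["informative"]].to_numpy(), table["label"])
        assert acc == 1.0

    def test_deterministic_given_seed(self):
        table = _separable_table(np.random.default_rng(6))
        feats = ["informative", "noise0"]
        p1 = train_voxel_classifier(table, feats, seed=3).predict_proba(
            table[feats].to_numpy())
        p2 = train_voxel_classifier(table, feats, seed=3).predict_proba(
            table[feats].to_numpy())
        np.testing.assert_array_equal(p1, p2)

    def test_label_shuffle_gives_chance_accuracy(self):
        rng = np.random.default_rng(7)
        table = _separable_table(rng, n=600)
        table["label"] = rng.permutation(table["label"].to_numpy())
        train, test = table.iloc[:400], table.iloc[400:]
        clf = train_voxel_classifier(train, ["informative"], seed=0)
        acc = clf.score(test[["informative"]].to_numpy(), test["label"])
        assert 0.4 <= acc <= 0.6


class TestFusion:
    def _maps(self, triples):
        arr = np.asarray(triples, dtype=np.float64).T.reshape(3, 1, 1, -1)
        return [ProbabilityMap(a, (4, 4, 4)) for a in arr]

    def test_summed_threshold_boundary(self):
        pa, ps, pc = self._maps([(0.6, 0.6, 0.6), (1.0, 1.0, 1.0),
                                 (0.61, 0.61, 0.61)])
        res = fuse_views(pa, ps, pc, component_policy=False)
        # 1.8 excluded (strict >), 3.0 included, 1.83 included
        np.testing.assert_array_equal(res.mask.values.ravel(),
                                      [False, True, True])

    def test_sum_conservation_against_elementwise_oracle(self):
        rng = np.random.default_rng(8)
        maps = [ProbabilityMap(rng.random((4, 4, 4)).astype(np.float32),
                               (4, 4, 4)) for _ in range(3)]
        res = fuse_views(*maps, threshold=1.5, component_policy=False)
        oracle = (maps[0].values + maps[1].values + maps[2].values) > 1.5
        np.testing.assert_array_equal(res.mask.values, oracle)

    def test_threshold_monotone_nesting(self):
        rng = np.random.default_rng(9)
        maps = [ProbabilityMap(rng.random((5, 5, 5)).astype(np.float32),
                               (4, 4, 4)) for _ in range(3)]
        prev = None
        for thr in (1.2, 1.5, 1.8, 2.1):
            m = fuse_views(*maps, threshold=thr, component_policy=False).mask.values
            if prev is not None:
                assert np.all(m <= prev)
            prev = m

    def test_shape_mismatch(self):
        a = ProbabilityMap(np.zeros((3, 3, 3), np.float32), (4, 4, 4))
        b = ProbabilityMap(np.zeros((3, 3, 4), np.float32), (4, 4, 4))
        with pytest.raises(AlignmentError):
            fuse_views(a, a, b)

    def test_empty_fused_mask_flagged_missed(self):
        a = ProbabilityMap(np.full((3, 3, 3), 0.1, np.float32), (4, 4, 4))
        res = fuse_views(a, a, a)
        assert res.missed and res.matv_ml == 0.0


def test_untrained_classifier_rejected():
    from sklearn.ensemble import RandomForestClassifier
    from petseg import predict_view_probability
    vol = _vol(np.zeros((4, 4, 4)))
    with pytest.raises(StateError):
        predict_view_probability(vol, RandomForestClassifier(), "axial")
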