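import numpy as np
import pytest

from radcorr.features import (
    FEATURES,
    VOLUME_FEATURE,
    apply_volume_normalization,
    build_glcm,
    build_glrlm,
    build_glszm,
    build_ngtdm,
    extract_all,
    features_glcm,
    features_glrlm,
    features_glszm,
    features_intensity,
    features_ngtdm,
    vn_features,
)
from radcorr.features.values import NGTDM_EPS

from conftest import make_qroi, make_volume, random_roi
import oracles


class TestRegistry:
    def test_family_counts(self):
        by_family = {}
        for f in FEATURES:
            by_family[f.family] = by_family.get(f.family, 0) + 1
        assert by_family == {"GLCM": 8, "GLRLM": 13, "IS": 3, "NGTDM": 5, "GLSZM": 13}
        assert len(FEATURES) == 42

    def test_volume_normalized_entries(self):
        vn = {f.name: f.vn_type for f in vn_features()}
        assert vn == {
            "GLRLM_GLN": 1,
            "GLRLM_RLN": 1,
            "GLSZM_GLN": 1,
            "GLSZM_ZSN": 1,
            "NGTDM_Busyness": 3,
            "NGTDM_Coarseness": 4,
            "NGTDM_Strength": 2,
        }

    def test_names_unique(self):
        names = [f.name for f in FEATURES]
        assert len(set(names)) == 42


class TestGlcmFeatures:
    def test_line_112_hand_values(self):
        q = make_qroi(np.array([1, 1, 2]).reshape(1, 1, 3))
        f = features_glcm(build_glcm(q))
        assert f["GLCM_Energy"] == pytest.approx(0.375)
        assert f["GLCM_Entropy"] == pytest.approx(1.5)
        assert f["GLCM_Contrast"] == pytest.approx(0.5)
        assert f["GLCM_Homogeneity"] == pytest.approx(0.75)

    def test_constant_roi_closed_forms(self):
        q = make_qroi(np.ones((3, 3, 3), dtype=int))
        f = features_glcm(build_glcm(q))
        assert f["GLCM_Energy"] == 1.0
        assert f["GLCM_Entropy"] == 0.0
        assert f["GLCM_Contrast"] == 0.0
        assert f["GLCM_Dissimilarity"] == 0.0
        assert f["GLCM_Homogeneity"] == 1.0
        assert np.isnan(f["GLCM_Correlation"])  # zero marginal variance

    def test_bounds(self, rng):
        for _ in range(10):
            q = random_roi(rng)
            f = features_glcm(build_glcm(q))
            assert f["GLCM_Contrast"] >= 0
            assert 0 < f["GLCM_Energy"] <= 1


class TestIntensityFeatures:
    def test_hand_moments(self):
        f = features_intensity(np.array([1.0, 2.0, 3.0]))
        assert f["IS_Variance"] == pytest.approx(2.0 / 3.0)
        assert f["IS_Skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_sample_zero_skew(self, rng):
        x = rng.normal(size=500)
        f = features_intensity(np.concatenate([x, -x]))
        assert f["IS_Skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_kurtosis_three(self, rng):
        f = features_intensity(rng.standard_normal(100_000))
        assert f["IS_Kurtosis"] == pytest.approx(3.0, abs=0.1)

    def test_flat_flags_undefined(self):
        f = features_intensity(np.full(10, 4.2))
        assert f["IS_Variance"] == 0.0
        assert np.isnan(f["IS_Skewness"]) and np.isnan(f["IS_Kurtosis"])


class TestNgtdmFeatures:
    def test_constant_roi_sentinels(self):
        q = make_qroi(np.ones((3, 3, 3), dtype=int))
        f = features_ngtdm(build_ngtdm(q))
        assert f["NGTDM_Contrast"] == 0.0
        assert f["NGTDM_Coarseness"] == pytest.approx(1.0 / NGTDM_EPS)

    def test_nonnegative_bounds(self, rng):
        for _ in range(10):
            q = random_roi(rng)
            f = features_ngtdm(build_ngtdm(q))
            for key in ("NGTDM_Busyness", "NGTDM_Complexity", "NGTDM_Strength"):
                assert np.isnan(f[key]) or f[key] >= 0


class TestVolumeNormalization:
    def test_type1_type2_arithmetic(self):
        feats = {f.name: 10.0 for f in FEATURES}
        out = apply_volume_normalization(feats, None, volume=5.0)
        assert out["GLRLM_GLN"] == 2.0
        assert out["GLRLM_RLN"] == 2.0
        assert out["GLSZM_GLN"] == 2.0
        assert out["GLSZM_ZSN"] == 2.0
        assert out["NGTDM_Strength"] == 50.0
        assert out["GLRLM_SRE"] == 10.0  # untouched

    def test_type3_type4_match_oracle(self, rng):
        q = random_roi(rng, max_dim=5)
        parts = build_ngtdm(q)
        feats = features_ngtdm(parts)
        out = apply_volume_normalization(dict(feats), parts, volume=float(q.mask.n_voxels))
        oall = oracles.oracle_all_features(
            q.levels, q.mask.inside, q.n_levels, q.levels[q.mask.inside].astype(float)
        )
        assert out["NGTDM_Busyness"] == pytest.approx(oall["NGTDM_Busyness"], rel=1e-10)
        assert out["NGTDM_Coarseness"] == pytest.approx(oall["NGTDM_Coarseness"], rel=1e-10)

    def test_rejects_nonpositive_volume(self):
        with pytest.raises(ValueError):
            apply_volume_normalization({}, None, volume=0.0)

    def test_tiling_reduces_volume_sensitivity(self, rng):
        # Duplicating a texture into a gap-separated 2x tiling doubles raw GLN
        # but leaves volume-normalized GLN unchanged.
        for _ in range(20):
            q = random_roi(rng, max_dim=4)
            m1 = build_glrlm(q)
            f1 = features_glrlm(m1, q.mask.n_voxels)
            shape = q.levels.shape
            tiled_levels = np.zeros((shape[0], shape[1], 2 * shape[2] + 1), dtype=q.levels.dtype)
            tiled_mask = np.zeros_like(tiled_levels, dtype=bool)
            tiled_levels[:, :, : shape[2]] = q.levels
            tiled_levels[:, :, shape[2] + 1 :] = q.levels
            tiled_mask[:, :, : shape[2]] = q.mask.inside
            tiled_mask[:, :, shape[2] + 1 :] = q.mask.inside
            q2 = make_qroi(tiled_levels, tiled_mask, q.n_levels)
            f2 = features_glrlm(build_glrlm(q2), q2.mask.n_voxels)
            raw_change = abs(f2["GLRLM_GLN"] - f1["GLRLM_GLN"]) / f1["GLRLM_GLN"]
            vn1 = f1["GLRLM_GLN"] / q.mask.n_voxels
            vn2 = f2["GLRLM_GLN"] / q2.mask.n_voxels
            vn_change = abs(vn2 - vn1) / vn1
            assert vn_change < raw_change

    def test_tiling_invariance_type3_type4(self, rng):
        # With a gap separator each copy sees the same surroundings, so the
        # normalized busyness/coarseness are exactly tiling-invariant.
        q = random_roi(rng, max_dim=4)
        shape = q.levels.shape
        tiled_levels = np.zeros((shape[0], shape[1], 2 * shape[2] + 1), dtype=q.levels.dtype)
        tiled_mask = np.zeros_like(tiled_levels, dtype=bool)
        tiled_levels[:, :, : shape[2]] = q.levels
        tiled_levels[:, :, shape[2] + 1 :] = q.levels
        tiled_mask[:, :, : shape[2]] = q.mask.inside
        tiled_mask[:, :, shape[2] + 1 :] = q.mask.inside
        q2 = make_qroi(tiled_levels, tiled_mask, q.n_levels)
        for qq, scale in ((q, 1), (q2, 2)):
            parts = build_ngtdm(qq)
            f = apply_volume_normalization(
                features_ngtdm(parts), parts, float(qq.mask.n_voxels)
            )
            if scale == 1:
                base = f
            else:
                assert f["NGTDM_Busyness"] == pytest.approx(base["NGTDM_Busyness"], rel=1e-10, nan_ok=True)
                assert f["NGTDM_Coarseness"] == pytest.approx(base["NGTDM_Coarseness"], rel=1e-10)


class TestExtractAll:
    def test_forty_three_named_outputs(self, rng):
        q = random_roi(rng)
        vol = make_volume(q.levels.astype(float))
        out = extract_all(q, vol)
        assert len(out) == 43
        assert VOLUME_FEATURE in out
        assert set(f.name for f in FEATURES) <= set(out)

    def test_volume_is_voxel_count_times_voxel_volume(self, rng):
        q = random_roi(rng)
        vol = make_volume(q.levels.astype(float), spacing=(0.5, 0.5, 2.0))
        out = extract_all(q, vol)
        assert out[VOLUME_FEATURE] == pytest.approx(q.mask.n_voxels * 0.5)

    def test_matches_full_oracle(self, rng):
        for _ in range(10):
            q = random_roi(rng)
            raw = q.levels.astype(float) * 1.7 - 3.0
            out = extract_all(q, make_volume(raw))
            expected = oracles.oracle_all_features(
                q.levels, q.mask.inside, q.n_levels, raw[q.mask.inside]
            )
            for name, val in expected.items():
                got = out[name]
                if np.isnan(val):
                    assert np.isnan(got), name
                else:
                    assert got == pytest.approx(val, rel=1e-10), name

    def test_single_voxel_roi_flags_glcm_undefined(self):
        q = make_qroi(np.array([1]).reshape(1, 1, 1))
        out = extract_all(q, make_volume(np.array([5.0]).reshape(1, 1, 1)))
        assert np.isnan(out["GLCM_Energy"])
        assert out["GLRLM_RP"] == 1.0  # 13 unit runs / (1 voxel * 13)

    def test_level_shift_leaves_count_features_unchanged(self, rng):
        # A level relabeling g -> g + c preserves run/zone geometry, so the
        # count-based features do not move.
        q = random_roi(rng, max_levels=3)
        shifted = make_qroi(
            np.where(q.mask.inside, q.levels + 2, 0), q.mask.inside, q.n_levels + 2
        )
        raw = q.levels.astype(float)
        a = extract_all(q, make_volume(raw), volume_normalize=False)
        b = extract_all(shifted, make_volume(raw), volume_normalize=False)
        for name in ("GLRLM_RP", "GLSZM_ZP", "GLRLM_SRE", "GLRLM_LRE",
                      "GLRLM_GLN", "GLRLM_RLN", "GLSZM_GLN", "GLSZM_ZSN"):
            assert a[name] == pytest.approx(b[name], rel=1e-12), name
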