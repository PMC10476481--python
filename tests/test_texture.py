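"""Texture features: quantization, GLCM, run-length, first-order, extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemisym.grids import BinaryMask, VoxelGrid
from hemisym.texture import (
    DIRECTIONS_13,
    GLCM,
    GLCMSpec,
    QuantizedVolume,
    extract_subject_features,
    feature_name,
    first_order_features,
    glcm,
    glcm_features,
    parse_feature_name,
    quantize,
    rlm,
    rlm_features,
)
from tests._oracles import glcm_oracle, random_masked_volume, rlm_oracle, runs_to_matrix


def strip(levels, Z=2):
    arr = np.full((len(levels), 1, 1), -1, dtype=np.int32)
    arr[:, 0, 0] = levels
    return QuantizedVolume(arr, Z, BinaryMask(arr >= 0))


class TestQuantize:
    def test_bin_edges(self):
        data = np.zeros((3, 1, 1))
        data[:, 0, 0] = [0.0, 0.5, 1.0]
        q = quantize(VoxelGrid(data), BinaryMask(np.ones((3, 1, 1), bool)), 2)
        assert list(q.data[:, 0, 0]) == [0, 1, 1]

    def test_constant_region_level_zero(self):
        q = quantize(VoxelGrid(np.full((4, 4, 4), 2.0)), BinaryMask(np.ones((4, 4, 4), bool)), 8)
        assert (q.data == 0).all()

    def test_scale_invariance(self, rng):
        data = rng.random((5, 5, 5))
        mask = BinaryMask(np.ones((5, 5, 5), bool))
        a = quantize(VoxelGrid(data), mask, 8)
        b = quantize(VoxelGrid(2 * data), mask, 8)
        assert np.array_equal(a.data, b.data)

    def test_invalid_inputs(self, rng):
        v = VoxelGrid(rng.random((4, 4, 4)))
        with pytest.raises(ValueError):
            quantize(v, BinaryMask(np.ones((4, 4, 4), bool)), 1)
        with pytest.raises(ValueError):
            quantize(v, BinaryMask(np.zeros((4, 4, 4), bool)), 8)


class TestGLCM:
    def test_hand_counted_strip(self):
        g = glcm(strip([0, 0, 1, 1]), GLCMSpec(2, directions=((1, 0, 0),)))
        assert np.allclose(g.P, np.array([[2, 1], [1, 2]]) / 6)

    def test_constant_strip_single_entry(self):
        g = glcm(strip([0, 0, 0, 0]), GLCMSpec(2, directions=((1, 0, 0),)))
        assert g.P[0, 0] == 1.0 and g.P.sum() == 1.0

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(10):
            arr, mask = random_masked_volume(rng)
            q = QuantizedVolume(arr, 4, BinaryMask(mask))
            P = glcm(q, GLCMSpec(4)).P
            Po = glcm_oracle(arr, 4, 1, DIRECTIONS_13, True)
            assert np.abs(P - Po).max() < 1e-12

    def test_normalized_and_symmetric(self, rng):
        arr, mask = random_masked_volume(rng, Z=6, shape=(8, 8, 8))
        g = glcm(QuantizedVolume(arr, 6, BinaryMask(mask)), GLCMSpec(6))
        assert abs(g.P.sum() - 1.0) < 1e-12
        assert np.array_equal(g.P, g.P.T)

    def test_empty_pairs_raise(self):
        arr = np.full((3, 3, 3), -1, np.int32)
        arr[0, 0, 0] = 0
        q = QuantizedVolume(arr, 2, BinaryMask(arr >= 0))
        with pytest.raises(ValueError):
            glcm(q, GLCMSpec(2))


class TestGLCMFeatures:
    def test_degenerate_single_entry(self):
        f = glcm_features(GLCM(np.array([[1.0]]), GLCMSpec(2), 1))
        assert f == {"energy": 1.0, "contrast": 0.0, "idm": 1.0, "entropy": 0.0, "correlation": 0.0}

    def test_uniform_2x2(self):
        f = glcm_features(GLCM(np.full((2, 2), 0.25), GLCMSpec(2), 4))
        assert f["energy"] == pytest.approx(0.25)
        assert f["entropy"] == pytest.approx(2.0)

    def test_diagonal_perfect_correlation(self):
        f = glcm_features(GLCM(np.array([[0.5, 0.0], [0.0, 0.5]]), GLCMSpec(2), 2))
        assert f["contrast"] == 0.0
        assert f["correlation"] == pytest.approx(1.0)

    def test_feature_ranges_on_random_glcms(self, rng):
        for _ in range(20):
            Z = int(rng.integers(2, 8))
            P = rng.random((Z, Z))
            P = (P + P.T) / 2
            P /= P.sum()
            f = glcm_features(GLCM(P, GLCMSpec(Z), 1))
            assert 0 < f["energy"] <= 1
            assert 0 < f["idm"] <= 1
            assert 0 <= f["entropy"] <= 2 * np.log2(Z)
            assert -1 - 1e-12 <= f["correlation"] <= 1 + 1e-12

    def test_contrast_invariant_under_gray_reversal(self, rng):
        arr, mask = random_masked_volume(rng, Z=5)
        q = QuantizedVolume(arr, 5, BinaryMask(mask))
        f = glcm_features(glcm(q, GLCMSpec(5)))
        rev = arr.copy()
        rev[mask] = 4 - rev[mask]
        fr = glcm_features(glcm(QuantizedVolume(rev, 5, BinaryMask(mask)), GLCMSpec(5)))
        for k in ("contrast", "energy", "entropy"):
            assert f[k] == pytest.approx(fr[k])


class TestRLM:
    def test_two_runs_strip(self):
        r = rlm(strip([0, 0, 1, 1, 1]), [(1, 0, 0)])
        assert r.n_runs == 2
        assert r.R[0, 1] == 1 and r.R[1, 2] == 1

    def test_alternating_strip_unit_runs(self):
        r = rlm(strip([0, 1, 0, 1]), [(1, 0, 0)])
        assert r.n_runs == 4
        assert r.R[:, 0].sum() == 4

    def test_mask_gap_terminates_run(self):
        arr = np.full((5, 1, 1), -1, np.int32)
        arr[:, 0, 0] = [0, 0, -1, 0, 0]
        q = QuantizedVolume(arr, 2, BinaryMask(arr >= 0))
        r = rlm(q, [(1, 0, 0)])
        assert r.n_runs == 2 and r.R[0, 1] == 2

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(10):
            arr, mask = random_masked_volume(rng)
            R = rlm(QuantizedVolume(arr, 4, BinaryMask(mask))).R
            Ro = runs_to_matrix(rlm_oracle(arr, DIRECTIONS_13), 4)
            assert R.shape == Ro.shape and np.array_equal(R, Ro)

    def test_voxel_count_identity(self, rng):
        arr, mask = random_masked_volume(rng, shape=(7, 7, 7))
        r = rlm(QuantizedVolume(arr, 4, BinaryMask(mask)))
        j = np.arange(1, r.R.shape[1] + 1)
        assert (r.R * j).sum() == mask.sum() * len(DIRECTIONS_13)


class TestRLMFeatures:
    def test_hand_computed_sre(self):
        f = rlm_features(rlm(strip([0, 0, 1, 1, 1]), [(1, 0, 0)]))
        assert f["sre"] == pytest.approx(13 / 72)

    def test_unit_runs_give_unit_emphases(self):
        f = rlm_features(rlm(strip([0, 1, 0, 1]), [(1, 0, 0)]))
        assert f["sre"] == 1.0 and f["lre"] == 1.0

    def test_lowest_level_runs_give_unit_lgre(self):
        f = rlm_features(rlm(strip([0, 0, -1, 0], Z=2), [(1, 0, 0)]))
        assert f["lgre"] == 1.0

    def test_empty_matrix_rejected(self):
        from hemisym.texture import RunLengthMatrix

        with pytest.raises(ValueError):
            rlm_features(RunLengthMatrix(np.zeros((2, 1), np.int64), 0, 2, ((1, 0, 0),)))


class TestFirstOrder:
    def test_constant_region(self):
        f = first_order_features(
            VoxelGrid(np.full((4, 4, 4), 3.0)), BinaryMask(np.ones((4, 4, 4), bool))
        )
        assert f["variance"] == 0.0 and f["energy"] == 1.0 and f["entropy"] == 0.0

    def test_two_values_one_bit(self):
        data = np.zeros((4, 1, 1))
        data[:, 0, 0] = [0.0, 0.0, 1.0, 1.0]
        f = first_order_features(VoxelGrid(data), BinaryMask(np.ones((4, 1, 1), bool)), bins=2)
        assert f["entropy"] == pytest.approx(1.0)

    def test_mean_and_population_variance(self):
        data = np.zeros((3, 1, 1))
        data[:, 0, 0] = [1.0, 2.0, 3.0]
        f = first_order_features(VoxelGrid(data), BinaryMask(np.ones((3, 1, 1), bool)))
        assert f["mean"] == pytest.approx(2.0)
        assert f["variance"] == pytest.approx(2 / 3)


class TestSubjectExtraction:
    def test_feature_count_and_finiteness(self, ad_subject):
        fv = extract_subject_features(ad_subject)
        assert len(fv.values) == 144
        assert all(np.isfinite(v) for v in fv.values.values())

    def test_mirror_symmetric_subject_left_equals_right(self, nc_subject):
        fv = extract_subject_features(nc_subject)
        for name, info in fv.meta.items():
            if info.hemisphere == "left":
                other = feature_name(info.structure, "right", info.family, info.feature)
                assert fv.values[name] == fv.values[other], name

    def test_volume_features_match_structure_volume(self, ad_subject):
        from hemisym.io_preprocess import structure_volume

        fv = extract_subject_features(ad_subject)
        for s in ("gm", "hc"):
            expected = structure_volume(ad_subject.labels.mask(s, "left"))
            assert fv.values[f"{s}_left_volume"] == pytest.approx(expected)

    @given(st.sampled_from(["gm", "wm", "csf", "hc"]),
           st.sampled_from(["left", "right"]),
           st.sampled_from([("volume", "volume"), ("glcm", "contrast"), ("rlm", "lrlge"),
                            ("firstorder", "mean")]))
    @settings(max_examples=20, deadline=None)
    def test_feature_name_round_trip(self, s, h, fam_feat):
        fam, feat = fam_feat
        info = parse_feature_name(feature_name(s, h, fam, feat))
        assert (info.structure, info.hemisphere, info.family, info.feature) == (s, h, fam, feat)
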