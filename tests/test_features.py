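"""Radiomic feature inventory, image bank, and analytic limit checks."""

import numpy as np
import pandas as pd
import pytest

from kinhet import DegenerateRoiError, InvalidParameterError
from kinhet.features import (
    FIRSTORDER_FEATURES,
    FeatureConfig,
    GLCM_22,
    GLCM_ALL,
    build_image_bank,
    discretize,
    extract_feature_vector,
    feature_inventory,
    firstorder_features,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    shape_features,
)


class TestInventory:
    def test_whole_tumor_counts(self):
        inv = feature_inventory(FeatureConfig.whole_tumor())
        assert inv == {
            "shape": 14,
            "first_order": 234,
            "glcm": 286,
            "gldm": 182,
            "glrlm": 208,
            "glszm": 208,
            "total": 1132,
        }

    def test_washout_counts(self):
        inv = feature_inventory(FeatureConfig.washout())
        assert inv["glcm"] == 312
        assert inv["total"] == 1158

    @pytest.mark.parametrize("glcm_set", [GLCM_22, GLCM_ALL])
    def test_closed_form_holds(self, glcm_set):
        inv = feature_inventory(FeatureConfig(glcm_features=glcm_set))
        n = len(glcm_set)
        assert inv["total"] == 14 + 13 * (18 + n + 14 + 16 + 16)

    def test_hypothetical_zero_glcm(self):
        inv = feature_inventory(FeatureConfig(glcm_features=()))
        assert inv["total"] == 14 + 13 * 64 == 846


class TestImageBank:
    def test_bank_has_13_image_types(self, rng):
        bank = build_image_bank(rng.random((12, 12, 12)))
        assert len(bank) == 13
        assert "original" in bank and "wavelet-HHH" in bank
        assert sum(k.startswith("log-sigma") for k in bank) == 4

    def test_constant_volume_zero_detail_bands(self):
        bank = build_image_bank(np.full((10, 10, 10), 5.0))
        for name, img in bank.items():
            if name.startswith("wavelet") and "H" in name:
                np.testing.assert_allclose(img, 0.0, atol=1e-10)

    def test_deterministic(self, rng):
        vol = rng.random((10, 10, 10))
        a = build_image_bank(vol)
        b = build_image_bank(vol)
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_anisotropic_input_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            build_image_bank(rng.random((8, 8, 8)), (1.0, 1.0, 2.0))


def _ball_mask(shape=(24, 24, 24), radius=9.0):
    c = (np.asarray(shape) - 1) / 2
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    d2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
    return d2 <= radius**2


class TestAnalyticLimits:
    def test_sphere_shape_descriptors(self):
        mask = _ball_mask()
        f = shape_features(mask, (1, 1, 1))
        # marching cubes on a voxelized ball overestimates area slightly
        assert f["Sphericity"] == pytest.approx(1.0, abs=0.1)
        assert f["Maximum3DDiameter"] == pytest.approx(18.0, rel=0.1)
        assert f["Elongation"] == pytest.approx(1.0, abs=0.05)
        assert f["Flatness"] == pytest.approx(1.0, abs=0.05)
        assert f["VoxelVolume"] == mask.sum()

    def test_shape_invariant_to_intensity(self):
        # shape features consume the mask only
        mask = _ball_mask()
        a = shape_features(mask, (1, 1, 1))
        b = shape_features(mask.astype(np.uint8) * 7, (1, 1, 1))
        assert a == b

    def test_constant_roi_first_order(self):
        vals = np.full(500, 42.0)
        f = firstorder_features(vals, bin_width=25.0, voxel_volume=2.0)
        assert f["Mean"] == f["Median"] == f["Minimum"] == f["Maximum"] == 42.0
        assert f["Variance"] == 0.0
        assert f["Entropy"] == 0.0
        assert f["Uniformity"] == 1.0
        assert f["TotalEnergy"] == pytest.approx(2.0 * 500 * 42.0**2)

    def test_constant_roi_texture_entropies(self):
        # intensity-distribution entropies vanish on a constant ROI;
        # run/dependence entropies measure run geometry and only need to
        # be independent of the constant's value
        mask = _ball_mask((12, 12, 12), 5)
        levels = np.where(mask, 1, 0)
        assert glcm_features(levels, mask)["JointEntropy"] == 0.0
        assert glszm_features(levels, mask)["ZoneEntropy"] == 0.0
        other = np.where(mask, 9, 0)
        assert glrlm_features(levels, mask)["RunEntropy"] == pytest.approx(
            glrlm_features(other, mask)["RunEntropy"]
        )
        assert gldm_features(levels, mask)["DependenceEntropy"] == pytest.approx(
            gldm_features(other, mask)["DependenceEntropy"]
        )

    def test_texture_shift_invariance(self, rng):
        # bins anchored at the ROI minimum: adding a constant changes nothing
        vol = rng.random((10, 10, 10)) * 200
        mask = _ball_mask((10, 10, 10), 4)
        a = discretize(vol[mask], 25.0)
        b = discretize(vol[mask] + 1234.5, 25.0)
        np.testing.assert_array_equal(a, b)

    def test_checkerboard_glcm_contrast(self):
        # alternating levels 1/2: every distance-1 axial pair differs by 1
        z, y, x = np.indices((8, 8, 8))
        levels = 1 + (z + y + x) % 2
        mask = np.ones_like(levels, bool)
        f = glcm_features(levels, mask)
        assert f["MaximumProbability"] <= 1.0
        assert f["Contrast"] > 0.5  # parity alternation keeps contrast high

    def test_single_run_glrlm(self):
        # one straight line of equal gray: along that axis one long run
        levels = np.zeros((1, 1, 10), np.int64)
        levels[0, 0, :] = 1
        f = glrlm_features(levels, levels > 0)
        assert f["LongRunEmphasis"] > 1.0
        assert f["RunPercentage"] <= 1.0

    def test_glszm_single_zone(self):
        mask = _ball_mask((10, 10, 10), 3)
        levels = np.where(mask, 1, 0)
        f = glszm_features(levels, mask)
        assert f["ZonePercentage"] == pytest.approx(1.0 / mask.sum())
        assert f["LargeAreaEmphasis"] == pytest.approx(float(mask.sum()) ** 2)


class TestExtraction:
    @pytest.fixture(scope="class")
    def phantom_roi(self):
        rng = np.random.default_rng(0)
        vol = rng.normal(100, 20, (20, 20, 20))
        return vol, _ball_mask((20, 20, 20), 7.5)

    def test_whole_tumor_vector_length_1132(self, phantom_roi):
        vol, mask = phantom_roi
        vec = extract_feature_vector(vol, mask, FeatureConfig.whole_tumor())
        assert len(vec) == 1132
        assert vec.index.is_unique
        assert np.isfinite(vec.to_numpy()).all()

    def test_washout_vector_length_1158(self, phantom_roi):
        vol, mask = phantom_roi
        vec = extract_feature_vector(vol, mask, FeatureConfig.washout())
        assert len(vec) == 1158

    def test_degenerate_roi_flagged(self, phantom_roi):
        vol, _ = phantom_roi
        tiny = np.zeros(vol.shape, bool)
        tiny[0, 0, :5] = True
        with pytest.raises(DegenerateRoiError):
            extract_feature_vector(vol, tiny, FeatureConfig.whole_tumor())

    def test_column_naming_convention(self, phantom_roi):
        vol, mask = phantom_roi
        vec = extract_feature_vector(vol, mask, FeatureConfig.whole_tumor())
        assert "original_shape_Sphericity" in vec.index
        assert "original_firstorder_Mean" in vec.index
        assert "wavelet-HHH_glszm_ZoneEntropy" in vec.index
        assert vec["original_firstorder_Mean"] == pytest.approx(vol[mask].mean())
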