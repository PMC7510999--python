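"""Feature-family values, counts and pipeline invariances."""

import numpy as np
import pytest

from tempopet.discretise import DiscretisationScheme
from tempopet.grid_io import Image3D, VoiMask
from tempopet.static_radiomics import (
    STATIC_FAMILY_SIZES,
    extract_static_feature_set,
    glcm_features,
    glrlm_features,
    glszm_features,
    intensity_features,
    ngtdm_features,
    shape_features,
)


class TestGlcmFormulas:
    def test_hand_computed_contrast_and_energy(self):
        # probability matrix [[0, .5], [.5, 0]]: Contrast = sum p (i-j)^2 = 1,
        # JointEnergy = sum p^2 = 0.5
        counts = np.array([[0, 2], [2, 0]])
        f = glcm_features(counts)
        assert f["Contrast"] == pytest.approx(1.0)
        assert f["JointEnergy"] == pytest.approx(0.5)
        assert f["JointEntropy"] == pytest.approx(1.0)   # two cells at 0.5
        assert f["MaximumProbability"] == pytest.approx(0.5)

    def test_degenerate_single_level_conventions(self):
        f = glcm_features(np.array([[10]]))
        assert f["Correlation"] == 1.0
        assert f["Imc1"] == 0.0
        assert f["Imc2"] == 0.0
        assert f["InverseVariance"] == 0.0      # i == j terms omitted
        assert f["Contrast"] == 0.0

    def test_asymmetric_reduces_to_symmetric_definitions(self, rng):
        # when handed a symmetric matrix the two-marginal formulas must agree
        # with the classic single-marginal shortcut
        M = rng.integers(0, 9, size=(4, 4))
        M = M + M.T
        f = glcm_features(M)
        P = M / M.sum()
        iv = np.arange(1, 5)
        px = P.sum(axis=1)
        mu = iv @ px
        sig = np.sqrt(((iv - mu) ** 2) @ px)
        I, J = np.meshgrid(iv, iv, indexing="ij")
        classic = ((I * J * P).sum() - mu ** 2) / sig ** 2
        assert f["Correlation"] == pytest.approx(classic, rel=1e-12)
        assert f["JointAverage"] == pytest.approx(mu, rel=1e-12)


class TestRunZoneToneFormulas:
    def test_single_run_long_run_emphasis(self):
        R = np.zeros((2, 8), dtype=int)
        R[1, 7] = 5                       # five runs of length 8
        f = glrlm_features(R, n_potential=5 * 8)
        assert f["LongRunEmphasis"] == pytest.approx(64.0)
        assert f["ShortRunEmphasis"] == pytest.approx(1.0 / 64.0)
        assert f["RunPercentage"] == pytest.approx(5 / 40)

    def test_zone_features_on_two_zone_matrix(self):
        Z = np.zeros((2, 4), dtype=int)
        Z[0, 0] = 1    # level 1, size 1
        Z[1, 3] = 1    # level 2, size 4
        f = glszm_features(Z, n_voxels=5)
        assert f["SmallAreaEmphasis"] == pytest.approx((1 + 1 / 16) / 2)
        assert f["LargeAreaEmphasis"] == pytest.approx((1 + 16) / 2)
        assert f["ZonePercentage"] == pytest.approx(2 / 5)
        assert f["HighGrayLevelZoneEmphasis"] == pytest.approx((1 + 4) / 2)

    def test_ngtdm_uniform_voi_is_flat(self):
        n = np.array([20])
        s = np.array([0.0])
        f = ngtdm_features(n, s)
        assert f["Contrast"] == 0.0 and f["Busyness"] == 0.0
        assert f["Coarseness"] == 1e6       # no tone differences at all


class TestIntensityAndShape:
    def test_constant_voi_statistics(self):
        vals = np.full(30, 2.0)
        f = intensity_features(vals, np.full(30, 4, dtype=int), voxel_volume_mm3=27.0)
        assert f["Entropy"] == 0.0 and f["Uniformity"] == 1.0
        assert f["Variance"] == 0.0 and f["Skewness"] == 0.0
        assert f["Energy"] == pytest.approx(120.0)
        assert f["TotalEnergy"] == pytest.approx(27.0 * 120.0)

    def test_cube_shape_against_geometry(self):
        m = np.zeros((12, 12, 12), bool)
        m[2:10, 2:10, 2:10] = True           # 8x8x8 voxel cube at 2 mm spacing
        f = shape_features(VoiMask(m, spacing=2.0))
        # marching cubes traces the 0.5 iso-surface half a voxel outside the
        # outer voxel centres (side ~16 mm) and chamfers edges and corners,
        # so area and the corner-to-corner diameter sit slightly below the
        # sharp-cube values
        assert f["MeshVolume"] == pytest.approx(16.0 ** 3, rel=0.05)
        assert f["SurfaceArea"] == pytest.approx(6 * 16.0 ** 2, rel=0.10)
        assert 0.78 < f["Sphericity"] < 0.88   # sharp cube: ~0.806
        assert f["Maximum3DDiameter"] == pytest.approx(16 * np.sqrt(3), rel=0.10)
        assert f["Maximum2DDiameterAxial"] == pytest.approx(16 * np.sqrt(2), rel=0.10)
        assert f["Elongation"] == pytest.approx(1.0, rel=1e-6)
        assert f["Flatness"] == pytest.approx(1.0, rel=1e-6)

    def test_flat_slab_has_low_flatness(self):
        m = np.zeros((16, 16, 8), bool)
        m[2:14, 2:14, 3:5] = True
        f = shape_features(VoiMask(m, spacing=2.0))
        assert f["Flatness"] < 0.35
        assert f["MajorAxisLength"] > f["LeastAxisLength"] * 2.5


class TestStaticPipeline:
    def test_exactly_90_features_with_family_partition(self, noiseless_phantom):
        ph = noiseless_phantom
        feats = extract_static_feature_set(
            ph.series.frame(15), ph.voi_mask, DiscretisationScheme(0.05))
        assert len(feats) == 90
        counts = feats.groupby(level="family").size().to_dict()
        assert counts == STATIC_FAMILY_SIZES
        assert feats.index.is_unique

    def test_deterministic_repeat(self, noisy_phantom):
        ph = noisy_phantom
        a = extract_static_feature_set(ph.series.frame(15), ph.voi_mask,
                                       DiscretisationScheme(0.05))
        b = extract_static_feature_set(ph.series.frame(15), ph.voi_mask,
                                       DiscretisationScheme(0.05))
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_scale_covariance_of_texture_families(self, noiseless_phantom):
        """Scaling intensities by c with bin width c*w leaves texture unchanged."""
        ph = noiseless_phantom
        img = ph.series.frame(15)
        c = 3.7
        scaled = img.with_values(img.values * c)
        a = extract_static_feature_set(img, ph.voi_mask, DiscretisationScheme(0.05))
        b = extract_static_feature_set(scaled, ph.voi_mask,
                                       DiscretisationScheme(0.05 * c))
        for family in ("glcm", "glrlm", "glszm", "ngtdm"):
            np.testing.assert_allclose(a.loc[family].to_numpy(),
                                       b.loc[family].to_numpy(), rtol=1e-9)

    def test_two_level_lesion_has_higher_contrast_than_homogeneous(self):
        shape = (10, 10, 10)
        mask = np.zeros(shape, bool)
        mask[2:8, 2:8, 2:8] = True
        homogeneous = np.where(mask, 1.0, 0.0)
        split = homogeneous.copy()
        split[5:8, 2:8, 2:8] = 3.0          # two-level structure
        vm = VoiMask(mask, spacing=3.0)
        scheme = DiscretisationScheme(0.5)
        f_h = extract_static_feature_set(Image3D(homogeneous, 3.0), vm, scheme)
        f_s = extract_static_feature_set(Image3D(split, 3.0), vm, scheme)
        assert f_s[("glcm", "Contrast")] > f_h[("glcm", "Contrast")]

    def test_constant_voi_degenerates_cleanly(self):
        mask = np.zeros((6, 6, 6), bool)
        mask[1:5, 1:5, 1:5] = True
        img = Image3D(np.where(mask, 2.0, 0.0), spacing=3.0)
        feats = extract_static_feature_set(img, VoiMask(mask, spacing=3.0),
                                           DiscretisationScheme(0.5))
        assert feats[("glcm", "Contrast")] == 0.0
        assert feats[("glcm", "Correlation")] == 1.0
        assert feats[("intensity", "Entropy")] == 0.0
        assert np.isfinite(feats.to_numpy()).all()
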