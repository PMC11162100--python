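"""Morphometry tests: the 40-feature catalog against analytic oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import spearmanr
from skimage.draw import disk, ellipse

from conftest import match_labels
from uromorph.features import (
    FEATURE_CATALOG,
    FEATURE_NAMES,
    extract_features,
    neighborhood_features,
)
from uromorph.segmentation import CalibratedImage


def _image_with_mask(mask, fg=60, bg=230):
    rgb = np.full((*mask.shape, 3), bg, dtype=np.uint8)
    rgb[mask > 0] = fg
    return rgb


class TestCatalog:
    def test_exactly_forty_unique_features(self):
        assert len(FEATURE_NAMES) == 40
        assert len(set(FEATURE_NAMES)) == 40

    def test_family_sizes(self):
        fams = pd.Series([f for _, f in FEATURE_CATALOG]).value_counts()
        assert fams.to_dict() == {
            "geometry": 14, "color": 12, "texture": 8, "neighborhood": 6,
        }


class TestGeometry:
    def test_digital_ellipse_area_oracle(self):
        """Semi-axes 20 px and 10 px at 0.25 µm/px (5 µm and 2.5 µm): area
        within 5% of pi * 5 * 2.5 = 39.27 µm²."""
        mask = np.zeros((64, 64), dtype=np.int32)
        rr, cc = ellipse(31.6, 32.3, 20, 10)  # off-center to avoid aliasing
        mask[rr, cc] = 1
        img = CalibratedImage(_image_with_mask(mask), 0.25)
        row = extract_features(img, mask).iloc[0]
        assert row["area_um2"] == pytest.approx(np.pi * 5.0 * 2.5, rel=0.05)
        assert row["major_axis_um"] == pytest.approx(10.0, rel=0.1)
        assert row["minor_axis_um"] == pytest.approx(5.0, rel=0.1)

    def test_digital_disk_round_and_circular(self):
        mask = np.zeros((64, 64), dtype=np.int32)
        rr, cc = disk((32, 32), 12)
        mask[rr, cc] = 1
        img = CalibratedImage(_image_with_mask(mask), 0.5)
        row = extract_features(img, mask).iloc[0]
        assert row["eccentricity"] < 0.2
        assert 0.9 <= row["circularity"] <= 1.1
        assert row["aspect_ratio"] == pytest.approx(1.0, abs=0.05)

    def test_scale_equivariance_exact(self):
        """Doubling µm/px multiplies areas by 4 and lengths by 2 exactly."""
        mask = np.zeros((80, 80), dtype=np.int32)
        rr, cc = ellipse(40, 40, 14, 8, rotation=0.4)
        mask[rr, cc] = 1
        rgb = _image_with_mask(mask)
        f1 = extract_features(CalibratedImage(rgb, 0.5), mask).iloc[0]
        f2 = extract_features(CalibratedImage(rgb, 1.0), mask).iloc[0]
        for name in ("area_um2", "convex_area_um2", "bbox_area_um2"):
            assert f2[name] == pytest.approx(4.0 * f1[name], rel=1e-12)
        for name in (
            "perimeter_um", "equivalent_diameter_um", "major_axis_um",
            "minor_axis_um", "radial_sd_um",
        ):
            assert f2[name] == pytest.approx(2.0 * f1[name], rel=1e-12)


class TestColorAndTexture:
    def test_uniform_nucleus_zero_variation(self):
        """A nucleus rendered at constant intensity has sd_intensity = 0 and
        glcm_contrast = 0."""
        mask = np.zeros((40, 40), dtype=np.int32)
        rr, cc = disk((20, 20), 8)
        mask[rr, cc] = 1
        img = CalibratedImage(_image_with_mask(mask, fg=77), 0.5)
        row = extract_features(img, mask).iloc[0]
        assert row["sd_intensity"] == 0.0
        assert row["glcm_contrast"] == 0.0
        assert row["min_intensity"] == row["max_intensity"]

    def test_darker_nucleus_lower_intensity_higher_od(self):
        mask = np.zeros((40, 80), dtype=np.int32)
        rr, cc = disk((20, 20), 8)
        mask[rr, cc] = 1
        rr, cc = disk((20, 60), 8)
        mask[rr, cc] = 2
        rgb = np.full((40, 80, 3), 230, dtype=np.uint8)
        rgb[mask == 1] = 120
        rgb[mask == 2] = 40
        df = extract_features(CalibratedImage(rgb, 0.5), mask).set_index("label")
        assert df.loc[2, "mean_intensity"] < df.loc[1, "mean_intensity"]
        assert df.loc[2, "mean_hematoxylin_od"] > df.loc[1, "mean_hematoxylin_od"]

    def test_tiny_speck_gets_nan_texture(self):
        mask = np.zeros((20, 20), dtype=np.int32)
        mask[5:6, 5:8] = 1  # 3 px
        img = CalibratedImage(_image_with_mask(mask), 0.5)
        row = extract_features(img, mask).iloc[0]
        texture_cols = [n for n, fam in FEATURE_CATALOG if fam == "texture"]
        assert row[texture_cols].isna().all()
        assert row["area_um2"] > 0  # geometry still defined


class TestNeighborhood:
    def test_single_nucleus_undefined(self):
        out = neighborhood_features(np.array([[10.0, 10.0]]))
        assert np.isnan(out.loc[0, "nn1_distance_um"])

    def test_two_nuclei_symmetric(self):
        out = neighborhood_features(np.array([[0.0, 0.0], [30.0, 0.0]]))
        assert out["nn1_distance_um"].tolist() == [30.0, 30.0]

    def test_three_collinear_hand_oracle(self):
        out = neighborhood_features(np.array([[0.0, 0.0], [10.0, 0.0], [25.0, 0.0]]))
        assert out["nn1_distance_um"].tolist() == [10.0, 10.0, 15.0]
        # nn3 undefined with only two neighbors available
        assert out["nn3_mean_distance_um"].isna().all()

    def test_empty_input(self):
        assert len(neighborhood_features(np.empty((0, 2)))) == 0

    def test_count_within_radius(self):
        pts = np.array([[0.0, 0.0], [30.0, 0.0], [45.0, 0.0], [200.0, 0.0]])
        out = neighborhood_features(pts)
        assert out["count_within_50um"].tolist() == [2.0, 2.0, 2.0, 0.0]
        assert out.loc[0, "crowding_fraction_within_50um"] == pytest.approx(2 / 3)

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 500, allow_nan=False), st.floats(0, 500, allow_nan=False)
            ),
            min_size=2,
            max_size=25,
            unique=True,
        )
    )
    def test_nn1_matches_brute_force(self, points):
        """The nearest-neighbor distances agree exactly with an O(n²)
        brute-force oracle."""
        pts = np.asarray(points, dtype=float)
        out = neighborhood_features(pts)
        d2 = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d2, np.inf)
        brute = d2.min(axis=1)
        np.testing.assert_allclose(out["nn1_distance_um"].to_numpy(), brute, rtol=1e-9)


class TestAgainstGroundTruth:
    def test_measured_areas_track_truth(self, group5_segmented):
        """Measured areas within 5% of truth for nuclei >= 30 µm² (95% of
        them; digitization allows rare larger deviations) and intensity
        rank-correlates with drawn optical density (|rho| >= 0.9)."""
        cfg, rgb, gt, mask = group5_segmented
        img = CalibratedImage(rgb, cfg.microns_per_pixel)
        feats = extract_features(img, mask).set_index("label")
        matches = match_labels(mask, gt.label_mask)
        truth = gt.records.set_index("label")
        merged = matches.join(truth, on="truth_label").join(
            feats[["area_um2", "mean_intensity"]], on="seg_label"
        )
        big = merged[merged["true_area_um2"] >= 30.0]
        rel_err = (big["area_um2"] - big["true_area_um2"]).abs() / big["true_area_um2"]
        assert (rel_err <= 0.05).mean() >= 0.95
        assert rel_err.median() <= 0.02
        rho = spearmanr(merged["mean_intensity"], merged["hematoxylin_od"]).statistic
        assert rho <= -0.9
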