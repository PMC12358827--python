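"""Spot segmentation, normalization, calibration and pg/cell arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from nanospot import (
    CalibrationModel,
    GridTransform,
    SpotParams,
    WellLayout,
    fit_calibration,
    match_spots_to_wells,
    normalize_intensities,
    quantify_spot,
    quantify_spots,
    segment_psa_spots,
)

LAYOUT = WellLayout(10, 10, pitch_px=50.0, origin_px=(100.0, 100.0),
                    well_radius_px=8.0)
IDENT = GridTransform(scale=1.0, rotation_deg=0.0, translation=(0.0, 0.0))


def _disc_image(radius=10, center=(50, 50), value=100.0, shape=(101, 101)):
    img = np.zeros(shape)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    img[(xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2] = value
    return img


def _ellipse_image(a=20, b=5, shape=(101, 101), value=100.0):
    img = np.zeros(shape)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    img[((xx - 50) / a) ** 2 + ((yy - 50) / b) ** 2 <= 1.0] = value
    return img


class TestSegmentation:
    def test_disc_area_matches_flood_fill_oracle_exactly(self):
        img = _disc_image(radius=10)
        spots = segment_psa_spots(img, 1.0, SpotParams(threshold=50.0))
        lab, _ = ndimage.label(img > 50.0)
        assert spots["pixel_area"].iloc[0] == int((lab == 1).sum())

    def test_disc_area_and_roundness(self):
        spots = segment_psa_spots(_disc_image(radius=10), 1.0,
                                  SpotParams(threshold=50.0))
        assert len(spots) == 1
        assert spots["pixel_area"].iloc[0] == pytest.approx(np.pi * 100, rel=0.05)
        assert spots["roundness"].iloc[0] >= 0.9

    def test_elongated_ellipse_filtered_by_roundness(self):
        img = _ellipse_image(a=40, b=10, shape=(201, 201))
        kept = segment_psa_spots(
            img, 1.0, SpotParams(threshold=50.0, max_area_px=10**5)
        )
        assert len(kept) == 0  # roundness ~ b/a = 0.25 < 0.64
        raw = segment_psa_spots(
            img, 1.0,
            SpotParams(threshold=50.0, roundness_min=0.0, max_area_px=10**5),
        )
        # analytic roundness 4(pi a b)/(pi (2a)^2) = b/a
        assert raw["roundness"].iloc[0] == pytest.approx(0.25, rel=0.05)

    def test_blank_image_yields_empty_frame(self):
        spots = segment_psa_spots(np.zeros((50, 50)), 1.0,
                                  SpotParams(threshold=10.0))
        assert len(spots) == 0

    def test_area_window_excludes_small_and_large(self):
        img = _disc_image(radius=3) + _disc_image(radius=45, center=(250, 250),
                                                  shape=(101, 101))[:101, :101]
        img2 = np.zeros((301, 301))
        img2[:101, :101] = _disc_image(radius=3)
        img2[100:201, 100:201] = _disc_image(radius=45, shape=(101, 101),
                                             center=(50, 50))
        spots = segment_psa_spots(
            img2, 1.0, SpotParams(threshold=50.0, min_area_px=50, max_area_px=5000)
        )
        assert len(spots) == 0

    def test_mean_intensity_is_component_mean(self):
        img = _disc_image(radius=8, value=320.0)
        spots = segment_psa_spots(img, 2.0, SpotParams(threshold=100.0))
        assert spots["mean_intensity"].iloc[0] == pytest.approx(320.0)
        assert spots["area_um2"].iloc[0] == spots["pixel_area"].iloc[0] * 4.0

    def test_random_blobs_match_labeling_oracle(self):
        from skimage.data import binary_blobs
        img = binary_blobs(128, blob_size_fraction=0.08, rng=7).astype(float)
        spots = segment_psa_spots(
            img, 1.0,
            SpotParams(threshold=0.5, min_area_px=1, max_area_px=10**6,
                       roundness_min=0.0),
        )
        # 8-connectivity, the particle-analysis convention
        lab, n = ndimage.label(img > 0.5, structure=np.ones((3, 3)))
        oracle = np.sort(ndimage.sum_labels(np.ones_like(img), lab,
                                            np.arange(1, n + 1)))
        assert np.array_equal(np.sort(spots["pixel_area"].to_numpy()), oracle)


class TestNormalization:
    SPOTS = pd.DataFrame({"mean_intensity": [350.0, 100.0], "area_um2": [1.0, 1.0]})

    def test_fold_over_background(self):
        out = normalize_intensities(self.SPOTS, np.full(50, 100.0))
        assert out["normalized_intensity"].tolist() == [3.5, 1.0]

    def test_zero_background_raises(self):
        with pytest.raises(ValueError, match="background"):
            normalize_intensities(self.SPOTS, np.zeros(5))

    def test_short_background_sample_warns_but_computes(self):
        from nanospot import measure_background_wells
        img = np.full((600, 600), 100.0)
        with pytest.warns(UserWarning, match="background wells"):
            bg = measure_background_wells(img, IDENT, LAYOUT,
                                          np.arange(1, 11), n=50)
        assert len(bg) == 10
        out = normalize_intensities(self.SPOTS, bg)
        assert out["normalized_intensity"].iloc[0] == pytest.approx(3.5)


def _standards(densities, ni):
    # encode density through area at fixed concentration x volume
    dens = np.asarray(densities, dtype=float)
    return pd.DataFrame(
        {
            "concentration_ug_per_ml": 500.0,
            "volume_ul": 2.0,
            "area_um2": 500.0 * 2.0 * 1000.0 / dens,
            "normalized_intensity": ni,
        }
    )


class TestCalibration:
    def test_exact_line_recovered(self):
        d = np.array([0.05, 0.1, 0.2, 0.4, 1.0])
        model = fit_calibration(_standards(d, 2.0 * d + 0.1))
        assert model.slope == pytest.approx(2.0)
        assert model.intercept == pytest.approx(0.1)
        assert model.r_squared == pytest.approx(1.0)

    def test_too_few_standards_raise(self):
        d = np.array([0.1, 0.2])
        with pytest.raises(ValueError, match="at least 3"):
            fit_calibration(_standards(d, d))

    def test_degenerate_density_raises(self):
        d = np.array([0.2, 0.2, 0.2])
        with pytest.raises(ValueError, match="variance"):
            fit_calibration(_standards(d, d))

    def test_missing_column_raises(self):
        with pytest.raises(KeyError, match="volume_ul"):
            fit_calibration(pd.DataFrame({"concentration_ug_per_ml": [1, 2, 3]}))

    def test_noisy_standards_recover_slope_within_3se(self, rng):
        d = np.array([0.0315, 0.063, 0.125, 0.25, 0.5])
        true_slope, true_int = 200.0, 1.0
        ni_range = true_slope * (d.max() - d.min())
        noise = rng.normal(0, 0.05 * ni_range, len(d))
        model = fit_calibration(_standards(d, true_int + true_slope * d + noise))
        assert abs(model.slope - true_slope) <= 3 * model.slope_se
        assert model.r_squared >= 0.9


class TestQuantify:
    MODEL = CalibrationModel(slope=1.0, intercept=0.0, r_squared=1.0,
                             density_range=(0.0, 1.0))

    def test_arithmetic(self):
        density, pg, clamped = quantify_spot(0.005, 1200.0, self.MODEL)
        assert density == pytest.approx(0.005)
        assert pg == pytest.approx(6.0)
        assert not clamped

    def test_intensity_at_intercept_gives_zero(self):
        model = CalibrationModel(slope=2.0, intercept=0.3, r_squared=1.0,
                                 density_range=(0.0, 1.0))
        _, pg, clamped = quantify_spot(0.3, 1200.0, model)
        assert pg == 0.0 and not clamped

    def test_below_intercept_clamps_with_flag(self):
        _, pg, clamped = quantify_spot(-0.5, 1000.0, self.MODEL)
        assert pg == 0.0 and clamped

    def test_non_positive_slope_raises(self):
        bad = CalibrationModel(slope=0.0, intercept=0.0, r_squared=0.5,
                               density_range=(0.0, 1.0))
        with pytest.raises(ValueError, match="slope"):
            quantify_spot(1.0, 1.0, bad)

    def test_unprepared_spots_table_raises(self):
        with pytest.raises(ValueError, match="matched"):
            quantify_spots(pd.DataFrame({"area_um2": [1.0]}), self.MODEL)

    @settings(max_examples=50, deadline=None)
    @given(
        ni=st.floats(0.01, 10.0), area=st.floats(1.0, 1e4),
        dni=st.floats(0.01, 1.0), darea=st.floats(0.01, 100.0),
    )
    def test_pg_monotone_in_intensity_and_area(self, ni, area, dni, darea):
        """Above the intercept, pg/cell strictly increases in normalized
        intensity at fixed area and in area at fixed density."""
        _, pg0, _ = quantify_spot(ni, area, self.MODEL)
        _, pg1, _ = quantify_spot(ni + dni, area, self.MODEL)
        _, pg2, _ = quantify_spot(ni, area + darea, self.MODEL)
        assert pg1 > pg0
        assert pg2 > pg0


class TestMatchSpots:
    def _spots(self, rows):
        return pd.DataFrame(
            rows, columns=["x", "y", "pixel_area", "area_um2",
                           "mean_intensity", "roundness"]
        )

    def test_spot_at_transformed_center_matches_well(self):
        t = GridTransform(scale=1.0, rotation_deg=1.0, translation=(6.0, -3.0))
        x, y = t.forward(LAYOUT.center(42))
        spots = self._spots([[x, y, 100, 400.0, 5.0, 0.9]])
        out = match_spots_to_wells(spots, t, LAYOUT)
        assert out["matched_well"].iloc[0] == 42

    def test_fragments_merge_area_weighted(self):
        x, y = LAYOUT.center(42)
        spots = self._spots(
            [[x - 2, y, 200, 200.0, 3.0, 0.9], [x + 2, y, 100, 100.0, 6.0, 0.8]]
        )
        out = match_spots_to_wells(spots, IDENT, LAYOUT)
        assert len(out) == 1
        assert out["pixel_area"].iloc[0] == 300
        assert out["area_um2"].iloc[0] == pytest.approx(300.0)
        assert out["mean_intensity"].iloc[0] == pytest.approx(4.0)

    def test_off_chip_spot_kept_unmatched_and_excluded_from_records(self):
        spots = self._spots([[3000.0, 3000.0, 100, 100.0, 5.0, 0.9]])
        out = match_spots_to_wells(spots, IDENT, LAYOUT)
        assert out["matched_well"].isna().all()
        out["normalized_intensity"] = 2.0
        model = CalibrationModel(slope=1.0, intercept=1.0, r_squared=1.0,
                                 density_range=(0.0, 1.0))
        assert len(quantify_spots(out, model)) == 0

    def test_empty_spot_table_passes_through(self):
        out = match_spots_to_wells(self._spots([]), IDENT, LAYOUT)
        assert len(out) == 0 and "matched_well" in out.columns
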