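"""Per-section metrics: intensity, fractions, nucleus shape, FWHM, normalization."""

import math

import numpy as np
import pytest

from tendonquant import (
    ValidationError,
    area_fraction,
    fit_nucleus_shapes,
    mean_intensity,
    normalize_by_diameter,
    orientation_spread,
    quantify_section,
)
from tendonquant.quantification import SectionMetrics, circular_mean_axial_deg
from tendonquant.segmentation import BinaryMask, LabeledNuclei
from tendonquant.synthetic import _ellipse_coords, generate_section

from conftest import make_section


class TestMeanIntensity:
    def test_constant_field_recovered(self):
        red = np.full((10, 10), 150, dtype=np.uint8)
        mask = np.zeros((10, 10), dtype=bool)
        mask[:5] = True
        assert mean_intensity(red, mask) == 150.0

    def test_weighted_mean(self):
        # oracle: (100*30 + 200*10) / 40 = 125
        red = np.zeros((8, 8), dtype=np.uint8)
        mask = np.zeros((8, 8), dtype=bool)
        red.ravel()[:30] = 100
        red.ravel()[30:40] = 200
        mask.ravel()[:40] = True
        assert mean_intensity(red, mask) == 125.0

    def test_empty_mask_is_undefined_not_zero(self):
        with pytest.warns(UserWarning):
            out = mean_intensity(np.zeros((5, 5)), np.zeros((5, 5), dtype=bool))
        assert math.isnan(out)

    def test_localized_to_mask(self, rng):
        red = np.full((20, 20), 80, dtype=np.uint8)
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:10, 5:10] = True
        before = mean_intensity(red, mask)
        red[~mask] = rng.integers(0, 256, (20, 20), dtype=np.uint8)[~mask]
        assert mean_intensity(red, mask) == before


def test_area_fraction_counts_pixels():
    assert area_fraction(np.zeros((5, 5), dtype=bool)) == 0.0
    assert area_fraction(np.ones((5, 5), dtype=bool)) == 1.0
    mask = np.zeros((50, 50), dtype=bool)
    mask.ravel()[:250] = True
    assert area_fraction(BinaryMask(mask, "stain")) == pytest.approx(0.10)


def _nuclei_from_mask(mask: np.ndarray) -> LabeledNuclei:
    return LabeledNuclei((mask > 0).astype(np.int32), 1)


class TestNucleusShapes:
    def test_horizontal_row_orientation_zero(self):
        mask = np.zeros((10, 30), dtype=np.uint8)
        mask[5, 5:25] = 1
        (shape,) = fit_nucleus_shapes(_nuclei_from_mask(mask))
        assert shape.orientation_deg == pytest.approx(0.0, abs=1e-9)
        assert shape.aspect_ratio <= 0.1
        assert shape.minor_axis_px <= shape.major_axis_px

    def test_disk_is_round(self):
        mask = np.zeros((40, 40), dtype=np.uint8)
        rr, cc = _ellipse_coords((40, 40), 20, 20, 10, 10, 0)
        mask[rr, cc] = 1
        (shape,) = fit_nucleus_shapes(_nuclei_from_mask(mask))
        assert 0.95 <= shape.aspect_ratio <= 1.0

    def test_rotated_ellipse_recovers_drawn_parameters(self):
        # ground truth: full axes 20 and 8, major axis at +30 degrees
        mask = np.zeros((60, 60), dtype=np.uint8)
        rr, cc = _ellipse_coords((60, 60), 30, 30, 10, 4, 30)
        mask[rr, cc] = 1
        (shape,) = fit_nucleus_shapes(_nuclei_from_mask(mask))
        assert shape.aspect_ratio == pytest.approx(0.4, abs=0.05)
        assert shape.orientation_deg == pytest.approx(30, abs=3)

    @pytest.mark.parametrize("angle", [-75, -40, 0, 15, 55, 85])
    def test_aspect_ratio_rotation_invariant(self, angle):
        mask = np.zeros((64, 64), dtype=np.uint8)
        rr, cc = _ellipse_coords((64, 64), 32, 32, 12, 6, angle)
        mask[rr, cc] = 1
        (shape,) = fit_nucleus_shapes(_nuclei_from_mask(mask))
        assert shape.aspect_ratio == pytest.approx(0.5, abs=0.03)
        assert shape.orientation_deg == pytest.approx(angle, abs=3)

    def test_no_nuclei_rejected(self):
        with pytest.raises(ValidationError):
            fit_nucleus_shapes(LabeledNuclei(np.zeros((5, 5), dtype=np.int32), 0))


class TestOrientationSpread:
    def test_identical_angles_within_one_bin(self):
        dist = orientation_spread([12.0] * 50)
        assert dist.fwhm_deg <= 10.0

    def test_uniform_angles_give_180(self):
        angles = np.arange(-90, 90, 1.0)
        assert orientation_spread(angles).fwhm_deg == 180.0

    def test_wrapped_normal_matches_closed_form(self, rng):
        # oracle: FWHM of a normal = 2 sqrt(2 ln 2) sigma ~ 35.3 at sigma 15
        sigma = 15.0
        angles = rng.normal(0.0, sigma, size=500)
        fwhm = orientation_spread(angles).fwhm_deg
        expected = 2 * math.sqrt(2 * math.log(2)) * sigma
        assert abs(fwhm - expected) <= 0.2 * expected

    @pytest.mark.parametrize("shift", [30.0, 85.0, -60.0])
    def test_invariant_to_global_rotation(self, rng, shift):
        angles = rng.normal(0.0, 12.0, size=300)
        base = orientation_spread(angles).fwhm_deg
        rotated = (angles + shift + 90.0) % 180.0 - 90.0
        assert abs(orientation_spread(rotated).fwhm_deg - base) <= 10.0

    def test_circular_mean_handles_wraparound(self):
        # angles clustered around the +-90 seam
        angles = np.array([-88.0, -89.0, 89.0, 88.0])
        mean = circular_mean_axial_deg(angles)
        assert abs(abs(mean) - 90.0) <= 1.5 or abs(mean + 90.0) <= 1.5
        assert orientation_spread(angles).fwhm_deg <= 20.0

    def test_fewer_than_two_shapes_rejected(self):
        with pytest.raises(ValidationError):
            orientation_spread([5.0])
        with pytest.raises(ValidationError):
            orientation_spread([1.0, 2.0], bin_width_deg=7.0)


class TestDiameterNormalization:
    def test_division_and_identity(self):
        m = SectionMetrics(mean_intensity=120.0, nuclei_area_fraction=0.08,
                           vessel_area_fraction=0.04)
        out = normalize_by_diameter(m, 2.0)
        assert out.normalized_mean_intensity == 60.0
        assert out.normalized_nuclei_area_fraction == pytest.approx(0.04)
        assert out.mean_intensity == 120.0  # raw unchanged
        unit = normalize_by_diameter(m, 1.0)
        assert unit.normalized_mean_intensity == m.mean_intensity

    def test_two_sections_scale_in_ratio(self):
        m = SectionMetrics(mean_intensity=90.0)
        a = normalize_by_diameter(m, 1.5)
        b = normalize_by_diameter(m, 3.0)
        assert a.normalized_mean_intensity / b.normalized_mean_intensity == pytest.approx(2.0)

    def test_non_positive_diameter_rejected(self):
        with pytest.raises(ValidationError):
            normalize_by_diameter(SectionMetrics(), 0.0)


class TestQuantifySection:
    def test_synthetic_collagen_ground_truth_recovered(self):
        sec, truth = generate_section(
            "collagen1",
            size=(256, 256),
            seed=5,
            stain_mean_intensity=140.0,
            vessel_count=6,
            nuclei_area_fraction=0.06,
            nucleus_aspect_ratio=0.6,
            orientation_sigma_deg=20.0,
        )
        m = quantify_section(sec)
        assert m.mean_intensity == truth.stain_mean_intensity
        assert abs(m.nuclei_area_fraction - truth.nuclei_area_fraction) <= 0.005
        # detected vessel area bounded by truth and its radius-8 dilation
        assert truth.vessel_area_fraction <= m.vessel_area_fraction
        assert m.vessel_area_fraction <= truth.vessel_area_fraction * (
            (8.0 + 6.5 + 1) / 6.5
        ) ** 2
        assert abs(m.mean_aspect_ratio - truth.nucleus_aspect_ratio) <= 0.05

    def test_blank_section_yields_zero_fractions_and_undefined_intensity(self):
        sec = make_section(np.zeros((64, 64)), blue=np.zeros((64, 64)))
        m = quantify_section(sec)
        assert m.stain_area_fraction == 0.0
        assert m.vessel_area_fraction == 0.0
        assert m.nucleus_count == 0
        assert math.isnan(m.mean_intensity)

    def test_elastin_section_has_no_vessel_fraction(self):
        sec, _ = generate_section("elastin", size=(128, 128), seed=3, dot_count=5)
        m = quantify_section(sec)
        assert math.isnan(m.vessel_area_fraction)
        assert m.mean_intensity == pytest.approx(100.0)

    def test_diameter_triggers_normalized_fields(self):
        sec, _ = generate_section(
            "collagen1", size=(96, 96), seed=2, tendon_diameter_mm=2.0
        )
        m = quantify_section(sec)
        assert m.normalized_mean_intensity == pytest.approx(m.mean_intensity / 2.0)
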