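"""Pixel-moment morphometry against brute-force oracles and geometric
invariances."""

import math

import numpy as np
import pytest
from scipy import ndimage

from flowalign import (
    LabelMask,
    equivalent_ellipse_axes,
    measure_cells,
    orientation_from_moments,
)
from flowalign.alignment import axial_difference

from helpers import brute_force_moments, random_blob


class TestRectangleExample:
    """A solid 5x3 rectangle has closed-form moments under the
    pixel-center convention."""

    def test_axis_aligned_rectangle(self, rectangle_mask):
        (cell,) = measure_cells(rectangle_mask)
        assert cell.area_px == 15
        assert cell.orientation_deg == pytest.approx(0.0, abs=1e-12)
        assert cell.mu20 == pytest.approx(2.0, rel=1e-12)
        assert cell.mu02 == pytest.approx(2.0 / 3.0, rel=1e-12)
        assert cell.major_len == pytest.approx(4.0 * math.sqrt(2.0), rel=1e-12)
        assert cell.minor_len == pytest.approx(4.0 * math.sqrt(2.0 / 3.0), rel=1e-12)
        assert cell.elongation_factor == pytest.approx(math.sqrt(3.0), rel=1e-12)
        assert not cell.touches_border

    def test_transposed_rectangle(self, rectangle_mask):
        (cell,) = measure_cells(rectangle_mask.pixels.T)
        assert cell.orientation_deg == pytest.approx(90.0, abs=1e-12)
        assert cell.elongation_factor == pytest.approx(math.sqrt(3.0), rel=1e-12)


class TestDegenerateCells:
    def test_single_pixel(self):
        arr = np.zeros((5, 5), dtype=np.int32)
        arr[2, 2] = 1
        (cell,) = measure_cells(arr)
        assert cell.area_px == 1
        assert cell.elongation_factor == 1.0
        assert cell.orientation_deg == 0.0
        assert cell.major_len == 0.0

    def test_collinear_pixels_are_infinitely_elongated(self):
        arr = np.zeros((7, 7), dtype=np.int32)
        arr[3, 1:6] = 1
        (cell,) = measure_cells(arr)
        assert cell.minor_len == 0.0
        assert math.isinf(cell.elongation_factor)
        assert cell.orientation_deg == pytest.approx(0.0)

    def test_empty_mask_gives_empty_list(self):
        assert measure_cells(np.zeros((4, 4), dtype=np.int32)) == []


@pytest.mark.parametrize(
    "mu20, mu11, mu02, expected",
    [
        (2.0, 0.0, 1.0, 0.0),  # wider than tall
        (1.0, 0.0, 2.0, 90.0),  # taller than wide
        (1.0, 0.5, 1.0, 45.0),  # symmetric positive shear
        (1.0, -0.5, 1.0, -45.0),
        (1.0, 0.0, 1.0, 0.0),  # isotropic convention
    ],
)
def test_orientation_from_moments(mu20, mu11, mu02, expected):
    assert orientation_from_moments(mu20, mu11, mu02) == pytest.approx(
        expected, abs=1e-12
    )


class TestEquivalentEllipseAxes:
    def test_closed_forms(self):
        assert equivalent_ellipse_axes(0.0, 0.0) == (0.0, 0.0)
        major, minor = equivalent_ellipse_axes(2.0, 2.0 / 3.0)
        assert major == pytest.approx(5.656854249492381, rel=1e-12)
        assert minor == pytest.approx(3.265986323710904, rel=1e-12)
        assert equivalent_ellipse_axes(1.0, 1.0) == (4.0, 4.0)

    def test_negative_eigenvalue_rejected(self):
        with pytest.raises(ValueError):
            equivalent_ellipse_axes(1.0, -0.1)


def test_oracle_equivalence_on_random_blobs(rng):
    """Production moments/axes/orientation match a brute-force double-loop
    implementation to 1e-9 relative tolerance on 100 random blobs."""
    for _ in range(100):
        blob = random_blob(rng)
        (cell,) = measure_cells(blob)
        ref = brute_force_moments(blob, 1)
        assert cell.area_px == ref["area"]
        assert cell.centroid == pytest.approx(ref["centroid"], rel=1e-9)
        assert cell.mu20 == pytest.approx(ref["mu20"], rel=1e-9, abs=1e-12)
        assert cell.mu11 == pytest.approx(ref["mu11"], rel=1e-9, abs=1e-9)
        assert cell.mu02 == pytest.approx(ref["mu02"], rel=1e-9, abs=1e-12)
        assert cell.major_len == pytest.approx(ref["major_len"], rel=1e-9)
        assert cell.minor_len == pytest.approx(ref["minor_len"], rel=1e-9, abs=1e-9)
        assert abs(
            axial_difference(cell.orientation_deg, ref["orientation_deg"])
        ) < 1e-9 or cell.elongation_factor < 1.0 + 1e-9


def test_agrees_with_skimage_regionprops(rng):
    """Independent cross-check against skimage.regionprops (axis lengths
    equal; orientation related by theta = wrap(skimage_deg + 90))."""
    from skimage.measure import regionprops

    for _ in range(10):
        blob = random_blob(rng, min_area=80)
        (cell,) = measure_cells(blob)
        (props,) = regionprops(blob)
        assert cell.area_px == props.area
        assert cell.major_len == pytest.approx(props.axis_major_length, rel=1e-9)
        assert cell.minor_len == pytest.approx(props.axis_minor_length, rel=1e-9)
        if cell.elongation_factor > 1.05:  # orientation well-defined
            converted = math.degrees(props.orientation) + 90.0
            assert abs(axial_difference(cell.orientation_deg, converted)) < 1e-6


class TestGeometricInvariance:
    @pytest.mark.parametrize("offset", [(3, 0), (0, 5), (7, 11)])
    def test_translation_invariance(self, rng, offset):
        blob = random_blob(rng, shape=(48, 48))
        big = np.zeros((72, 72), dtype=blob.dtype)
        shifted = big.copy()
        big[:48, :48] = blob
        shifted[offset[0] : offset[0] + 48, offset[1] : offset[1] + 48] = blob
        blob = big
        (a,) = measure_cells(blob)
        (b,) = measure_cells(shifted)
        assert a.area_px == b.area_px
        assert (a.mu20, a.mu11, a.mu02) == pytest.approx((b.mu20, b.mu11, b.mu02))
        assert a.orientation_deg == pytest.approx(b.orientation_deg)
        assert a.elongation_factor == pytest.approx(b.elongation_factor)

    def test_rot90_wraps_orientation_and_preserves_elongation(self, rng):
        for _ in range(20):
            blob = random_blob(rng)
            (a,) = measure_cells(blob)
            (b,) = measure_cells(np.rot90(blob))
            assert b.elongation_factor == pytest.approx(a.elongation_factor, rel=1e-12)
            if a.elongation_factor > 1.05:
                expected = axial_difference(a.orientation_deg + 90.0, 0.0)
                assert abs(axial_difference(b.orientation_deg, expected)) < 1e-9

    @pytest.mark.parametrize("angle", [17.0, 33.0, 61.0])
    def test_raster_rotation_changes_elongation_by_at_most_5pct(self, rng, angle):
        """Nearest-neighbour raster rotation perturbs the elongation factor
        by no more than 5% for blobs of at least 200 px."""
        blob = random_blob(rng, shape=(128, 128), min_area=300)
        rotated = ndimage.rotate(blob, angle, order=0, reshape=True)
        (a,) = measure_cells(blob)
        (b,) = measure_cells(rotated)
        assert b.elongation_factor == pytest.approx(a.elongation_factor, rel=0.05)


def test_disconnected_label_measured_as_one_region(caplog):
    arr = np.zeros((10, 10), dtype=np.int32)
    arr[1:3, 1:3] = 1
    arr[7:9, 7:9] = 1
    import logging

    with caplog.at_level(logging.WARNING, logger="flowalign.morphometry"):
        cells = measure_cells(arr)
    assert len(cells) == 1
    assert cells[0].area_px == 8
    assert any("disconnected" in r.message for r in caplog.records)


def test_border_flag_set_only_on_edge_contact():
    arr = np.zeros((6, 6), dtype=np.int32)
    arr[0:2, 2:4] = 1  # touches row 0
    arr[3:5, 2:4] = 2  # interior
    cells = {c.label: c for c in measure_cells(arr)}
    assert cells[1].touches_border
    assert not cells[2].touches_border
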