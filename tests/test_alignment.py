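"""Axial orientation statistics: wrapping, median, deviations, CV and
radial histograms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flowalign import (
    UNIFORM_NULL_CV,
    alignment_cv,
    axial_difference,
    axial_mean,
    axial_median,
    deviations_from_median,
    radial_histogram,
    sample_orientations,
)
from flowalign.alignment import AlignmentSummary, ElongationSummary

from helpers import axial_median_exhaustive

angles = st.floats(min_value=-1e4, max_value=1e4, allow_nan=False)


class TestAxialDifference:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (30.0, 10.0, 20.0),
            (42.0, 42.0, 0.0),
            (85.0, -85.0, -10.0),  # short way around the axial circle
            (90.0, 0.0, 90.0),
            (0.0, 90.0, 90.0),  # -90 maps to the +90 edge
        ],
    )
    def test_examples(self, a, b, expected):
        assert axial_difference(a, b) == pytest.approx(expected, abs=1e-12)

    @given(a=angles, b=angles)
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_range_and_period(self, a, b):
        d = axial_difference(a, b)
        assert -90.0 < d <= 90.0
        assert axial_difference(a + 180.0, b) == pytest.approx(d, abs=1e-6)


class TestAxialMedian:
    @pytest.mark.parametrize(
        "orientations, expected",
        [
            ([10.0, 20.0, 30.0], 20.0),
            ([-80.0, 80.0, 90.0], 90.0),  # wraps the short way
            ([0.0, 90.0], 0.0),  # tie broken by smallest angle
        ],
    )
    def test_examples(self, orientations, expected):
        assert axial_median(orientations) == pytest.approx(expected)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            axial_median([])

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(50):
            theta = rng.uniform(-90.0, 90.0, size=rng.integers(2, 25))
            got = axial_median(theta)
            ref = axial_median_exhaustive(theta)
            assert abs(axial_difference(got, ref)) < 1e-9


class TestDeviations:
    def test_simple(self):
        assert deviations_from_median([10, 20, 30]) == pytest.approx([-10, 0, 10])

    def test_all_equal_gives_zeros(self):
        assert deviations_from_median([37.0] * 5) == pytest.approx([0.0] * 5)

    def test_wrapped_case(self):
        # median of {85, -85, 90} is 90 (total axial distance 10)
        assert deviations_from_median([85.0, -85.0, 90.0]) == pytest.approx(
            [-5.0, 5.0, 0.0]
        )

    def test_median_of_deviations_is_zero(self, rng):
        for _ in range(20):
            theta = rng.uniform(-90, 90, size=31)
            dev = deviations_from_median(theta)
            assert abs(axial_median(dev)) < 1e-9


class TestAlignmentCV:
    def test_all_zero_deviations(self):
        assert alignment_cv([0.0, 0.0, 0.0]) == 0.0

    def test_two_point_example(self):
        # shifted values {45, 135}: mean 90, sample SD 45*sqrt(2)
        cv = alignment_cv([-45.0, 45.0])
        assert cv == pytest.approx(45.0 * math.sqrt(2.0) / 90.0, rel=1e-12)

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            alignment_cv([3.0])

    def test_uniform_null_monte_carlo_mean(self, rng):
        """Mean CV over 1000 replicates of 100 i.i.d. uniform axial
        deviations is within 0.02 of 1/sqrt(3)."""
        cvs = [
            alignment_cv(rng.uniform(-90, 90, size=100)) for _ in range(1000)
        ]
        assert np.mean(cvs) == pytest.approx(UNIFORM_NULL_CV, abs=0.02)

    def test_median_centering_keeps_uniform_cv_near_null(self, rng):
        """Through the full median-centering path the uniform-null CV keeps
        a small finite-sample downward bias but stays within 0.05 of
        1/sqrt(3) at n = 100."""
        cvs = [
            alignment_cv(deviations_from_median(rng.uniform(-90, 90, size=100)))
            for _ in range(400)
        ]
        assert np.median(cvs) == pytest.approx(UNIFORM_NULL_CV, abs=0.05)

    def test_cv_decreases_with_concentration(self, rng):
        """Mean CV strictly decreases through kappa in {0, 1, 2, 4, 8}
        (200 replicates each)."""
        means = []
        for kappa in [0.0, 1.0, 2.0, 4.0, 8.0]:
            cvs = [
                alignment_cv(
                    deviations_from_median(
                        sample_orientations(100, kappa, mu=0.0, rng=rng)
                    )
                )
                for _ in range(200)
            ]
            means.append(np.mean(cvs))
        assert all(a > b for a, b in zip(means, means[1:]))


class TestRadialHistogram:
    def test_single_zero_deviation(self):
        bins = dict(radial_histogram([0.0], n_bins=36))
        assert bins[0.0] == 1 and bins[180.0] == 1
        assert sum(dict(bins).values()) == 2

    def test_negative_deviation_maps_to_opposite_spokes(self):
        bins = dict(radial_histogram([-30.0], n_bins=36))
        assert bins[330.0] == 1 and bins[150.0] == 1

    def test_counts_sum_to_twice_n(self, rng):
        dev = rng.uniform(-90, 90, size=57)
        bins = radial_histogram(dev, n_bins=36)
        assert sum(c for _, c in bins) == 2 * 57

    def test_point_symmetry(self, rng):
        dev = rng.uniform(-90, 90, size=200)
        counts = [c for _, c in radial_histogram(dev, n_bins=24)]
        half = len(counts) // 2
        assert counts[:half] == counts[half:]

    @pytest.mark.parametrize("bad", [0, 7, 100])
    def test_bins_must_divide_360(self, bad):
        with pytest.raises(ValueError):
            radial_histogram([0.0], n_bins=bad)


def test_rotation_equivariance(rng):
    """Adding a constant to all orientations leaves deviations and CV
    unchanged."""
    theta = rng.uniform(-90, 90, size=60)
    base = deviations_from_median(theta)
    for shift in [13.0, 90.0, -41.5]:
        rotated = deviations_from_median(theta + shift)
        assert rotated == pytest.approx(base, abs=1e-9)
        assert alignment_cv(rotated) == pytest.approx(alignment_cv(base), rel=1e-9)


def test_axial_mean_recovers_concentration_direction(rng):
    theta = sample_orientations(2000, kappa=6.0, mu=25.0, rng=rng)
    assert abs(axial_difference(axial_mean(theta), 25.0)) < 3.0


class TestSummaries:
    def test_alignment_summary_invariants(self, rng):
        theta = rng.uniform(-90, 90, size=80)
        s = AlignmentSummary.from_orientations(theta, scope="img1")
        assert s.n_cells == 80
        assert abs(axial_median(s.deviations_deg)) < 1e-9
        assert sum(c for _, c in s.radial_bins) == 160
        assert s.cv >= 0

    def test_elongation_summary_stats(self):
        s = ElongationSummary(scope="cond", values=np.array([1.0, 2.0, 3.0]))
        assert s.n_cells == 3
        assert s.mean == pytest.approx(2.0)
        assert s.median == pytest.approx(2.0)
        assert s.sd == pytest.approx(1.0)
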