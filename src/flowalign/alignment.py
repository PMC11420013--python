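"""Axial orientation statistics: median-centred deviations, radial
histograms, and the alignment coefficient of variation.

A cell's major-axis orientation is *axial* data — defined modulo 180°,
since the axis is undirected.  All arithmetic here therefore wraps
differences into ``(-90, 90]``.  Alignment of a monolayer is quantified
relative to itself: each cell's orientation is re-expressed as its signed
axial deviation from the per-image median orientation (which becomes 0),
and the spread of those deviations summarises how collectively oriented
the cells are.

The coefficient of variation is computed on the deviations shifted by
+90° (so values lie in (0, 180]): CV = sample SD / sample mean of
``d + 90``.  For orientations uniform on the axial range (a fully
unaligned, static-like monolayer) the CV approaches
``sqrt(180**2 / 12) / 90 = 1/sqrt(3) ≈ 0.577``; for a perfectly aligned
monolayer it approaches 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "axial_difference",
    "axial_median",
    "axial_mean",
    "deviations_from_median",
    "alignment_cv",
    "radial_histogram",
    "AlignmentSummary",
    "ElongationSummary",
    "UNIFORM_NULL_CV",
]

#: CV of the alignment statistic under fully unaligned (uniform axial)
#: orientations: sqrt(180^2/12)/90 = 1/sqrt(3).
UNIFORM_NULL_CV = 1.0 / math.sqrt(3.0)


def axial_difference(a: float, b: float) -> float:
    """Signed axial difference ``a - b`` wrapped into ``(-90, 90]``.

    Angles are treated modulo 180° (undirected axes), so e.g.
    ``axial_difference(85, -85) == -10``: the short way around.
    """
    d = (float(a) - float(b) + 90.0) % 180.0 - 90.0
    if d <= -90.0:  # map the closed lower edge to +90
        d += 180.0
    return d


def _wrap_axial(theta: float) -> float:
    """Wrap an angle into the axial range ``(-90, 90]``."""
    return axial_difference(theta, 0.0)


def axial_median(orientations: Sequence[float]) -> float:
    """Axial median: the data value minimising the summed absolute axial
    distance to all orientations.

    Ties are broken by the smallest wrapped angle in ``(-90, 90]``.
    Raises on an empty input.
    """
    theta = np.asarray(orientations, dtype=np.float64)
    if theta.size == 0:
        raise ValueError("axial_median requires at least one orientation")
    wrapped = np.array([_wrap_axial(t) for t in theta])
    candidates = np.unique(wrapped)
    # pairwise axial distances, vectorised wrap
    diff = (wrapped[None, :] - candidates[:, None] + 90.0) % 180.0 - 90.0
    diff[diff <= -90.0] += 180.0
    costs = np.abs(diff).sum(axis=1)
    best = costs.min()
    # tie-break: smallest angle among minimisers (candidates are sorted)
    minimisers = candidates[np.isclose(costs, best, rtol=0.0, atol=1e-9)]
    return float(minimisers[0])


def axial_mean(orientations: Sequence[float]) -> float:
    """Axial circular mean via angle doubling, degrees in ``(-90, 90]``.

    Used mainly to compare a monolayer's collective orientation against a
    known flow direction; undefined (returns 0) for a perfectly balanced
    distribution.
    """
    theta = np.radians(np.asarray(orientations, dtype=np.float64)) * 2.0
    if theta.size == 0:
        raise ValueError("axial_mean requires at least one orientation")
    mean = 0.5 * math.atan2(np.sin(theta).sum(), np.cos(theta).sum())
    return _wrap_axial(math.degrees(mean))


def deviations_from_median(orientations: Sequence[float]) -> np.ndarray:
    """Signed axial deviation of each orientation from the axial median.

    The median itself maps to 0; all deviations lie in ``(-90, 90]``.
    """
    med = axial_median(orientations)
    return np.array([axial_difference(t, med) for t in orientations])


def alignment_cv(deviations: Sequence[float]) -> float:
    """Coefficient of variation of the shifted deviations ``d + 90``.

    Uses the sample (n-1) standard deviation.  Requires at least two
    deviations.  All-equal deviations give 0; uniform axial orientations
    give ≈ :data:`UNIFORM_NULL_CV`.
    """
    d = np.asarray(deviations, dtype=np.float64)
    if d.size < 2:
        raise ValueError("alignment_cv requires at least two deviations")
    shifted = d + 90.0
    mean = shifted.mean()
    sd = shifted.std(ddof=1)
    return float(sd / mean)


def radial_histogram(
    deviations: Sequence[float], n_bins: int = 36
) -> list[tuple[float, int]]:
    """Bin each deviation as a *diameter*: two counts per cell, at
    ``d mod 360`` and ``(d + 180) mod 360``, on ``[0, 360)``.

    Returns ``(bin_start_deg, count)`` pairs; ``n_bins`` must divide 360.
    The histogram is point-symmetric by construction and its counts sum
    to twice the number of cells.
    """
    if n_bins <= 0 or 360 % n_bins != 0:
        raise ValueError(f"n_bins must divide 360, got {n_bins}")
    width = 360.0 / n_bins
    d = np.asarray(deviations, dtype=np.float64)
    angles = np.concatenate([d % 360.0, (d + 180.0) % 360.0])
    idx = np.floor(angles / width).astype(int) % n_bins
    counts = np.bincount(idx, minlength=n_bins)
    return [(i * width, int(c)) for i, c in enumerate(counts)]


@dataclass
class AlignmentSummary:
    """Alignment statistics for one scope (an image or a pooled condition)."""

    scope: str
    n_cells: int
    median_orientation_deg: float
    deviations_deg: np.ndarray
    cv: float
    radial_bins: list[tuple[float, int]]

    @classmethod
    def from_orientations(
        cls,
        orientations: Sequence[float],
        *,
        scope: str = "",
        n_bins: int = 36,
    ) -> "AlignmentSummary":
        """Summarise one image's kept-cell orientations."""
        med = axial_median(orientations)
        dev = deviations_from_median(orientations)
        return cls(
            scope=scope,
            n_cells=len(dev),
            median_orientation_deg=med,
            deviations_deg=dev,
            cv=alignment_cv(dev),
            radial_bins=radial_histogram(dev, n_bins=n_bins),
        )

    @classmethod
    def from_deviations(
        cls,
        deviations: Sequence[float],
        *,
        scope: str = "",
        n_bins: int = 36,
    ) -> "AlignmentSummary":
        """Summarise already-centred deviations (e.g. pooled across images)."""
        dev = np.asarray(deviations, dtype=np.float64)
        return cls(
            scope=scope,
            n_cells=len(dev),
            median_orientation_deg=0.0,
            deviations_deg=dev,
            cv=alignment_cv(dev),
            radial_bins=radial_histogram(dev, n_bins=n_bins),
        )


@dataclass
class ElongationSummary:
    """Elongation-factor distribution for one scope."""

    scope: str
    values: np.ndarray
    mean: float = field(init=False)
    sd: float = field(init=False)
    median: float = field(init=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        self.values = vals
        self.mean = float(vals.mean()) if vals.size else math.nan
        self.sd = float(vals.std(ddof=1)) if vals.size > 1 else math.nan
        self.median = float(np.median(vals)) if vals.size else math.nan

    @property
    def n_cells(self) -> int:
        return int(self.values.size)
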