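"""Per-cell morphometry from pixel second moments.

Each labelled region is summarised by the ellipse sharing its normalized
central second moments: the covariance eigenvalues ``lam1 >= lam2`` give the
equivalent-ellipse axis lengths ``4*sqrt(lam)`` and the elongation factor
``sqrt(lam1/lam2)`` (equivalently major/minor axis length).  Orientation is
the angle of the major axis from the horizontal (x) axis, positive
counter-clockwise, reported in ``(-90, 90]``.

Conventions
-----------
* Moments are taken over pixel centers with no per-pixel variance
  correction, the dominant region-properties convention.  A solid
  5-column-by-3-row rectangle therefore has ``lam1 = 2``, ``lam2 = 2/3``,
  major length ``4*sqrt(2)`` and elongation factor ``sqrt(3)`` exactly.
* Image rows point down; the mixed moment ``mu11`` is computed with
  ``y = -row`` so that a positive orientation is counter-clockwise from the
  horizontal when the image is displayed conventionally.
* Degenerate regions: collinear pixels (``lam2 = 0 < lam1``) get minor
  length 0 and elongation factor ``+inf``; a single pixel
  (``lam1 = lam2 = 0``) gets elongation factor 1 and orientation 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import LabelMask

__all__ = [
    "CellShape",
    "measure_cells",
    "orientation_from_moments",
    "equivalent_ellipse_axes",
    "covariance_eigenvalues",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CellShape:
    """Morphometric record of one segmented cell.

    ``mu20``/``mu02`` are the normalized central second moments along the
    horizontal/vertical axes (pixel² units); ``mu11`` uses the y-up sign
    convention.  ``orientation_deg`` is in ``(-90, 90]`` from the
    horizontal axis, counter-clockwise positive.
    """

    label: int
    area_px: int
    centroid: tuple[float, float]  # (row, col)
    mu20: float
    mu11: float
    mu02: float
    orientation_deg: float
    major_len: float
    minor_len: float
    elongation_factor: float
    touches_border: bool

    def __post_init__(self) -> None:
        if self.area_px < 1:
            raise ValueError("cell area must be >= 1 pixel")


def orientation_from_moments(mu20: float, mu11: float, mu02: float) -> float:
    """Major-axis angle from the horizontal axis, degrees in ``(-90, 90]``.

    Computed as ``0.5 * atan2(2*mu11, mu20 - mu02)``.  An isotropic region
    (``mu11 == 0`` and ``mu20 == mu02``) returns 0 by convention.
    """
    theta = 0.5 * math.degrees(math.atan2(2.0 * mu11, mu20 - mu02))
    # atan2 yields (-180, 180]; the half-angle already lies in (-90, 90].
    if theta <= -90.0:
        theta += 180.0
    return theta


def covariance_eigenvalues(mu20: float, mu11: float, mu02: float) -> tuple[float, float]:
    """Eigenvalues (lam1 >= lam2 >= 0) of the 2x2 moment covariance."""
    mean = 0.5 * (mu20 + mu02)
    half_diff = 0.5 * (mu20 - mu02)
    root = math.hypot(half_diff, mu11)
    lam1 = mean + root
    lam2 = mean - root
    # guard tiny negative round-off on positive semidefinite input
    if lam2 < 0.0:
        if lam2 < -1e-9 * max(lam1, 1.0):
            raise ValueError("moment covariance is not positive semidefinite")
        lam2 = 0.0
    return lam1, lam2


def equivalent_ellipse_axes(lam1: float, lam2: float) -> tuple[float, float]:
    """Full axis lengths ``(4*sqrt(lam1), 4*sqrt(lam2))`` of the ellipse
    with covariance eigenvalues ``lam1 >= lam2 >= 0``."""
    if lam2 < 0 or lam1 < lam2:
        raise ValueError("require lam1 >= lam2 >= 0")
    return 4.0 * math.sqrt(lam1), 4.0 * math.sqrt(lam2)


def _elongation(lam1: float, lam2: float) -> float:
    if lam1 == 0.0:
        return 1.0  # single pixel / fully degenerate: isotropic by convention
    if lam2 == 0.0:
        return math.inf
    return math.sqrt(lam1 / lam2)


def measure_cells(mask: LabelMask | np.ndarray) -> list[CellShape]:
    """Measure every distinct positive label of a mask.

    Returns one :class:`CellShape` per label, in ascending label order.
    A mask without positive labels yields an empty list.  Labels are not
    required to be 4/8-connected; a disconnected label is measured as a
    single region and a warning is logged.
    """
    pixels = mask.pixels if isinstance(mask, LabelMask) else np.asarray(mask)
    if pixels.ndim != 2:
        raise ValueError("mask must be 2-D")
    labels = np.unique(pixels)
    labels = labels[labels > 0]
    if labels.size == 0:
        return []

    nrows, ncols = pixels.shape
    slices = ndimage.find_objects(pixels, max_label=int(labels.max()))
    out: list[CellShape] = []
    for lab in labels:
        sl = slices[int(lab) - 1]
        sub = pixels[sl] == lab
        rr, cc = np.nonzero(sub)
        rows = rr.astype(np.float64) + sl[0].start
        cols = cc.astype(np.float64) + sl[1].start
        n = rows.size
        r0 = rows.mean()
        c0 = cols.mean()
        dx = cols - c0
        dy = -(rows - r0)  # y-up frame
        mu20 = float(dx @ dx) / n
        mu02 = float(dy @ dy) / n
        mu11 = float(dx @ dy) / n
        lam1, lam2 = covariance_eigenvalues(mu20, mu11, mu02)
        major, minor = equivalent_ellipse_axes(lam1, lam2)
        touches = bool(
            rows.min() == 0
            or rows.max() == nrows - 1
            or cols.min() == 0
            or cols.max() == ncols - 1
        )
        if ndimage.label(sub, structure=np.ones((3, 3), dtype=bool))[1] > 1:
            logger.warning("label %d is disconnected; measured as one region", lab)
        out.append(
            CellShape(
                label=int(lab),
                area_px=int(n),
                centroid=(r0, c0),
                mu20=mu20,
                mu11=mu11,
                mu02=mu02,
                orientation_deg=orientation_from_moments(mu20, mu11, mu02),
                major_len=major,
                minor_len=minor,
                elongation_factor=_elongation(lam1, lam2),
                touches_border=touches,
            )
        )
    return out
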