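"""Mask quality control.

Three filters remove false-positive segmentations before any shape
statistics are computed:

* **border** — partial cells touching the image border;
* **too_elongated** — oddly shaped segments with major/minor axis ratio
  strictly greater than ``max_aspect`` (default 10);
* **too_small** — segmentations with area strictly less than
  ``min_area_fraction`` (default 20%) of the largest cell in the image.

The reference area (the largest cell) is computed over *all* measured
cells before any removal, and all three rules are evaluated in a single
pass over the original set, so the outcome does not depend on any rule
ordering.  A cell failing several rules is reported under the first
matching reason in the order border > too_elongated > too_small.
"""

from __future__ import annotations

from dataclasses import dataclass

from .morphometry import CellShape

__all__ = ["QCConfig", "QCResult", "apply_qc", "QC_REASONS"]

QC_REASONS = ("border", "too_elongated", "too_small")


@dataclass(frozen=True)
class QCConfig:
    """Thresholds for the three mask quality filters."""

    min_area_fraction: float = 0.2
    max_aspect: float = 10.0
    remove_border: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_area_fraction < 1.0):
            raise ValueError("min_area_fraction must lie in [0, 1)")
        if self.max_aspect <= 1.0:
            raise ValueError("max_aspect must exceed 1")


@dataclass
class QCResult:
    """Kept/removed partition of one image's cells with removal reasons."""

    kept: list[CellShape]
    removed: list[tuple[CellShape, str]]
    reference_area: int

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.removed)

    def reason_counts(self) -> dict[str, int]:
        counts = {r: 0 for r in QC_REASONS}
        for _, reason in self.removed:
            counts[reason] += 1
        return counts


def apply_qc(cells: list[CellShape], config: QCConfig | None = None) -> QCResult:
    """Partition measured cells of one image into kept and removed.

    An empty input yields an empty result with ``reference_area`` 0.
    Both thresholds are strict: area exactly at ``min_area_fraction`` of the
    reference is kept, and elongation factor exactly equal to ``max_aspect``
    is kept.
    """
    if config is None:
        config = QCConfig()
    if not cells:
        return QCResult(kept=[], removed=[], reference_area=0)

    reference_area = max(c.area_px for c in cells)
    area_floor = config.min_area_fraction * reference_area
    kept: list[CellShape] = []
    removed: list[tuple[CellShape, str]] = []
    for cell in cells:
        if config.remove_border and cell.touches_border:
            removed.append((cell, "border"))
        elif cell.elongation_factor > config.max_aspect:
            removed.append((cell, "too_elongated"))
        elif cell.area_px < area_floor:
            removed.append((cell, "too_small"))
        else:
            kept.append(cell)
    return QCResult(kept=kept, removed=removed, reference_area=reference_area)
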