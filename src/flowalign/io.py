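"""Reading and writing of label masks, study manifests and per-cell tables.

A *label mask* is a 2-D integer image in which 0 is background and each
positive integer identifies one segmented cell instance, as produced by any
instance segmenter.  Masks are grouped into a study by a plain-text
comma-separated *manifest* listing, per image, the mask path, the
experimental condition, the replicate, and the flow-direction angle.

TIFF (8/16/32-bit unsigned integer, single channel) is the canonical mask
container; PNG is accepted for masks with few labels (8-bit up to 255
labels, 16-bit up to 65535).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "LabelMask",
    "Manifest",
    "ManifestRow",
    "read_label_mask",
    "write_label_mask",
    "load_manifest",
    "write_cells_table",
    "read_cells_table",
    "CELLS_TABLE_COLUMNS",
]


def _check_flow_angle(angle: float) -> float:
    angle = float(angle)
    if not (-90.0 < angle <= 90.0):
        raise ValueError(
            f"flow_angle_deg must lie in (-90, 90], got {angle!r}"
        )
    return angle


@dataclass
class LabelMask:
    """A 2-D integer label image plus its study metadata.

    Parameters
    ----------
    pixels
        2-D array of non-negative integers; 0 is background, each positive
        value labels one cell.
    image_id
        Identifier for the image (defaults to the file stem on read).
    condition, replicate
        Experimental grouping labels.
    flow_angle_deg
        Direction of applied flow, degrees from the horizontal (x) axis,
        in (-90, 90].  0 means flow along the image's horizontal axis.
    """

    pixels: np.ndarray
    image_id: str = ""
    condition: str = ""
    replicate: str = ""
    flow_angle_deg: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(
                f"label mask must be a single-channel 2-D image, got shape {arr.shape}"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError(
                f"label mask must have an integer pixel type, got {arr.dtype}"
            )
        if arr.size and arr.min() < 0:
            raise ValueError("label mask contains negative pixel values")
        self.pixels = arr
        self.flow_angle_deg = _check_flow_angle(self.flow_angle_deg)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def labels(self) -> np.ndarray:
        """Sorted array of distinct positive labels present in the mask."""
        vals = np.unique(self.pixels)
        return vals[vals > 0]

    @property
    def n_cells(self) -> int:
        return int(self.labels.size)


@dataclass(frozen=True)
class ManifestRow:
    mask_path: Path
    condition: str
    replicate: str
    flow_angle_deg: float = 0.0


@dataclass
class Manifest:
    """Ordered collection of mask records defining one study."""

    rows: list[ManifestRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    @property
    def conditions(self) -> list[str]:
        """Distinct conditions in first-appearance order."""
        seen: dict[str, None] = {}
        for row in self.rows:
            seen.setdefault(row.condition, None)
        return list(seen)


def read_label_mask(
    path: str | Path,
    *,
    image_id: str | None = None,
    condition: str = "",
    replicate: str = "",
    flow_angle_deg: float = 0.0,
) -> LabelMask:
    """Read a single-channel integer TIFF or PNG label mask.

    Pixel values are preserved bit-exactly.  Multi-channel (RGB) images and
    floating-point pixel types are rejected: a label mask is categorical
    data and any conversion would corrupt labels silently.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label mask not found: {path}")
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(
            f"{path.name}: expected a single-channel 2-D label image, "
            f"got shape {arr.shape} (multi-channel masks are not label masks)"
        )
    if np.issubdtype(arr.dtype, np.floating):
        raise ValueError(
            f"{path.name}: floating-point pixel type {arr.dtype} is not a "
            "valid label image; labels must be integers"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path.name}: unsupported pixel type {arr.dtype}")
    if arr.size and arr.min() < 0:
        raise ValueError(f"{path.name}: negative pixel values are not valid labels")
    return LabelMask(
        pixels=arr,
        image_id=image_id if image_id is not None else path.stem,
        condition=condition,
        replicate=replicate,
        flow_angle_deg=flow_angle_deg,
    )


def write_label_mask(mask: LabelMask | np.ndarray, path: str | Path) -> None:
    """Write a label mask as TIFF (canonical) or PNG.

    The narrowest unsigned dtype that holds the maximum label is chosen.
    PNG supports at most 16-bit labels; requesting a PNG for labels above
    65535 (or above 255 when an 8-bit array is forced) raises with advice
    to use a 16-bit container.
    """
    arr = mask.pixels if isinstance(mask, LabelMask) else np.asarray(mask)
    if arr.size and arr.min() < 0:
        raise ValueError("negative labels cannot be serialized")
    path = Path(path)
    maxlab = int(arr.max()) if arr.size else 0
    if maxlab <= 0xFF:
        out = arr.astype(np.uint8)
    elif maxlab <= 0xFFFF:
        out = arr.astype(np.uint16)
    else:
        out = arr.astype(np.uint32)
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        tifffile.imwrite(path, out)
    elif suffix == ".png":
        # PNG is supported for small label counts only; TIFF is canonical
        if maxlab > 0xFF:
            raise ValueError(
                f"label {maxlab} exceeds the 8-bit PNG label budget; "
                "use a 16-bit TIFF container instead"
            )
        iio.imwrite(path, out)
    else:
        raise ValueError(f"unsupported mask container {path.suffix!r}; use .tif or .png")


def load_manifest(path: str | Path) -> Manifest:
    """Load a comma-separated study manifest.

    Expected header columns: ``mask_path, condition, replicate,
    flow_angle_deg`` — the last is optional and defaults to 0.  Relative
    mask paths are resolved against the manifest's own directory.  Lines
    starting with ``#`` are comments.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    base = path.parent
    rows: list[ManifestRow] = []
    seen_paths: set[Path] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        lines = [ln for ln in fh if not ln.lstrip().startswith("#")]
    reader = csv.DictReader(lines)
    if reader.fieldnames is None:
        raise ValueError(f"{path}: empty manifest")
    fields = [f.strip() for f in reader.fieldnames]
    required = {"mask_path", "condition", "replicate"}
    missing = required - set(fields)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    for i, rec in enumerate(reader, start=1):
        rec = {(k or "").strip(): (v or "").strip() for k, v in rec.items()}
        mask_path = Path(rec["mask_path"])
        if not mask_path.is_absolute():
            mask_path = (base / mask_path).resolve()
        if mask_path in seen_paths:
            raise ValueError(f"{path}: duplicate mask_path {rec['mask_path']!r} (row {i})")
        seen_paths.add(mask_path)
        if not mask_path.exists():
            raise FileNotFoundError(
                f"{path}: row {i} references nonexistent mask {rec['mask_path']!r}"
            )
        condition = rec["condition"]
        if not condition:
            raise ValueError(f"{path}: row {i} has an empty condition")
        angle_text = rec.get("flow_angle_deg", "")
        angle = float(angle_text) if angle_text else 0.0
        rows.append(
            ManifestRow(
                mask_path=mask_path,
                condition=condition,
                replicate=rec["replicate"],
                flow_angle_deg=_check_flow_angle(angle),
            )
        )
    return Manifest(rows=rows)


#: Fixed column order of the per-cell output table.
CELLS_TABLE_COLUMNS = [
    "image_id",
    "condition",
    "replicate",
    "label",
    "area_px",
    "centroid_row",
    "centroid_col",
    "orientation_deg",
    "major_len",
    "minor_len",
    "elongation_factor",
    "touches_border",
    "qc_kept",
    "qc_reason",
]


def _fmt(value) -> str:
    if isinstance(value, bool) or isinstance(value, np.bool_):
        return "True" if value else "False"
    if isinstance(value, (float, np.floating)):
        return repr(float(value))  # shortest round-trip form, >= 9 sig digits
    return str(value)


def write_cells_table(records: Iterable[dict], path: str | Path) -> None:
    """Write per-cell records (dicts keyed by :data:`CELLS_TABLE_COLUMNS`)
    as a comma-separated table with the fixed documented column order.

    Floats are serialized in round-trip (repr) form so a read-back
    reproduces them exactly.
    """
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CELLS_TABLE_COLUMNS)
        for rec in records:
            writer.writerow([_fmt(rec.get(col, "")) for col in CELLS_TABLE_COLUMNS])


def read_cells_table(path: str | Path):
    """Read back a cells table written by :func:`write_cells_table` as a
    :class:`pandas.DataFrame`."""
    import pandas as pd

    return pd.read_csv(path, dtype={"condition": str, "replicate": str, "image_id": str})
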