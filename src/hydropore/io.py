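"""Micrograph and result-table I/O with physical calibration.

Conventions used throughout the package:

* images are 2D ``float64`` arrays with intensities in the nominal range
  0–255, indexed ``(row, col)``, 0-based, origin at the top-left corner,
  rows increasing downward;
* binary masks are 2D ``bool`` arrays, ``True`` = foreground;
* label maps are 2D non-negative ``int`` arrays, 0 = background and
  1..N = distinct objects.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .features import PoreRecord

__all__ = [
    "Calibration",
    "read_image",
    "write_image",
    "write_mask",
    "write_labels",
    "write_records",
    "read_records",
    "RECORD_COLUMNS",
]

# Rec. 601 luma weights, used when RGB channels genuinely differ.
_LUMA = np.array([0.299, 0.587, 0.114])

RECORD_COLUMNS = (
    "pore_id",
    "centroid_row_px",
    "centroid_col_px",
    "area_px2",
    "area_um2",
    "equiv_diameter_um",
)


@dataclasses.dataclass(frozen=True)
class Calibration:
    """Physical pixel size of a micrograph.

    Parameters
    ----------
    microns_per_pixel : float
        Edge length of one pixel in micrometres. Must be strictly
        positive. Supplied by the user (e.g. from the microscope
        metadata); the package never infers it from scale bars.
    """

    microns_per_pixel: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.microns_per_pixel) or self.microns_per_pixel <= 0:
            raise ValueError(
                f"microns_per_pixel must be finite and > 0, "
                f"got {self.microns_per_pixel!r}"
            )

    @property
    def um2_per_px2(self) -> float:
        """Area of one pixel in µm²."""
        return self.microns_per_pixel**2


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF/PNG micrograph as a float grayscale image in [0, 255].

    RGB inputs with identical channels collapse to that channel; channels
    that differ are combined by Rec. 601 luminance. 16-bit data are
    rescaled linearly so that 65535 maps to 255. An alpha channel, if
    present, is discarded.

    Raises
    ------
    OSError
        If the file cannot be read or decoded.
    ValueError
        If the decoded image has a zero-sized dimension.
    """
    path = Path(path)
    raw = iio.imread(path)
    src_dtype = raw.dtype
    if raw.ndim == 3:
        if raw.shape[2] >= 4:
            raw = raw[:, :, :3]
        chans = raw.astype(np.float64)
        if np.all(chans == chans[:, :, :1]):
            arr = chans[:, :, 0]
        else:
            arr = chans @ _LUMA
    else:
        arr = np.asarray(raw, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0 or min(arr.shape) < 1:
        raise ValueError(f"{path}: expected a non-empty 2D image, got shape {arr.shape}")
    if src_dtype == np.uint16:
        arr = arr * (255.0 / 65535.0)
    elif src_dtype in (np.float32, np.float64):
        arr = np.clip(arr, 0.0, 255.0)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{path}: image contains non-finite intensities")
    return arr


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a grayscale image as 8-bit PNG/TIFF (values clipped to [0, 255])."""
    out = np.clip(np.asarray(image, dtype=np.float64), 0, 255)
    iio.imwrite(Path(path), np.round(out).astype(np.uint8))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit PNG (foreground 255, background 0)."""
    iio.imwrite(Path(path), np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    """Write a label map as 16-bit PNG."""
    lab = np.asarray(labels)
    if lab.min() < 0 or lab.max() > np.iinfo(np.uint16).max:
        raise ValueError("label values outside the uint16 range")
    iio.imwrite(Path(path), lab.astype(np.uint16))


def _records_frame(records: Iterable["PoreRecord"]) -> pd.DataFrame:
    rows = [
        (
            r.pore_id,
            r.centroid_row_px,
            r.centroid_col_px,
            r.area_px2,
            r.area_um2,
            r.equiv_diameter_um,
        )
        for r in records
    ]
    df = pd.DataFrame(rows, columns=list(RECORD_COLUMNS))
    return df.sort_values("pore_id").reset_index(drop=True)


def write_records(records: Sequence["PoreRecord"], path: str | Path) -> None:
    """Export pore records to a UTF-8 tab-separated table.

    Rows are ordered by ``pore_id``. Floats are written with 10
    significant digits so that re-parsing reproduces the values to well
    beyond 6 significant digits.
    """
    df = _records_frame(records)
    df.to_csv(Path(path), sep="\t", index=False, float_format="%.10g", encoding="utf-8")


def read_records(path: str | Path) -> list["PoreRecord"]:
    """Parse a table written by :func:`write_records` back into records."""
    from .features import PoreRecord

    df = pd.read_csv(Path(path), sep="\t")
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        PoreRecord(
            pore_id=int(row.pore_id),
            centroid_row_px=float(row.centroid_row_px),
            centroid_col_px=float(row.centroid_col_px),
            area_px2=int(row.area_px2),
            area_um2=float(row.area_um2),
            equiv_diameter_um=float(row.equiv_diameter_um),
        )
        for row in df.itertuples(index=False)
    ]
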