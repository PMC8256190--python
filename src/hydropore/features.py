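"""Per-pore measurements from a label map, in pixels and micrometres."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage

from .io import Calibration

__all__ = ["PoreRecord", "PoreSummary", "measure_pores", "summarize"]


@dataclasses.dataclass(frozen=True)
class PoreRecord:
    """One detected pore.

    ``centroid_*`` is the geometric centre of mass (unweighted mean of
    member pixel coordinates); ``equiv_diameter_um`` is the diameter of
    the circle with the same area, d = 2*sqrt(A/pi).
    """

    pore_id: int
    centroid_row_px: float
    centroid_col_px: float
    area_px2: int
    area_um2: float
    equiv_diameter_um: float


@dataclasses.dataclass(frozen=True)
class PoreSummary:
    """Count and equivalent-diameter statistics of a set of pores (µm)."""

    count: int
    mean_equiv_diameter_um: float | None
    median_equiv_diameter_um: float | None
    min_equiv_diameter_um: float | None
    max_equiv_diameter_um: float | None


def equiv_diameter(area: float) -> float:
    """Diameter of the circle of equal area."""
    return 2.0 * math.sqrt(area / math.pi)


def measure_pores(labels: np.ndarray, cal: Calibration) -> list[PoreRecord]:
    """Measure centroid, area and equivalent diameter of every label.

    Records come back sorted by ``pore_id`` (= label value). An empty
    label map yields an empty list.
    """
    labels = np.asarray(labels)
    n = int(labels.max())
    if n == 0:
        return []
    ids = np.arange(1, n + 1)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=ids)
    centroids = ndimage.center_of_mass(np.ones_like(labels, float), labels, index=ids)
    px2um2 = cal.um2_per_px2
    records = []
    for pid, area, (cr, cc) in zip(ids, areas, centroids):
        if area == 0:
            continue  # tolerate gaps in label numbering
        a_um2 = float(area) * px2um2
        records.append(
            PoreRecord(
                pore_id=int(pid),
                centroid_row_px=float(cr),
                centroid_col_px=float(cc),
                area_px2=int(round(float(area))),
                area_um2=a_um2,
                equiv_diameter_um=equiv_diameter(a_um2),
            )
        )
    return records


def summarize(records: list[PoreRecord]) -> PoreSummary:
    """Count and mean/median/min/max of the equivalent diameters."""
    if not records:
        return PoreSummary(0, None, None, None, None)
    d = np.array([r.equiv_diameter_um for r in records])
    return PoreSummary(
        count=len(records),
        mean_equiv_diameter_um=float(d.mean()),
        median_equiv_diameter_um=float(np.median(d)),
        min_equiv_diameter_um=float(d.min()),
        max_equiv_diameter_um=float(d.max()),
    )
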