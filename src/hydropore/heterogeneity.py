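"""Spatial-heterogeneity analysis of detected pores.

Pore placement in a hydrogel is rarely uniform: small pores often
cluster where the polymer network is denser. Beyond the pore-size
histogram, the module quantifies this with a bivariate Gaussian kernel
density estimate (KDE) fitted to the pore centres of mass: a high
density marks a region packed with many pores per unit area, a low
density a sparse region or one covered by few large pores. The fitted
field supports contour maps and per-pore density readouts (dot plots).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from skimage import measure as _skmeasure

from .features import PoreRecord

__all__ = [
    "KDEField",
    "pore_size_histogram",
    "scott_bandwidth",
    "silverman_bandwidth",
    "fit_kde",
    "density_at_points",
    "contour_map",
]


@dataclasses.dataclass
class KDEField:
    """Evaluated 2D kernel density surface over image coordinates.

    ``grid_density[i, j]`` is the density (per px²) at
    ``(row_coords[i], col_coords[j])``; the grid covers the image extent
    padded by three bandwidths on each side so the estimate integrates
    to ~1 over the grid.
    """

    grid_density: np.ndarray
    bandwidth: np.ndarray  # (bw_row, bw_col) in px
    grid_spacing: float  # px per grid cell
    row_coords: np.ndarray
    col_coords: np.ndarray

    def integral(self) -> float:
        """Riemann sum of density × cell area over the grid."""
        return float(self.grid_density.sum() * self.grid_spacing**2)

    def argmax(self) -> tuple[float, float]:
        """(row, col) pixel coordinates of the density maximum."""
        i, j = np.unravel_index(int(np.argmax(self.grid_density)),
                                self.grid_density.shape)
        return float(self.row_coords[i]), float(self.col_coords[j])


def pore_size_histogram(
    records: Sequence[PoreRecord], bin_width: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of equivalent diameters with fixed-width bins from 0.

    Returns ``(edges, counts)`` with bins ``[k*w, (k+1)*w)`` covering
    ``[0, max + w)``; the counts always sum to the number of records.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if not records:
        return np.array([0.0]), np.array([], dtype=int)
    d = np.array([r.equiv_diameter_um for r in records])
    n_bins = int(np.floor(d.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.histogram(d, bins=edges)[0]
    return edges, counts


def scott_bandwidth(points: np.ndarray) -> np.ndarray:
    """Scott's rule per axis for 2D data: n^(-1/6) * std(axis)."""
    n = points.shape[0]
    sd = points.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero variance along an axis: data-driven bandwidth undefined")
    return n ** (-1.0 / 6.0) * sd


def silverman_bandwidth(points: np.ndarray) -> np.ndarray:
    """Silverman's rule per axis for 2D data: (n*(d+2)/4)^(-1/(d+4)) * std."""
    n = points.shape[0]
    sd = points.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero variance along an axis: data-driven bandwidth undefined")
    return (n * (2 + 2) / 4.0) ** (-1.0 / 6.0) * sd


def fit_kde(
    centroids: Sequence[tuple[float, float]] | np.ndarray,
    bandwidth_rule: str = "scott",
    fixed_bw: float | tuple[float, float] | None = None,
    grid_spacing: float | None = None,
    extent: tuple[float, float, float, float] | None = None,
) -> KDEField:
    """Fit a bivariate Gaussian product-kernel density to pore centres.

    Parameters
    ----------
    centroids : sequence of (row, col)
        Pore centres of mass, in pixels.
    bandwidth_rule : {"scott", "silverman", "fixed"}
        Per-axis bandwidth selection; ``fixed`` uses ``fixed_bw``.
    fixed_bw : float or (bw_row, bw_col)
        Bandwidth in px when ``bandwidth_rule == "fixed"``.
    grid_spacing : float, optional
        Grid step in px; defaults to max(1, image_width/256) where the
        image width is taken from ``extent`` (or the centroid spread).
    extent : (row_min, row_max, col_min, col_max), optional
        Image extent to cover; defaults to the centroid bounding box.
        The evaluation grid pads this by 3 bandwidths per side.

    The estimate is ``f(x) = (1/n) * sum_i K_hr(r - ri) K_hc(c - ci)``
    with 1D Gaussian kernels, so it integrates to 1 over the plane.
    """
    pts = np.asarray(centroids, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
        raise ValueError("centroids must be an (n, 2) array with n >= 1")
    if bandwidth_rule == "fixed":
        if fixed_bw is None:
            raise ValueError("fixed bandwidth rule requires fixed_bw")
        bw = np.broadcast_to(np.asarray(fixed_bw, float), (2,)).copy()
    elif bandwidth_rule == "scott":
        if pts.shape[0] < 2:
            raise ValueError("data-driven bandwidth needs >= 2 points")
        bw = scott_bandwidth(pts)
    elif bandwidth_rule == "silverman":
        if pts.shape[0] < 2:
            raise ValueError("data-driven bandwidth needs >= 2 points")
        bw = silverman_bandwidth(pts)
    else:
        raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")
    if np.any(bw <= 0):
        raise ValueError("bandwidth must be positive")

    if extent is None:
        extent = (pts[:, 0].min(), pts[:, 0].max(), pts[:, 1].min(), pts[:, 1].max())
    r0, r1, c0, c1 = map(float, extent)
    if grid_spacing is None:
        grid_spacing = max(1.0, (c1 - c0) / 256.0)
    pad = 3.0 * bw
    rows = np.arange(r0 - pad[0], r1 + pad[0] + grid_spacing, grid_spacing)
    cols = np.arange(c0 - pad[1], c1 + pad[1] + grid_spacing, grid_spacing)

    # product kernel, evaluated separably: (n_rows, n) and (n_cols, n)
    kr = np.exp(-0.5 * ((rows[:, None] - pts[None, :, 0]) / bw[0]) ** 2)
    kr /= bw[0] * np.sqrt(2 * np.pi)
    kc = np.exp(-0.5 * ((cols[:, None] - pts[None, :, 1]) / bw[1]) ** 2)
    kc /= bw[1] * np.sqrt(2 * np.pi)
    density = (kr @ kc.T) / pts.shape[0]
    return KDEField(
        grid_density=density,
        bandwidth=bw,
        grid_spacing=float(grid_spacing),
        row_coords=rows,
        col_coords=cols,
    )


def density_at_points(
    field: KDEField, points: Sequence[tuple[float, float]] | np.ndarray
) -> np.ndarray:
    """Bilinear interpolation of the density surface at pixel points.

    Raises if any point lies outside the padded grid.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    interp = RegularGridInterpolator(
        (field.row_coords, field.col_coords),
        field.grid_density,
        method="linear",
        bounds_error=True,
    )
    try:
        return interp(pts)
    except ValueError as err:
        raise ValueError(f"point outside the KDE grid: {err}") from err


def contour_map(
    field: KDEField, n_levels: int = 8
) -> list[tuple[float, list[np.ndarray]]]:
    """Iso-density contours of the field, in image pixel coordinates.

    Levels are ``n_levels`` values equally spaced strictly between the
    grid minimum and maximum. Each entry is ``(level, polylines)`` where
    every polyline is an (m, 2) array of (row, col) points. A constant
    field has no contours and triggers a warning.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    lo, hi = float(field.grid_density.min()), float(field.grid_density.max())
    if hi == lo:
        warnings.warn("constant density field: no contours")
        return []
    levels = np.linspace(lo, hi, n_levels + 2)[1:-1]
    out: list[tuple[float, list[np.ndarray]]] = []
    r0, c0, s = field.row_coords[0], field.col_coords[0], field.grid_spacing
    for lev in levels:
        polys = [
            np.column_stack([r0 + p[:, 0] * s, c0 + p[:, 1] * s])
            for p in _skmeasure.find_contours(field.grid_density, lev)
        ]
        out.append((float(lev), polys))
    return out
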