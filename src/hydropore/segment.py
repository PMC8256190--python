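"""Binarisation, morphological cleaning and watershed splitting.

The stage order used by the pipeline is: threshold -> border clearing ->
erosion -> opening -> hole filling -> morphological reconstruction ->
distance-transform watershed. Foreground is always ``True`` in the
boolean masks; whether foreground means pores or walls is decided by the
pipeline mode (walls are obtained by inverting the pore mask).

Morphological operations use the 3×3 elliptical structuring element,
whose discretisation on a 3×3 grid is the cross (centre plus the four
edge neighbours). Pixels outside the image are treated as background.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage.morphology import h_maxima
from skimage.segmentation import watershed as _skimage_watershed

from .preprocess import gaussian_kernel_1d

__all__ = [
    "SegmentParams",
    "CROSS",
    "structure_for_connectivity",
    "adaptive_gaussian_threshold",
    "otsu_threshold",
    "invert_foreground",
    "clear_border",
    "erode",
    "binary_open",
    "fill_holes",
    "reconstruct",
    "watershed_split",
]

#: 3×3 elliptical structuring element (cross: centre + 4-neighbours).
CROSS = ndimage.generate_binary_structure(2, 1)


@dataclasses.dataclass
class SegmentParams:
    """Parameters of the threshold/morphology/watershed stages.

    ``offset_c`` is the constant subtracted from the Gaussian-weighted
    local mean before comparison; a small positive value suppresses
    speckle in flat regions. ``watershed_max_threshold`` sets the
    dynamics cut for watershed markers as a fraction of the
    distance-transform maximum (see :func:`watershed_split`).
    """

    threshold_method: str = "adaptive_gaussian"
    window: int = 25
    offset_c: float = 10.0
    erosion_iters: int = 1
    opening_iters: int = 5
    watershed_max_threshold: float = 0.05
    connectivity: int = 8
    min_area_px: int = 0

    def validate(self) -> None:
        if self.threshold_method not in ("adaptive_gaussian", "otsu"):
            raise ValueError("threshold_method must be 'adaptive_gaussian' or 'otsu'")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if not 0 < self.watershed_max_threshold < 1:
            raise ValueError("watershed_max_threshold must be in (0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.erosion_iters < 0 or self.opening_iters < 0:
            raise ValueError("iteration counts must be >= 0")


def structure_for_connectivity(connectivity: int) -> np.ndarray:
    """3×3 neighbourhood structure for 4- or 8-connectivity."""
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ValueError("connectivity must be 4 or 8")


def adaptive_threshold_sigma(window: int) -> float:
    """Default Gaussian width for a given window, sigma = 0.3((w-1)/2 - 1) + 0.8.

    This is the conventional size-to-sigma rule used by mainstream
    imaging libraries for Gaussian-weighted adaptive thresholding, so a
    25×25 window reproduces the customary weighting.
    """
    return 0.3 * ((window - 1) * 0.5 - 1.0) + 0.8


def local_gaussian_mean(
    img: np.ndarray, window: int, sigma: float | None = None
) -> np.ndarray:
    """Gaussian-weighted mean of each pixel's window, edge replicated."""
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if min(img.shape) < window:
        raise ValueError(
            f"window {window} larger than image of shape {img.shape}"
        )
    if sigma is None:
        sigma = adaptive_threshold_sigma(window)
    k1 = gaussian_kernel_1d(sigma, window)
    out = ndimage.correlate1d(np.asarray(img, float), k1, axis=0, mode="nearest")
    return ndimage.correlate1d(out, k1, axis=1, mode="nearest")


def adaptive_gaussian_threshold(
    img: np.ndarray, window: int = 25, offset_c: float = 10.0,
    sigma: float | None = None,
) -> np.ndarray:
    """Local threshold against the Gaussian-weighted window mean.

    A pixel is foreground iff its intensity exceeds the
    Gaussian-weighted mean of its ``window``×``window`` neighbourhood
    minus ``offset_c``. Because the reference level moves with the local
    neighbourhood, the decision is insensitive to slow illumination
    drift across the field of view — the reason this thresholding is
    preferred over a single global cut for SEM micrographs.
    """
    img = np.asarray(img, dtype=np.float64)
    return img > local_gaussian_mean(img, window, sigma) - offset_c


def otsu_threshold(img: np.ndarray, return_threshold: bool = False):
    """Global threshold maximising between-class variance over 256 bins.

    Intensities are quantised to the 0–255 integer grid; the returned
    mask is ``img > t`` for the argmax threshold ``t`` (first argmax on
    ties). Raises on a constant image, which has no two classes.
    """
    img = np.asarray(img, dtype=np.float64)
    q = np.clip(np.round(img), 0, 255).astype(np.int64)
    if q.min() == q.max():
        raise ValueError("constant image: Otsu threshold undefined")
    hist = np.bincount(q.ravel(), minlength=256).astype(np.float64)
    p = hist / hist.sum()
    omega = np.cumsum(p)                      # P(class0) for t = 0..255
    mu = np.cumsum(p * np.arange(256))        # first moment of class0
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = 0.0
    t = int(np.argmax(sigma_b))
    mask = img > t
    return (mask, t) if return_threshold else mask


def invert_foreground(mask: np.ndarray) -> np.ndarray:
    """Logical complement; swaps the roles of pores and walls."""
    return ~np.asarray(mask, dtype=bool)


def clear_border(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Remove every foreground component that touches the image border."""
    mask = np.asarray(mask, dtype=bool)
    labels, _ = ndimage.label(mask, structure=structure_for_connectivity(connectivity))
    border = np.concatenate(
        [labels[0], labels[-1], labels[:, 0], labels[:, -1]]
    )
    bad = np.unique(border[border > 0])
    if bad.size == 0:
        return mask.copy()
    return mask & ~np.isin(labels, bad)


def erode(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Binary erosion by the 3×3 elliptical (cross) element."""
    mask = np.asarray(mask, dtype=bool)
    if iterations == 0:
        return mask.copy()
    return ndimage.binary_erosion(mask, structure=CROSS, iterations=iterations)


def binary_open(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Opening (erosion then dilation) by the cross element, iterated as a unit.

    Each iteration applies one erosion followed by one dilation; since
    opening is idempotent, iterating the unit changes nothing beyond the
    first pass, which is exactly the small-speckle removal intended.
    """
    mask = np.asarray(mask, dtype=bool)
    out = mask.copy()
    for _ in range(iterations):
        out = ndimage.binary_dilation(
            ndimage.binary_erosion(out, structure=CROSS), structure=CROSS
        )
    return out


def fill_holes(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Fill background regions not connected to the border.

    The background is traversed with the connectivity complementary to
    the foreground's (4-connected background for 8-connected
    foreground), avoiding the digital-topology paradox on complementary
    masks.
    """
    comp_conn = 4 if connectivity == 8 else 8
    return ndimage.binary_fill_holes(
        np.asarray(mask, dtype=bool),
        structure=structure_for_connectivity(comp_conn),
    )


def reconstruct(
    marker: np.ndarray, reference: np.ndarray, connectivity: int = 8
) -> np.ndarray:
    """Morphological reconstruction by dilation of ``marker`` under ``reference``.

    Returns the union of the connected components of ``reference`` that
    intersect ``marker`` (the marker is intersected with the reference
    first, so any marker pixels outside the reference are ignored).
    Used to restore the full shapes of pores that survived the
    erosion/opening cleaning.
    """
    marker = np.asarray(marker, dtype=bool) & np.asarray(reference, dtype=bool)
    labels, _ = ndimage.label(
        reference, structure=structure_for_connectivity(connectivity)
    )
    keep = np.unique(labels[marker])
    keep = keep[keep > 0]
    return np.isin(labels, keep)


def watershed_split(
    mask: np.ndarray, max_threshold: float = 0.05, connectivity: int = 8
) -> np.ndarray:
    """Split touching pores with a marker-controlled distance watershed.

    The Euclidean distance transform D of the foreground is treated as a
    topographic relief. Markers are the maxima of D whose dynamics
    (height above the saddle separating them from a higher maximum)
    exceed ``max_threshold * max(D)``: two fused pores produce two deep
    maxima separated by a shallow saddle at the neck, while the small
    spurious maxima of a single rough pore fall below the cut. The
    watershed of -D restricted to the mask then assigns every foreground
    pixel to exactly one marker; any component left without a marker
    keeps a single label of its own. Labels are renumbered 1..N.
    """
    if not 0 < max_threshold < 1:
        raise ValueError("max_threshold must be in (0, 1)")
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    if not mask.any():
        return labels
    structure = structure_for_connectivity(connectivity)
    dist = ndimage.distance_transform_edt(mask)
    h = max_threshold * float(dist.max())
    peaks = h_maxima(dist, h) if h > 0 else dist == dist.max()
    peaks &= mask
    markers, _ = ndimage.label(peaks, structure=structure)
    skim_conn = 2 if connectivity == 8 else 1
    labels = _skimage_watershed(
        -dist, markers=markers, mask=mask, connectivity=skim_conn
    ).astype(np.int32)
    # Components with no surviving maximum (possible for very flat or
    # tiny blobs) still deserve one label each.
    leftover = mask & (labels == 0)
    if leftover.any():
        extra, n_extra = ndimage.label(leftover, structure=structure)
        labels = np.where(leftover, extra + labels.max(), labels)
    # renumber contiguously
    vals = np.unique(labels)
    vals = vals[vals > 0]
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[vals] = np.arange(1, vals.size + 1, dtype=np.int32)
    return lut[labels]
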