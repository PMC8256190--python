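"""Pre-processing chain for porous-network micrographs.

Contrast normalisation, Gaussian denoising, edge emphasis and
frequency-domain band-pass filtering. All spatial convolutions use edge
replication at the borders so that no dark halo is introduced there
(border-touching pores are discarded later anyway, but a halo would also
bias their neighbours).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage

__all__ = [
    "PreprocessParams",
    "normalize_contrast",
    "gaussian_kernel_1d",
    "gaussian_smooth",
    "edge_emphasis",
    "bandpass_filter",
    "run_chain",
]

EDGE_OPERATORS = ("sobel", "scharr", "laplacian")


@dataclasses.dataclass
class PreprocessParams:
    """Parameters of the pre-processing chain.

    Attributes
    ----------
    gaussian_sigma : float
        Standard deviation of the denoising Gaussian, in pixels.
    gaussian_kernel : int
        Side of the (odd) truncated Gaussian kernel, in pixels.
    edge_operator : str
        One of ``sobel`` (default), ``scharr``, ``laplacian``.
    bandpass_low_frac, bandpass_high_frac : float
        Radial cut-off frequencies of the annular pass band as fractions
        of the Nyquist radius (half the smaller image dimension in
        frequency-index units). The low cut removes slow illumination
        drift; the high cut removes pixel-scale noise.
    bandpass_taper : float
        Standard deviation (in fractions of the Nyquist radius) of an
        optional Gaussian taper applied to the annulus edges to suppress
        ringing; 0 gives the hard (ideal) annulus.
    """

    gaussian_sigma: float = 0.7
    gaussian_kernel: int = 3
    edge_operator: str = "sobel"
    bandpass_low_frac: float = 0.05
    bandpass_high_frac: float = 0.6
    bandpass_taper: float = 0.0

    def validate(self) -> None:
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be > 0")
        if self.gaussian_kernel < 3 or self.gaussian_kernel % 2 == 0:
            raise ValueError("gaussian_kernel must be odd and >= 3")
        if self.edge_operator not in EDGE_OPERATORS:
            raise ValueError(f"edge_operator must be one of {EDGE_OPERATORS}")
        if not 0 < self.bandpass_low_frac < self.bandpass_high_frac <= 1:
            raise ValueError("need 0 < bandpass_low_frac < bandpass_high_frac <= 1")
        if self.bandpass_taper < 0:
            raise ValueError("bandpass_taper must be >= 0")


def _rescale_255(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        warnings.warn("constant image: no contrast to stretch, returning zeros")
        return np.zeros_like(img, dtype=np.float64)
    return (img - lo) * (255.0 / (hi - lo))


def normalize_contrast(img: np.ndarray) -> np.ndarray:
    """Stretch the gray-level histogram linearly onto [0, 255].

    A constant image has no contrast to stretch; it maps to all zeros
    and a warning is emitted.
    """
    img = np.asarray(img, dtype=np.float64)
    return _rescale_255(img)


def gaussian_kernel_1d(sigma: float, size: int) -> np.ndarray:
    """Normalised truncated 1D Gaussian kernel of odd ``size``."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if size < 1 or size % 2 == 0:
        raise ValueError("kernel size must be odd and >= 1")
    half = size // 2
    x = np.arange(-half, half + 1, dtype=np.float64)
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def gaussian_smooth(img: np.ndarray, sigma: float = 0.7, kernel: int = 3) -> np.ndarray:
    """Convolve with a normalised truncated Gaussian of the given size.

    The kernel is the outer product of two 1D truncated Gaussians
    (renormalised to sum to 1), applied separably with edge replication.
    A constant image is therefore a fixed point and the overall mean is
    preserved up to border effects.
    """
    img = np.asarray(img, dtype=np.float64)
    k1 = gaussian_kernel_1d(sigma, kernel)
    out = ndimage.correlate1d(img, k1, axis=0, mode="nearest")
    out = ndimage.correlate1d(out, k1, axis=1, mode="nearest")
    return out


_SCHARR_X = np.array([[-3, 0, 3], [-10, 0, 10], [-3, 0, 3]], dtype=np.float64)


def edge_emphasis(img: np.ndarray, operator: str = "sobel") -> np.ndarray:
    """Gradient-magnitude edge map, rescaled to [0, 255].

    ``sobel`` and ``scharr`` compute sqrt(Gx² + Gy²) from the standard
    3×3 derivative pair; ``laplacian`` uses |∇²|. Borders are edge
    replicated. A constant image yields all zeros.
    """
    img = np.asarray(img, dtype=np.float64)
    if operator == "sobel":
        gx = ndimage.sobel(img, axis=1, mode="nearest")
        gy = ndimage.sobel(img, axis=0, mode="nearest")
        mag = np.hypot(gx, gy)
    elif operator == "scharr":
        gx = ndimage.correlate(img, _SCHARR_X, mode="nearest")
        gy = ndimage.correlate(img, _SCHARR_X.T, mode="nearest")
        mag = np.hypot(gx, gy)
    elif operator == "laplacian":
        mag = np.abs(ndimage.laplace(img, mode="nearest"))
    else:
        raise ValueError(f"unknown edge operator {operator!r}")
    if mag.max() == 0:
        return np.zeros_like(mag)
    return mag * (255.0 / mag.max())


def bandpass_annulus(
    shape: tuple[int, int], low_frac: float, high_frac: float, taper: float = 0.0
) -> np.ndarray:
    """Centered annular transfer function over the 2D frequency plane.

    Radial frequency is measured in index units of the centered
    spectrum; the Nyquist radius R is half the smaller image dimension.
    The pass band keeps ``low_frac*R <= r <= high_frac*R``; with
    ``taper`` > 0 the band edges roll off as Gaussians of std
    ``taper*R`` instead of cutting hard.
    """
    h, w = shape
    fr = np.fft.fftshift(np.fft.fftfreq(h)) * h
    fc = np.fft.fftshift(np.fft.fftfreq(w)) * w
    r = np.hypot(fr[:, None], fc[None, :])
    nyq = min(h, w) / 2.0
    lo, hi = low_frac * nyq, high_frac * nyq
    if taper <= 0:
        return ((r >= lo) & (r <= hi)).astype(np.float64)
    s = taper * nyq
    mask = np.ones_like(r)
    mask = np.where(r < lo, np.exp(-((r - lo) ** 2) / (2 * s**2)), mask)
    mask = np.where(r > hi, np.exp(-((r - hi) ** 2) / (2 * s**2)), mask)
    return mask


def bandpass_filter(
    img: np.ndarray,
    low_frac: float = 0.05,
    high_frac: float = 0.6,
    taper: float = 0.0,
    rescale: bool = True,
) -> np.ndarray:
    """Annular Fourier band-pass, keeping mid-range spatial frequencies.

    The centered spectrum is multiplied by the annulus of
    :func:`bandpass_annulus`, inverse transformed, and the real part is
    linearly rescaled to [0, 255] (set ``rescale=False`` to keep the raw
    signed response, e.g. for spectral-energy checks). Removing the DC
    term means a constant image maps to zero everywhere.
    """
    if not 0 < low_frac < high_frac <= 1:
        raise ValueError("need 0 < low_frac < high_frac <= 1")
    img = np.asarray(img, dtype=np.float64)
    spec = np.fft.fftshift(np.fft.fft2(img))
    spec *= bandpass_annulus(img.shape, low_frac, high_frac, taper)
    out = np.fft.ifft2(np.fft.ifftshift(spec)).real
    return _rescale_255(out) if rescale else out


def run_chain(img: np.ndarray, params: PreprocessParams) -> dict[str, np.ndarray]:
    """Run the full pre-processing chain and return every stage image.

    Stages, in order: ``normalized`` -> ``smoothed`` -> ``edges`` (edge
    map of the smoothed image) -> ``bandpassed`` (band-pass of the edge
    map). ``bandpassed_intensity`` is additionally provided: the same
    annular filter applied to the smoothed intensity image, which keeps
    the pore/wall polarity and is what the default segmentation
    thresholds.
    """
    params.validate()
    stages: dict[str, np.ndarray] = {}
    stages["normalized"] = normalize_contrast(img)
    stages["smoothed"] = gaussian_smooth(
        stages["normalized"], params.gaussian_sigma, params.gaussian_kernel
    )
    stages["edges"] = edge_emphasis(stages["smoothed"], params.edge_operator)
    stages["bandpassed"] = bandpass_filter(
        stages["edges"],
        params.bandpass_low_frac,
        params.bandpass_high_frac,
        params.bandpass_taper,
    )
    stages["bandpassed_intensity"] = bandpass_filter(
        stages["smoothed"],
        params.bandpass_low_frac,
        params.bandpass_high_frac,
        params.bandpass_taper,
    )
    return stages
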