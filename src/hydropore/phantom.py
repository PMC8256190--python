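"""Synthetic SEM-like porous micrographs with exact ground truth.

The generator emulates the structure of a cryo-SEM hydrogel micrograph:
a bright polymer wall matrix, dark roughly circular pores, a slow linear
illumination drift across the field of view and additive Gaussian
detector noise. Pores are rendered as disks so that the equivalent
diameter of each planted pore is known exactly; an optional clustered
placement mimics the small-pore clusters seen in real gels, and fused
disk pairs exercise the watershed's ability to split touching pores.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .features import PoreRecord, equiv_diameter

__all__ = [
    "PhantomSpec",
    "PlantedPore",
    "GroundTruth",
    "DetectionScore",
    "generate_phantom",
    "render_clean",
    "score_detection",
]


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of a synthetic porous micrograph.

    Defaults produce the benchmark condition used throughout the test
    suite: a 512×512 field with 50 non-touching disks of radius 4–20 px,
    a 40-gray-level horizontal illumination ramp and additive Gaussian
    noise of σ = 8 — a moderately noisy, unevenly lit micrograph.
    """

    height: int = 512
    width: int = 512
    n_pores: int = 50
    radius_min: float = 4.0
    radius_max: float = 20.0
    radius_law: str = "uniform"  # or "lognormal"
    wall_intensity: float = 200.0
    pore_intensity: float = 60.0
    illumination_gradient: float = 40.0  # peak-to-peak, along columns
    noise_sigma: float = 8.0
    allow_touching: bool = False
    min_gap: float = 4.0  # min clearance between disk rims when not touching
    margin: float = 4.0  # min clearance of disk rims from the border
    cluster_box: tuple[float, float, float, float] | None = None  # r0, r1, c0, c1
    cluster_fraction: float = 0.0
    fused_pairs: int = 0
    fused_radius: float = 8.0
    fused_separation: float = 20.0
    fused_neck_width: float = 3.0
    wall_texture_sigma: float = 0.0  # band-limited wall texture amplitude
    seed: int = 0

    def validate(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("image dimensions must be >= 1")
        if self.radius_min < 2:
            raise ValueError("radii must be >= 2 px")
        if self.radius_max < self.radius_min:
            raise ValueError("radius_max must be >= radius_min")
        if not self.pore_intensity < self.wall_intensity:
            raise ValueError("pores must be darker than walls")
        if self.radius_law not in ("uniform", "lognormal"):
            raise ValueError("radius_law must be 'uniform' or 'lognormal'")
        if not 0.0 <= self.cluster_fraction <= 1.0:
            raise ValueError("cluster_fraction must be in [0, 1]")
        if self.cluster_fraction > 0 and self.cluster_box is None:
            raise ValueError("cluster_fraction > 0 requires cluster_box")


@dataclasses.dataclass(frozen=True)
class PlantedPore:
    """Ground truth for one planted pore."""

    pore_id: int
    center_row: float
    center_col: float
    radius_px: float
    area_px2: int  # rasterised area
    touches_border: bool

    @property
    def equiv_diameter_px(self) -> float:
        """Equivalent diameter of the rasterised disk, in px."""
        return equiv_diameter(self.area_px2)


@dataclasses.dataclass
class GroundTruth:
    """Exact label map and per-pore truth of a phantom."""

    labels: np.ndarray
    pores: list[PlantedPore]

    @property
    def interior_pores(self) -> list[PlantedPore]:
        return [p for p in self.pores if not p.touches_border]


@dataclasses.dataclass(frozen=True)
class DetectionScore:
    """Recall/precision of detections against planted pores.

    ``mean_rel_diameter_error`` averages |d_found - d_true| / d_true over
    matched pairs (diameters in px). Precision is ``None`` when there
    are no detections, the error ``None`` when there are no matches.
    """

    n_true: int
    n_found: int
    n_matched: int
    recall: float
    precision: float | None
    mean_rel_diameter_error: float | None


def _draw_radii(spec: PhantomSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    if spec.radius_law == "uniform":
        return rng.uniform(spec.radius_min, spec.radius_max, size=n)
    # lognormal shaped to sit mostly inside [radius_min, radius_max]
    mu = np.log(np.sqrt(spec.radius_min * spec.radius_max))
    sigma = np.log(spec.radius_max / spec.radius_min) / 4.0
    return np.clip(rng.lognormal(mu, sigma, size=n), spec.radius_min, spec.radius_max)


def _disk_mask(shape: tuple[int, int], row: float, col: float, radius: float) -> np.ndarray:
    rr = np.arange(shape[0])[:, None] - row
    cc = np.arange(shape[1])[None, :] - col
    return rr**2 + cc**2 <= radius**2


def _place_disks(spec: PhantomSpec, rng: np.random.Generator) -> list[tuple[float, float, float]]:
    """Rejection-sample (row, col, radius) triples honouring gap/margin."""
    radii = np.sort(_draw_radii(spec, rng, spec.n_pores))[::-1]  # big first: fewer rejects
    n_cluster = int(round(spec.cluster_fraction * spec.n_pores))
    # the *smallest* pores go into the cluster, mirroring real gels where
    # small pores pack densely in locally denser network regions
    clustered = set(range(spec.n_pores - n_cluster, spec.n_pores))
    placed: list[tuple[float, float, float]] = []
    max_tries = 400 * max(spec.n_pores, 1)
    tries = 0
    for i, r in enumerate(radii):
        while True:
            tries += 1
            if tries > max_tries:
                raise RuntimeError(
                    "could not place all pores without overlap; "
                    "reduce n_pores or the radii"
                )
            lo_r, hi_r = r + spec.margin, spec.height - 1 - r - spec.margin
            lo_c, hi_c = r + spec.margin, spec.width - 1 - r - spec.margin
            if i in clustered and spec.cluster_box is not None:
                b0, b1, c0, c1 = spec.cluster_box
                lo_r, hi_r = max(lo_r, b0), min(hi_r, b1)
                lo_c, hi_c = max(lo_c, c0), min(hi_c, c1)
            if hi_r <= lo_r or hi_c <= lo_c:
                raise RuntimeError("pore does not fit inside the placement region")
            row = rng.uniform(lo_r, hi_r)
            col = rng.uniform(lo_c, hi_c)
            if spec.allow_touching or all(
                np.hypot(row - pr, col - pc) >= r + p_rad + spec.min_gap
                for pr, pc, p_rad in placed
            ):
                placed.append((row, col, r))
                break
    return placed


def _render_labels(spec: PhantomSpec, centers: list[tuple[float, float, float]],
                   pairs: list[tuple[tuple[float, float], tuple[float, float], float]]
                   ) -> tuple[np.ndarray, list[PlantedPore]]:
    shape = (spec.height, spec.width)
    labels = np.zeros(shape, dtype=np.int32)
    pores: list[PlantedPore] = []
    next_id = 1
    for row, col, rad in centers:
        disk = _disk_mask(shape, row, col, rad)
        labels[disk] = next_id
        pores.append(
            PlantedPore(next_id, row, col, rad, int(disk.sum()),
                        _touches_border(disk))
        )
        next_id += 1
    for (r1, c1), (r2, c2), rad in pairs:
        d1 = _disk_mask(shape, r1, c1, rad)
        d2 = _disk_mask(shape, r2, c2, rad)
        neck = _neck_mask(shape, (r1, c1), (r2, c2), spec.fused_neck_width)
        rr = np.arange(shape[0])[:, None]
        cc = np.arange(shape[1])[None, :]
        nearer1 = (rr - r1) ** 2 + (cc - c1) ** 2 <= (rr - r2) ** 2 + (cc - c2) ** 2
        region = d1 | d2 | neck
        labels[region & nearer1] = next_id
        labels[region & ~nearer1] = next_id + 1
        a1 = int((region & nearer1).sum())
        a2 = int((region & ~nearer1).sum())
        pores.append(PlantedPore(next_id, r1, c1, rad, a1, _touches_border(d1 | neck)))
        pores.append(PlantedPore(next_id + 1, r2, c2, rad, a2, _touches_border(d2 | neck)))
        next_id += 2
    return labels, pores


def _touches_border(mask: np.ndarray) -> bool:
    return bool(mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any())


def _neck_mask(shape: tuple[int, int], p1: tuple[float, float],
               p2: tuple[float, float], width: float) -> np.ndarray:
    """Pixels within width/2 of the segment p1-p2."""
    rr = np.arange(shape[0])[:, None].astype(float)
    cc = np.arange(shape[1])[None, :].astype(float)
    v = np.array([p2[0] - p1[0], p2[1] - p1[1]])
    L2 = float(v @ v)
    t = ((rr - p1[0]) * v[0] + (cc - p1[1]) * v[1]) / L2
    t = np.clip(t, 0.0, 1.0)
    dr = rr - (p1[0] + t * v[0])
    dc = cc - (p1[1] + t * v[1])
    return dr**2 + dc**2 <= (width / 2.0) ** 2


def _place_pairs(spec: PhantomSpec, rng: np.random.Generator,
                 occupied: list[tuple[float, float, float]]
                 ) -> list[tuple[tuple[float, float], tuple[float, float], float]]:
    pairs = []
    eff_r = spec.fused_separation / 2.0 + spec.fused_radius  # pair half-extent
    tries = 0
    while len(pairs) < spec.fused_pairs:
        tries += 1
        if tries > 400 * max(spec.fused_pairs, 1):
            raise RuntimeError("could not place fused pairs without overlap")
        row = rng.uniform(eff_r + spec.margin, spec.height - 1 - eff_r - spec.margin)
        col = rng.uniform(eff_r + spec.margin, spec.width - 1 - eff_r - spec.margin)
        theta = rng.uniform(0, np.pi)
        dr = spec.fused_separation / 2.0 * np.sin(theta)
        dc = spec.fused_separation / 2.0 * np.cos(theta)
        p1, p2 = (row - dr, col - dc), (row + dr, col + dc)
        clear = all(
            np.hypot(row - pr, col - pc) >= eff_r + p_rad + spec.min_gap
            for pr, pc, p_rad in occupied
        )
        if clear:
            occupied.append((row, col, eff_r))
            pairs.append((p1, p2, spec.fused_radius))
    return pairs


def render_clean(spec: PhantomSpec, gt: GroundTruth) -> np.ndarray:
    """Noise-free image implied by a ground truth: walls + pores + ramp."""
    img = np.full((spec.height, spec.width), spec.wall_intensity, dtype=np.float64)
    img[gt.labels > 0] = spec.pore_intensity
    cols = np.arange(spec.width, dtype=np.float64)
    denom = max(spec.width - 1, 1)
    img += spec.illumination_gradient * (cols[None, :] / denom - 0.5)
    return np.clip(img, 0.0, 255.0)


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Generate a synthetic micrograph and its exact ground truth.

    The image is ``wall_intensity`` everywhere, with planted dark disks
    (plus fused disk pairs when requested), a linear horizontal
    illumination ramp of the given peak-to-peak amplitude centred on
    zero, optional band-limited wall texture, and i.i.d. Gaussian noise,
    clipped to [0, 255]. The same spec (same seed) always produces a
    bit-identical image.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    centers = _place_disks(spec, rng)
    pairs = _place_pairs(spec, rng, list(centers)) if spec.fused_pairs else []
    labels, pores = _render_labels(spec, centers, pairs)
    gt = GroundTruth(labels=labels, pores=pores)
    img = render_clean(spec, gt)
    if spec.wall_texture_sigma > 0:
        # band-limited texture on the walls only, so the band-pass stage
        # has realistic mid-frequency content to work against
        from scipy import ndimage as _ndi

        tex = rng.normal(0.0, 1.0, size=img.shape)
        tex = _ndi.gaussian_filter(tex, 2.0)
        tex *= spec.wall_texture_sigma / max(tex.std(), 1e-12)
        img = img + np.where(gt.labels == 0, tex, 0.0)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 255.0), gt


def score_detection(
    gt: GroundTruth,
    found: Sequence[PoreRecord],
    match_radius_px: float = 5.0,
    microns_per_pixel: float = 1.0,
    interior_only: bool = True,
) -> DetectionScore:
    """Greedy one-to-one centroid matching of detections to ground truth.

    Candidate (truth, detection) pairs within ``match_radius_px`` are
    matched closest-first, each side at most once. Diameter errors are
    computed in pixels (detected µm diameters are converted back with
    ``microns_per_pixel``). By default only interior planted pores count
    as truth, since the pipeline discards border-touching pores.
    """
    if match_radius_px <= 0:
        raise ValueError("match_radius_px must be > 0")
    truth = gt.interior_pores if interior_only else gt.pores
    n_true, n_found = len(truth), len(found)
    if n_found == 0:
        return DetectionScore(n_true, 0, 0, 0.0 if n_true else 1.0, None, None)
    cand = []
    for i, p in enumerate(truth):
        for j, f in enumerate(found):
            d = np.hypot(p.center_row - f.centroid_row_px,
                         p.center_col - f.centroid_col_px)
            if d <= match_radius_px:
                cand.append((d, i, j))
    cand.sort()
    used_t: set[int] = set()
    used_f: set[int] = set()
    errors = []
    for d, i, j in cand:
        if i in used_t or j in used_f:
            continue
        used_t.add(i)
        used_f.add(j)
        d_true = truth[i].equiv_diameter_px
        d_found = found[j].equiv_diameter_um / microns_per_pixel
        errors.append(abs(d_found - d_true) / d_true)
    n_matched = len(used_t)
    return DetectionScore(
        n_true=n_true,
        n_found=n_found,
        n_matched=n_matched,
        recall=n_matched / n_true if n_true else 1.0,
        precision=n_matched / n_found,
        mean_rel_diameter_error=float(np.mean(errors)) if errors else None,
    )
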