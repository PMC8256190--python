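# Methods

`hydropore` quantifies the porosity and spatial heterogeneity of porous
hydrogel micrographs — typically cryo-SEM images of fully hydrated
gels, where the polymer wall network images bright and the pores dark.
This note records the processing model, the parameters that matter, the
numerical choices that were genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Processing model

The pipeline treats segmentation as five stages.

**1. Pre-processing.** The gray-level histogram is stretched linearly
to [0, 255]; a truncated Gaussian kernel (σ = 0.7, 3×3) removes pixel
noise while preserving edges; a Sobel gradient-magnitude map emphasises
the wall/pore transitions; and an annular Fourier band-pass keeps
mid-range spatial frequencies. The low radial cut removes slow
illumination drift (frequencies below 5% of the Nyquist radius by
default), the high cut (60%) removes the remaining pixel-scale noise.
All spatial convolutions replicate the border pixel rather than padding
with zeros, so no artificial dark halo is introduced at the frame.

The stage the threshold consumes is configurable
(`threshold_source`). The default is the band-pass of the *smoothed
intensity* image: it keeps the dark-pore/bright-wall polarity, and the
pore boundary sits at the zero crossing of the band-passed step, so
pore radii are recovered without systematic bias. Thresholding the
band-passed *edge-magnitude* map instead (also available) locates pores
by their boundary ridges; because a filled ridge extends half a
ridge-width beyond the true boundary, radii come out ~2 px large, which
is a poor trade for small pores. The edge map remains part of every run
and is exported with `--save-stages` for inspection.

**2. Thresholding.** The default binarisation is adaptive (local)
Gaussian thresholding: a pixel passes if its intensity exceeds the
Gaussian-weighted mean of its 25×25 px window minus an offset C. The
window Gaussian uses the conventional size-to-sigma rule
σ = 0.3·((w−1)/2 − 1) + 0.8. Because the reference level travels with
the neighbourhood, the decision is unaffected by illumination drift —
the property that makes local thresholding the method of choice for
SEM images. A global Otsu threshold (maximising between-class variance
over the 256-bin histogram) ships as the `validation` preset.

The offset defaults to **C = 10** gray levels. C controls the false-
positive rate in flat regions: a pixel of pure noise passes the local
test with probability P(noise < −C). At C = 2 roughly 40% of flat
wall/pore pixels pass; that speckle percolates under 8-connectivity
into image-spanning clusters which morphological cleaning cannot
remove (measured precision on the benchmark: 0.10). At C = 10 the
flat-field pass rate is a few percent, isolated, and fully removed by
the erosion/opening step (precision 1.00 at identical recall). C = 10
is robust on the benchmark family across noise σ 2–16, ramps 0–80
levels, low contrast and log-normal radii; for other imagery it is the
first knob to adjust (raise it if walls break up into spurious pores,
lower it if faint pores vanish).

Thresholding marks *bright* pixels; on intensity images the bright
phase is the wall, so in `pores` mode the binary look-up table is
inverted immediately after thresholding to bring the pores into the
foreground (`walls` mode keeps the walls).

**3. Morphological cleaning.** With a 3×3 elliptical structuring
element — whose discretisation on a 3×3 grid is the cross (centre +
4-neighbours) — the pipeline: clears every component touching the
image border (those pores are truncated and unmeasurable); erodes once;
opens five times, where one opening = one erosion followed by one
dilation and the pair is iterated as a unit (opening is idempotent, so
the repeats are a no-op by design — the alternative convention,
erode×5 then dilate×5, destroys every pore of radius ≲ 6 px and was
rejected for that reason); fills enclosed background holes (background
traversed with the connectivity complementary to the foreground's, 4
vs 8, avoiding the digital-topology paradox); and finally restores the
full pre-erosion shape of every surviving pore by morphological
reconstruction, using the cleaned mask as marker and the hole-filled,
border-cleared threshold mask as reference. Using the *unfilled* mask
as reference would restore ring shapes rather than solid pores, which
is why the reference is filled first.

**4. Watershed.** Touching pores are split on the Euclidean distance
transform D of the pore mask, negated so pore centres are basins.
Markers are the maxima of D whose *dynamics* — height above the saddle
separating them from a higher maximum — exceed
`watershed_max_threshold · max(D)` (default 0.05). Two fused pores
give two deep maxima with a shallow saddle at the neck and are cut
there; the shallow spurious maxima of a single rough pore fall under
the cut and are suppressed. This dynamics (h-maxima) reading of the
0.05 marker threshold both splits planted fused pairs (10/10 on the
benchmark) and leaves isolated disks whole; the alternative reading —
markers as connected components of {D > 0.05·max(D)} — cannot split
any realistic neck, because a 5% cut lies far below the saddle height
of every renderable neck. Components left without a marker (possible
for very flat blobs) keep one label each, so the labels always
partition the mask. Flooding itself is standard marker-controlled
watershed (8-connected by default).

**5. Measurement and heterogeneity.** Each label yields its geometric
(unweighted) centre of mass, pixel area, area in µm² via the
user-supplied calibration (µm/px, squared), and equivalent diameter
d = 2√(A/π) — the diameter of the circle of equal area. The pore-size
distribution uses fixed-width bins from zero (default 2 µm). Spatial
heterogeneity is a bivariate Gaussian *product-kernel* density fitted
to the pore centres: per-axis bandwidth by Scott's rule n^(−1/6)·σ_axis
(Silverman and fixed bandwidths available), evaluated on a regular
grid covering the image extent padded by three bandwidths per side, so
the Riemann sum of the field is ≈ 1 (the ≤ 0.6% deficit is the
Gaussian mass beyond 3σ). Iso-density contours are extracted by
marching squares at levels equally spaced strictly between the field
minimum and maximum; per-pore densities (dot plots) come from bilinear
interpolation of the grid. Density is areal (pores per px²) and
unweighted by pore size; a high value marks many pores per unit area,
a low value a sparse region or one covered by few large pores.

## Parameters at a glance

| parameter | default | unit | role |
|---|---|---|---|
| `gaussian_sigma`, `gaussian_kernel` | 0.7, 3 | px | denoising strength |
| `bandpass_low_frac`, `bandpass_high_frac` | 0.05, 0.6 | Nyquist fraction | drift / noise cut-offs |
| `bandpass_taper` | 0 (hard annulus) | Nyquist fraction | Gaussian roll-off against ringing |
| `window` | 25 | px | adaptive-threshold neighbourhood |
| `offset_c` | 10 | gray levels | flat-field false-positive control |
| `erosion_iters`, `opening_iters` | 1, 5 | — | speckle removal |
| `watershed_max_threshold` | 0.05 | fraction of max(D) | marker dynamics cut |
| `connectivity` | 8 | — | foreground connectivity |
| `microns_per_pixel` | 1.0 | µm/px | physical calibration (user-supplied, never inferred from scale bars) |
| `bandwidth_rule` | scott | — | KDE bandwidth per axis |
| `bin_width_um` | 2 | µm | pore-size histogram bin |

The `validation` preset swaps the adaptive threshold for global Otsu
while keeping the 0.05 watershed cut; everything else is shared.

## The synthetic benchmark

The phantom generator emulates the *structure* of a porous-gel
micrograph: a bright wall matrix (200), dark disk pores (60), a linear
horizontal illumination ramp (40 gray levels peak-to-peak), and
i.i.d. Gaussian noise (σ = 8), clipped to [0, 255]. The benchmark
condition is a 512×512 field with 50 non-touching disks of radius
4–20 px. Disks make the ground truth exact — centre, pixel area and
equivalent diameter are known by construction — and the generator can
additionally pack a chosen fraction of (the smallest) pores into a
cluster box, plant fused disk pairs joined by 3-px necks for watershed
testing, and texture the walls with band-limited noise.

What the phantom does *not* emulate: irregular pore shapes, partially
out-of-plane pores, wall-thickness variation, charging and sublimation
artifacts of real cryo-SEM, and correlated detector noise. Passing the
benchmark therefore demonstrates that the implementation is correct
and well-calibrated on its stated model — convex dark objects under
drift and noise — not that the default parameters are optimal for any
particular instrument's output. On the benchmark the default pipeline
reaches recall 1.00, precision ≥ 0.98 and mean equivalent-diameter
error < 1%; the numbers are recomputed from scratch by
`scripts/acceptance.py`.

## Numerical choices and degenerate inputs

- Contrast stretching of a constant image returns all zeros with a
  warning (there is no contrast to stretch); Otsu rejects constant
  images outright (no two classes).
- The Otsu threshold quantises intensities to the 0–255 integer grid
  and takes the first variance argmax on ties; the mask is identical
  for any threshold inside an empty histogram gap, so tie-breaking is
  observationally irrelevant.
- The band-pass annulus is hard-edged by default; `bandpass_taper`
  applies a Gaussian roll-off for imagery where ringing is visible.
  DC removal means a constant image maps to zero.
- Erosion/dilation treat out-of-image pixels as background.
- An empty pore mask yields zero labels, an empty record list, and an
  absent (None) diameter summary — not an error. The KDE needs ≥ 2
  distinct centres for data-driven bandwidths (≥ 1 for fixed) and
  refuses zero-variance point sets.
- All randomness lives in the phantom generator and is seeded through
  `PhantomSpec.seed`; the pipeline itself is deterministic, and two
  runs on identical input and config produce byte-identical TSV
  exports (floats written with 10 significant digits).

## Known limitations

- Heavily textured walls (texture σ comparable to the threshold
  offset) generate spurious detections at the default C; raising
  `offset_c` or narrowing the band-pass restores precision at some
  cost in sensitivity to faint pores.
- The equivalent diameter of a strongly non-convex pore is a crude
  summary, and the watershed may split elongated pores with multiple
  deep distance maxima.
- `walls` mode keeps the wall phase in the foreground, but a fully
  connected wall matrix touches the border and is removed by border
  clearing; wall-thickness metrology would need a different cleaning
  chain and is not attempted here.
- KDE field values depend on the bandwidth rule and grid; they are
  comparable within one analysis, and cluster *locations* are the
  robust output, not absolute density numbers.
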