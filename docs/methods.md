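# Methods

## Model and assumptions

The comparison treats a super-resolution reconstruction purely as a 2D
intensity grid with a known pixel size.  Its premise is that a test
reconstruction and a HAWK-preprocessed (or otherwise unbiased) reference
fail in *different* ways: density-induced fitting bias displaces
structure in the test image, while the reference suffers only a loss of
localisation precision.  Agreement of the two therefore certifies the
structure; disagreement localises bias.  Because reconstruction
intensity is not linearly related to labelling density (repeat
appearances, missed detections, background), all comparisons are made on
binarised or skeletonised representations, never on intensities.

Scales are Gaussian-blur FWHMs in integer multiples of the
reconstruction pixel.  The default ladder tops out at the instrument PSF
FWHM expressed in reconstruction pixels, because the PSF is typically
the smallest separation at which localisation algorithms are reliably
unbiased; the maximum is user-overridable for very-high-density data.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| flatten percentile | 98 (of nonzero pixels) | caps repeat-appearance hot pixels; zeros excluded so sparse images are not crushed |
| `C_b` sharpening / structure | 0.7 / 0.85 | proportional Wellner coefficients; 0.7 thresholds linear structures at roughly their FWHM and separates features with peak-to-trough ratio ≈ 2; 0.85 isolates local maxima for skeletonisation and must never be below the sharpening value |
| `C_a` sharpening / structure | 0.04 / 0.02 | absolute baseline suppressing isolated background localisations (image is normalised to max 1) |
| auxiliary coefficient | 0.1 | weight of the half-PSF-window mean added to both thresholds; damps threshold gradients that would fragment structure at small scales |
| full-confidence correlation | 0.85 | local PCC treated as complete agreement; a perfect correlation is unattainable because the reference has degraded precision and skeletons are re-blurred |
| artefact-scale threshold | 0.9 | confidence needed to call a pixel artefact-free at a scale |

Scale geometry: window side `2r+1` with `r = ceil(scale_no/2) − 1` is
the largest odd pixel count not exceeding the scale number; the
auxiliary window uses `r' = ceil(psf_scale_no/2) − 1`; `σ = FWHM /
(2√(2 ln 2))`.

## Numerical choices

- **Border handling** (blur and window means): truncated-support
  renormalisation — zero-padded filter output divided by the filtered
  ones image, i.e. averages over in-bounds pixels only.  Zero padding
  alone would darken borders and binarise as spurious structure edges.
- **Gaussian truncation** at 4σ (< 1e-4 mass loss), matching the sampled
  kernel the dense-convolution test oracle uses.
- **Binarisation** is strict (`P > P_thr`), so an all-zero background
  stays all-false even with `C_a = 0`.
- **Skeletonisation**: Zhang–Suen thinning on the 8-connected
  foreground.  Thinning is branch-sensitive on noisy masks; the blur
  applied before binarisation suppresses this, increasingly at larger
  scales.
- **Local correlation windows** are square, dense (per-pixel stride),
  with side the largest odd integer ≤ max(scale, 3); a 1-pixel window
  has no defined variance.  Window statistics use truncated borders,
  consistent with the means.
- **Zero-variance windows.**  A Pearson correlation is undefined in a
  constant window.  For the continuous structure grids such windows are
  treated as carrying no evidence: they are excluded from
  mean-confidence statistics and shown desaturated in the confidence
  map.  For the binary sharpening masks, windows in which *both* masks
  are constant are compared by content: both entirely foreground is
  scored as full agreement, foreground against background as full
  disagreement, both empty as no evidence.  Interior foreground
  agreement is real evidence — without it the statistics would be
  dominated by mask boundaries and entire agreeing structures would be
  scored as unknown.
- **Confidence clamping.**  Each `min(1, PCC/0.85)` term is clamped to
  [0, 1]: an anti-correlated window carries no positive evidence, and
  the displayed colour scale has no negative range.  Undefined terms
  contribute 0.
- **Structure-term correlation inputs** are the re-blurred skeletons
  blurred once more at the current scale, making the comparison
  progressively tolerant of sub-scale displacements.
- **Global PCCs** are computed over the full frame including background;
  constant inputs are reported as undefined, not 0.
- **Re-blurred skeletons** are normalised to maximum 1; the correlations
  are affine-invariant, so this affects only map brightness.
- **Artefact scale map** thresholds the raw per-pixel confidence; pixels
  that never reach the threshold keep a sentinel value rendered grey,
  visually distinct from every scale hue (red → purple sweep).
- The pipeline has no stochastic step: identical inputs give
  bit-identical maps and metrics.

## The synthetic-data generator

The generator emulates the bias phenomenology at the *localisation*
level; it does not simulate camera frames, photon noise, or any specific
fitting algorithm.  Ground-truth emitters sit on a 10 nm grid along a
chosen structure (line pair, crossing, ring, or a sarcomere-like doublet
of 20 nm-wide lines with 60 nm centre spacing, leaving a 40 nm gap),
labelled at 100 emitters/µm per grid column.  Each emitter appears a
Poisson-distributed number of times (mean 5; sub-unit means such as 0.75
are supported), on uniformly random frames (default 100, which at the
default geometry gives several active emitters per PSF width per frame —
a high-density condition), jittered by the localisation precision.
Density bias is emulated by moving, with probability `bias_fraction`,
each appearance that has same-frame neighbours within the PSF FWHM
(270 nm) a `bias_pull` fraction (default 0.5) towards the centroid of
those overlapping appearances.  For an isolated pair this is the
classic pull towards the mutual midpoint; on dense structures it
reproduces collapse towards the midline together with reduced scatter.
A nearest-neighbour-only variant was tried first and rejected: on dense
lines the nearest neighbour is almost always the along-line one, which
moves localisations along the structure and produces no visible
collapse.

Rendering defaults to one Gaussian per localisation with σ equal to the
localisation precision (the standard rendering of fitted positions,
integrated exactly over each pixel so image mass equals localisation
count); histogram binning is available.  The reference table is
unbiased at 25 nm precision (emulating HAWK's precision cost), the test
table biased at 15 nm; both are rendered at 10 nm pixels.  A single
seeded random stream drives the whole generation, so fixtures are
bit-reproducible.

What passing tests on these fixtures do **not** show: robustness to
camera noise models, non-Poisson blinking kinetics, drift, anisotropic
PSFs, sample-dependent background, or the idiosyncrasies of real fitting
algorithms — the emulation reproduces the geometry of density bias, not
its photophysical origin.

## Validation experiment design

- **Peak-to-trough separation rule.**  The claim that `C_b = 0.7` picks
  up features with peak-to-trough ratio ≈ 2 is a property of the
  proportional Wellner term alone, so the experiment applies the
  threshold with the auxiliary and baseline terms disabled, window
  spanning the ridge separation (20 px), and bisects the trough depth of
  a two-ridge image until the binarisation stops yielding two
  components.  The crossover lands at a ratio of ≈ 1.9.
- **Detection-scale recovery** uses line pairs at 50/100/150 nm
  separation with strong bias (0.8) and *matched 5 nm precisions* for
  both inputs.  The high-precision reference acts as a ground-truth
  proxy: at the default 25 nm reference precision a 50 nm pair is
  unresolvable in the reference itself, so test and reference agree (the
  method correctly reports that nothing can be said below the reference
  resolution) and the recovery scale would not track the separation.
  With a resolving reference the first scale at which mean confidence
  reaches 0.9 increases strictly with separation, because the collapse
  displacement grows with the pair distance.
- **Null calibration.**  For an unbiased pair sampled twice at matched
  15 nm precision, mean confidence reaches 0.9 by scale 3 (= 2× the
  precision at 10 nm pixels): residual disagreement between two
  independent samplings is confined to scales below twice the
  localisation precision.
- Mean confidence is averaged over pixels where both correlation terms
  are defined and the combined intensity is positive.

Problem sizes throughout (256×256 self-comparison over 27 scales,
200×200 fixtures, 50-image oracle batches) were chosen as the smallest
at which the behaviours above are stable and clearly resolved.

## Known limitations

- 2D only; no bi-plane/3D support and no spatially varying PSF.
- The noise baseline `C_a` assumes spatially uniform background; regions
  with different background levels should be cropped and analysed
  separately.
- Labelling artefacts (fluorophores displaced from the target protein)
  are invisible to the comparison by construction.
- The local-correlation window shape/stride and the exact hue ramps are
  implementation choices; endpoint colours follow the published
  conventions (yellow/magenta/cyan overlays, red→cyan confidence,
  red→purple artefact scale).
- When the reference precision is worse than the structure spacing the
  method reports agreement of two equally unresolved images; the
  artefact scale map then reflects the reference's resolution, not the
  test image's fidelity.
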