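"""Per-scale comparison of test and reference representations.

For each length scale the sharpening masks and re-blurred skeletons of the
two inputs are correlated with a dense sliding-window Pearson correlation
whose window side equals the current scale (forced odd and at least 3).
The two correlations are combined into a confidence score

    S_conf = 1/2 * min(1, PCC_sharp / 0.85) + 1/2 * min(1, PCC_str / 0.85)

with each term clamped to [0, 1]: a local correlation of 0.85 in both
representations already indicates valid structure, because the slightly
reduced precision of a HAWK reference and the skeleton re-blur make a
perfect correlation unlikely even for faithful reconstructions.  Windows
in which either input has zero variance carry no evidence and are flagged
undefined rather than scored.

Rendered outputs follow the published colour conventions: overlay maps
show agreement in yellow, test-only structure in magenta (artificial
sharpening) and reference-only structure in cyan (missing structure);
confidence maps sweep hue from red (0) to cyan (1) with brightness equal
to the combined input intensity; the artefact scale map colours each pixel
by the smallest scale at which its confidence exceeds 90%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb
from scipy import ndimage

from hawkman.recon_io import ReconstructionImage, flatten_intensity
from hawkman.scalespace import (
    BinaryMap,
    ScaleSpec,
    ThresholdParams,
    adaptive_threshold,
    binarise,
    blur_fwhm_px,
    reblur_skeleton,
    skeletonise,
)

#: Local correlation treated as full confidence.
FULL_CONFIDENCE_PCC = 0.85

#: Confidence level above which a pixel counts as artefact-free at a scale.
ARTEFACT_CONFIDENCE = 0.9

#: Artefact-scale-map value for pixels that never reach high confidence.
SCALE_SENTINEL = 0

#: Window variances at or below this are treated as undefined correlations.
_VAR_TOL = 1e-12


def _grid(x) -> np.ndarray:
    if isinstance(x, BinaryMap):
        return x.mask.astype(float)
    if isinstance(x, ReconstructionImage):
        return x.pixels
    return np.asarray(x, dtype=float)


def local_pcc(a, b, window_px: int, constant_policy: str = "undefined") -> tuple[np.ndarray, np.ndarray]:
    """Dense sliding-window Pearson correlation of two grids.

    The window is the centred square of side equal to the largest odd
    integer <= max(window_px, 3); at borders only in-bounds pixels enter.
    Returns ``(pcc, defined)``: the correlation grid (NaN where undefined,
    clipped to [-1, 1]) and the boolean mask of windows carrying evidence.

    Windows in which either input has zero variance have no Pearson
    correlation.  With ``constant_policy="undefined"`` they are all flagged
    undefined.  With ``constant_policy="binary"`` (for 0/1 mask inputs),
    windows in which *both* inputs are constant are compared by content:
    both entirely foreground is perfect agreement (correlation 1, defined),
    foreground against background is perfect disagreement (correlation -1,
    defined), and both empty remains undefined — agreement on empty
    background would be vacuous evidence.
    """
    a = _grid(a)
    b = _grid(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    if window_px < 1:
        raise ValueError("window_px must be >= 1")
    if constant_policy not in ("undefined", "binary"):
        raise ValueError(f"unknown constant_policy {constant_policy!r}")
    side = max(int(window_px), 3)
    if side % 2 == 0:
        side -= 1

    def wsum(x):
        return ndimage.uniform_filter(x, size=side, mode="constant", cval=0.0) * side**2

    n = wsum(np.ones_like(a))
    ma = wsum(a) / n
    mb = wsum(b) / n
    var_a = np.maximum(wsum(a * a) / n - ma * ma, 0.0)
    var_b = np.maximum(wsum(b * b) / n - mb * mb, 0.0)
    cov = wsum(a * b) / n - ma * mb
    defined = (var_a > _VAR_TOL) & (var_b > _VAR_TOL)
    pcc = np.full(a.shape, np.nan)
    pcc[defined] = np.clip(
        cov[defined] / np.sqrt(var_a[defined] * var_b[defined]), -1.0, 1.0
    )
    if constant_policy == "binary":
        const_both = (var_a <= _VAR_TOL) & (var_b <= _VAR_TOL)
        fg_a = ma > 0.5
        fg_b = mb > 0.5
        agree = const_both & fg_a & fg_b
        clash = const_both & (fg_a ^ fg_b)
        pcc[agree] = 1.0
        pcc[clash] = -1.0
        defined = defined | agree | clash
    return pcc, defined


def confidence_score(pcc_sharp, pcc_str, full_threshold: float = FULL_CONFIDENCE_PCC):
    """Combine sharpening and structure correlations into S_conf in [0, 1].

    Each term ``min(1, PCC / full_threshold)`` is clamped below at 0 (an
    anti-correlated window carries no positive evidence, and the displayed
    colour scale has no negative range); undefined correlations (NaN)
    contribute 0.  Accepts scalars or arrays.
    """

    def term(p):
        p = np.asarray(p, dtype=float)
        t = np.clip(np.minimum(1.0, p / full_threshold), 0.0, 1.0)
        return np.where(np.isnan(p), 0.0, t)

    s = 0.5 * term(pcc_sharp) + 0.5 * term(pcc_str)
    if s.ndim == 0:
        return float(s)
    return s


def global_pcc(a, b) -> float | None:
    """Whole-frame Pearson correlation; ``None`` when either input is constant."""
    a = _grid(a).ravel()
    b = _grid(b).ravel()
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    da = a - a.mean()
    db = b - b.mean()
    na = np.sqrt((da * da).sum())
    nb = np.sqrt((db * db).sum())
    if na == 0.0 or nb == 0.0:
        return None
    return float(np.clip((da * db).sum() / (na * nb), -1.0, 1.0))


def overlay_map(test, ref) -> np.ndarray:
    """Colour overlay: yellow agreement, magenta test-only, cyan reference-only.

    Binary masks map to pure colours; intensity grids (expected in [0, 1])
    grade continuously, with per-channel brightness proportional to each
    input's intensity.  Returns an 8-bit RGB array.
    """
    t = np.clip(_grid(test), 0.0, 1.0)
    r = np.clip(_grid(ref), 0.0, 1.0)
    if t.shape != r.shape:
        raise ValueError("shape mismatch")
    rgb = np.stack([t, r, np.abs(t - r)], axis=-1)
    return np.round(rgb * 255.0).astype(np.uint8)


def confidence_map(combined, s_conf, defined=None) -> np.ndarray:
    """Colourise the combined input intensity by confidence.

    Hue sweeps red (S_conf = 0) to cyan (S_conf = 1); the value channel is
    the combined (normalised) intensity, so background stays black.
    Pixels with no defined correlation are shown desaturated (grey).
    """
    c = np.clip(_grid(combined), 0.0, 1.0)
    s = np.nan_to_num(np.clip(_grid(s_conf), 0.0, 1.0))
    if c.shape != s.shape:
        raise ValueError("shape mismatch")
    hue = 0.5 * s
    sat = np.ones_like(c)
    if defined is not None:
        sat = np.where(np.asarray(defined, dtype=bool), 1.0, 0.0)
    rgb = hsv_to_rgb(np.stack([hue, sat, c], axis=-1))
    return np.round(rgb * 255.0).astype(np.uint8)


@dataclass
class ScaleResult:
    """All per-scale outputs of the comparison."""

    scale: ScaleSpec
    sharp_test: BinaryMap
    sharp_ref: BinaryMap
    struct_test: np.ndarray
    struct_ref: np.ndarray
    pcc_sharp_local: np.ndarray
    pcc_str_local: np.ndarray
    defined_sharp: np.ndarray
    defined_struct: np.ndarray
    s_conf: np.ndarray
    conf_defined: np.ndarray
    combined: np.ndarray
    pcc_sharp_global: float | None
    pcc_str_global: float | None
    mean_conf: float
    maps: dict = field(default_factory=dict)


def global_metrics(result: ScaleResult) -> tuple[float | None, float | None]:
    """Whole-frame PCCs between the sharpening masks and the structure grids.

    These are the single-number quality summaries of a scale: the
    correlation between the binarised test/reference sharpening maps and
    between the re-blurred skeleton grids.  Constant image pairs are
    undefined and reported as ``None``, not 0.
    """
    g_sharp = global_pcc(result.sharp_test, result.sharp_ref)
    g_str = global_pcc(result.struct_test, result.struct_ref)
    return g_sharp, g_str


@dataclass
class ArtefactScaleMap:
    """Per-pixel smallest scale at which confidence exceeds the threshold.

    ``scale_of_confidence`` holds scale numbers (SCALE_SENTINEL = 0 marks
    pixels that never reach the threshold).  The rendering colours pixels
    by scale, hue sweeping red (smallest) to purple (largest), brightness
    equal to the combined input intensity; sentinel pixels are grey.
    """

    scale_of_confidence: np.ndarray
    rgb: np.ndarray
    max_scale_no: int
    threshold: float
    sentinel: int = SCALE_SENTINEL


def artefact_scale_map(
    conf_stack,
    scale_nos,
    combined,
    threshold: float = ARTEFACT_CONFIDENCE,
) -> ArtefactScaleMap:
    """Reduce a stack of per-scale confidence grids to an artefact scale map.

    ``conf_stack`` is a sequence of S_conf grids matching ``scale_nos``,
    which must cover ``1..max`` contiguously.  For each pixel the smallest
    scale with S_conf >= threshold is recorded; pixels that never reach it
    keep the sentinel value 0.
    """
    scale_nos = [int(s) for s in scale_nos]
    conf_stack = [np.asarray(c, dtype=float) for c in conf_stack]
    if not conf_stack:
        raise ValueError("empty confidence stack")
    if len(conf_stack) != len(scale_nos):
        raise ValueError("conf_stack and scale_nos length mismatch")
    if scale_nos != list(range(1, len(scale_nos) + 1)):
        raise ValueError("scale numbers must cover 1..max contiguously")
    shape = conf_stack[0].shape
    scale_map = np.full(shape, SCALE_SENTINEL, dtype=int)
    for scale_no, s_conf in zip(scale_nos, conf_stack):
        with np.errstate(invalid="ignore"):
            hit = (s_conf >= threshold) & (scale_map == SCALE_SENTINEL)
        scale_map[hit] = scale_no

    max_scale = scale_nos[-1]
    c = np.clip(_grid(combined), 0.0, 1.0)
    if max_scale > 1:
        hue = 0.8 * (scale_map - 1) / (max_scale - 1)
    else:
        hue = np.zeros(shape)
    sat = np.where(scale_map == SCALE_SENTINEL, 0.0, 1.0)
    hue = np.where(scale_map == SCALE_SENTINEL, 0.0, hue)
    rgb = np.round(hsv_to_rgb(np.stack([hue, sat, c], axis=-1)) * 255.0).astype(np.uint8)
    return ArtefactScaleMap(scale_map, rgb, max_scale, threshold)


@dataclass
class HawkmanRun:
    """Full result of a comparison: per-scale results plus the scale map."""

    scales: list
    artefact: ArtefactScaleMap
    params: ThresholdParams
    pixel_size_nm: float

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for res in self.scales:
            rows.append(
                {
                    "scale_no": res.scale.scale_no,
                    "fwhm_nm": res.scale.fwhm_nm,
                    "pcc_sharp": np.nan if res.pcc_sharp_global is None else res.pcc_sharp_global,
                    "pcc_str": np.nan if res.pcc_str_global is None else res.pcc_str_global,
                    "mean_conf": res.mean_conf,
                }
            )
        return pd.DataFrame(rows)


def run_hawkman(
    test: ReconstructionImage,
    ref: ReconstructionImage,
    params: ThresholdParams | None = None,
    max_scale_no: int | None = None,
    psf_fwhm_nm: float | None = None,
    confidence_full_threshold: float = FULL_CONFIDENCE_PCC,
    artefact_threshold: float = ARTEFACT_CONFIDENCE,
    flatten_percentile: float = 98.0,
    render: bool = True,
) -> HawkmanRun:
    """Run the full multi-scale comparison of a test and reference image.

    Per scale: flatten -> blur -> max-normalise; binarise for the
    sharpening representation; binarise at the higher threshold,
    skeletonise and re-blur for the structure representation; correlate
    both locally (the structure grids are blurred once more to the current
    scale before correlation, making them progressively tolerant of
    sub-scale differences); combine into the confidence score; accumulate
    the artefact scale map.  Deterministic: identical inputs give
    identical outputs.

    ``params`` may be omitted if ``psf_fwhm_nm`` is given, in which case
    default coefficients are used with ``psf_scale_no`` rounded from the
    PSF FWHM; ``max_scale_no`` defaults to ``psf_scale_no``.
    """
    if test.shape != ref.shape:
        raise ValueError(f"image shape mismatch: {test.shape} vs {ref.shape}")
    if test.pixel_size_nm != ref.pixel_size_nm:
        raise ValueError("test and reference pixel sizes differ")
    if params is None:
        if psf_fwhm_nm is None:
            raise ValueError("provide either params or psf_fwhm_nm")
        psf_scale_no = max(1, int(round(psf_fwhm_nm / test.pixel_size_nm)))
        params = ThresholdParams(psf_scale_no=psf_scale_no)
    if max_scale_no is None:
        max_scale_no = params.psf_scale_no
    if max_scale_no < 1:
        raise ValueError("max_scale_no must be >= 1")

    flat_t = flatten_intensity(test, flatten_percentile)
    flat_r = flatten_intensity(ref, flatten_percentile)

    results: list[ScaleResult] = []
    for scale_no in range(1, max_scale_no + 1):
        spec = ScaleSpec(scale_no, test.pixel_size_nm, params.psf_scale_no)
        bt = blur_fwhm_px(flat_t.pixels, spec.fwhm_px)
        br = blur_fwhm_px(flat_r.pixels, spec.fwhm_px)
        bt /= bt.max()
        br /= br.max()
        combined = bt + br
        combined /= combined.max()

        sharp_t = binarise(bt, adaptive_threshold(bt, spec, params, "sharpening"), spec)
        sharp_r = binarise(br, adaptive_threshold(br, spec, params, "sharpening"), spec)

        struct_bin_t = binarise(
            bt, adaptive_threshold(bt, spec, params, "structure"), spec, "structure"
        )
        struct_bin_r = binarise(
            br, adaptive_threshold(br, spec, params, "structure"), spec, "structure"
        )
        struct_t = reblur_skeleton(skeletonise(struct_bin_t), spec)
        struct_r = reblur_skeleton(skeletonise(struct_bin_r), spec)

        # correlation inputs: 0/1 sharpening masks and once-more-blurred skeletons
        struct_corr_t = blur_fwhm_px(struct_t, spec.fwhm_px)
        struct_corr_r = blur_fwhm_px(struct_r, spec.fwhm_px)
        pcc_sharp, def_sharp = local_pcc(sharp_t, sharp_r, scale_no, constant_policy="binary")
        pcc_str, def_str = local_pcc(struct_corr_t, struct_corr_r, scale_no)

        s_conf = confidence_score(pcc_sharp, pcc_str, confidence_full_threshold)
        conf_defined = def_sharp & def_str & (combined > 0)
        mean_conf = float(s_conf[conf_defined].mean()) if conf_defined.any() else float("nan")

        res = ScaleResult(
            scale=spec,
            sharp_test=sharp_t,
            sharp_ref=sharp_r,
            struct_test=struct_t,
            struct_ref=struct_r,
            pcc_sharp_local=pcc_sharp,
            pcc_str_local=pcc_str,
            defined_sharp=def_sharp,
            defined_struct=def_str,
            s_conf=s_conf,
            conf_defined=conf_defined,
            combined=combined,
            pcc_sharp_global=None,
            pcc_str_global=None,
            mean_conf=mean_conf,
        )
        res.pcc_sharp_global, res.pcc_str_global = global_metrics(res)
        if render:
            res.maps = {
                "sharpening": overlay_map(sharp_t, sharp_r),
                "structure": overlay_map(struct_t, struct_r),
                "confidence": confidence_map(combined, s_conf, conf_defined),
            }
        results.append(res)

    base = flat_t.pixels / flat_t.pixels.max() + flat_r.pixels / flat_r.pixels.max()
    base /= base.max()
    artefact = artefact_scale_map(
        [r.s_conf for r in results],
        [r.scale.scale_no for r in results],
        base,
        artefact_threshold,
    )
    return HawkmanRun(results, artefact, params, test.pixel_size_nm)
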