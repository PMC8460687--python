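"""Reconstruction image I/O, localisation-table rendering and preconditioning.

Both comparison inputs are reduced to a :class:`ReconstructionImage`: a 2D
grid of non-negative intensities with a known reconstruction pixel size in
nanometres.  Images can be loaded directly (TIFF/PNG) or rendered from a
localisation table (CSV with x/y in nm).  Preconditioning consists of
intensity flattening — capping hot pixels at a percentile of the nonzero
intensity histogram, which suppresses repeatedly sampled emitters — and
normalisation to a maximum of one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy.special import ndtr

logger = logging.getLogger(__name__)

#: ITU-R 601 luminance weights used when a colour image must be collapsed.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class ReconstructionImage:
    """A 2D super-resolution reconstruction with physical pixel size.

    Parameters
    ----------
    pixels
        2D array of finite, non-negative intensities (arbitrary units).
    pixel_size_nm
        Side of one reconstruction pixel in nanometres (> 0).
    name
        Free-text label used in log messages and error diagnostics.
    """

    pixels: np.ndarray
    pixel_size_nm: float
    name: str = ""

    def __post_init__(self) -> None:
        px = np.array(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(
                f"{self.name or 'image'}: expected a 2D image, got shape {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise ValueError(f"{self.name or 'image'}: non-finite intensities present")
        if (px < 0).any():
            i, j = map(int, np.argwhere(px < 0)[0])
            raise ValueError(
                f"{self.name or 'image'}: negative intensity at pixel ({i}, {j})"
            )
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "ReconstructionImage":
        """Copy carrying new pixel data but the same metadata."""
        return ReconstructionImage(pixels, self.pixel_size_nm, self.name)


def load_reconstruction(path, pixel_size_nm: float) -> ReconstructionImage:
    """Load a single-channel 2D TIFF or PNG as a :class:`ReconstructionImage`.

    Integer encodings are converted to float without rescaling (a 16-bit
    image with maximum 65535 loads with maximum 65535.0).  Multi-channel
    images are converted to luminance with a warning; multi-page TIFFs use
    the first page only, with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    if path.suffix.lower() in {".tif", ".tiff"}:
        with tifffile.TiffFile(path) as tf:
            arr = tf.pages[0].asarray()
            # a 3D page is a plane stack unless it clearly holds colour
            # channels in the last axis
            is_planes = arr.ndim == 3 and not (arr.shape[-1] in (3, 4) and arr.shape[0] > 4)
            if len(tf.pages) > 1 or is_planes:
                warnings.warn(
                    f"{path.name}: multi-page TIFF, using first page only",
                    stacklevel=2,
                )
                if is_planes:
                    arr = arr[0]
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        warnings.warn(
            f"{path.name}: multi-channel image converted to luminance", stacklevel=2
        )
        arr = arr[..., :3].astype(float) @ _LUMA
    if arr.ndim != 2:
        raise ValueError(f"{path.name}: expected 2D image data, got shape {arr.shape}")
    return ReconstructionImage(arr.astype(float), pixel_size_nm, name=path.stem)


def save_reconstruction(img: ReconstructionImage, path) -> None:
    """Write the intensity grid to TIFF, preserving the floating dtype."""
    tifffile.imwrite(str(path), np.asarray(img.pixels))


def save_rgb(rgb: np.ndarray, path) -> None:
    """Write an 8-bit RGB map to PNG or TIFF."""
    rgb = np.asarray(rgb)
    if rgb.dtype != np.uint8:
        rgb = np.clip(np.round(rgb), 0, 255).astype(np.uint8)
    iio.imwrite(str(path), rgb)


# ---------------------------------------------------------------------------
# Localisation tables
# ---------------------------------------------------------------------------

#: Canonical column names after parsing.
_CANONICAL = {"x": "x_nm", "y": "y_nm", "frame": "frame", "photons": "photons"}


def _canonical_key(name: str) -> str:
    """Normalise a CSV header name: case, whitespace, '[nm]' suffixes."""
    key = name.strip().lower()
    for junk in ("[nm]", "(nm)", "_nm", " nm"):
        key = key.replace(junk, "")
    return key.strip().strip("_ ")


def read_localisations(path) -> pd.DataFrame:
    """Read a localisation table from CSV.

    Columns ``x`` and ``y`` (in nm, case-insensitive, with or without a
    ``[nm]``/``_nm`` suffix) are mandatory; ``frame`` and ``photons`` are
    kept when present.  Returns a DataFrame with canonical columns
    ``x_nm``, ``y_nm`` (+ optional ``frame``, ``photons``).
    """
    df = pd.read_csv(path)
    rename = {}
    for col in df.columns:
        key = _canonical_key(str(col))
        if key in _CANONICAL:
            rename[col] = _CANONICAL[key]
    df = df.rename(columns=rename)
    for required in ("x_nm", "y_nm"):
        if required not in df.columns:
            raise ValueError(f"{path}: missing required localisation column {required!r}")
    keep = [c for c in ("x_nm", "y_nm", "frame", "photons") if c in df.columns]
    df = df[keep].copy()
    if len(df) and not np.all(np.isfinite(df[["x_nm", "y_nm"]].to_numpy(float))):
        raise ValueError(f"{path}: non-finite localisation coordinates")
    return df


def write_localisations(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def render_localisations(
    table: pd.DataFrame,
    pixel_size_nm: float,
    extent,
    mode: str = "histogram",
    sigma_nm: float | None = None,
    name: str = "",
) -> ReconstructionImage:
    """Render a localisation table to a reconstruction image.

    Parameters
    ----------
    table
        DataFrame with ``x_nm``/``y_nm`` columns (may be empty).
    extent
        Bounding box ``(xmin, xmax, ymin, ymax)`` in nm; must be
        non-degenerate.  Pixel ``(i, j)`` covers the half-open interval
        ``[xmin + j*ps, xmin + (j+1)*ps) x [ymin + i*ps, ymin + (i+1)*ps)``
        with the row index running along y.
    mode
        ``"histogram"`` counts localisations per pixel; ``"gaussian"`` adds
        one unit-integral Gaussian of standard deviation ``sigma_nm`` per
        localisation (pixel values are the Gaussian mass integrated over
        each pixel, so the image total approximates the localisation count).

    Localisations outside the extent are dropped; the count is logged.
    """
    xmin, xmax, ymin, ymax = (float(v) for v in extent)
    ps = float(pixel_size_nm)
    if not ps > 0:
        raise ValueError("pixel_size_nm must be positive")
    if not (xmax > xmin and ymax > ymin):
        raise ValueError(f"degenerate extent {extent!r}")
    nx = max(1, int(round((xmax - xmin) / ps)))
    ny = max(1, int(round((ymax - ymin) / ps)))

    if len(table):
        x = table["x_nm"].to_numpy(float)
        y = table["y_nm"].to_numpy(float)
    else:
        x = np.empty(0)
        y = np.empty(0)
    inside = (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)
    dropped = int((~inside).sum())
    if dropped:
        logger.info("render_localisations: dropped %d localisations outside extent", dropped)
    x, y = x[inside], y[inside]

    img = np.zeros((ny, nx))
    if mode == "histogram":
        ix = np.floor((x - xmin) / ps).astype(int)
        iy = np.floor((y - ymin) / ps).astype(int)
        # rounding of nx/ny can leave the last sliver outside the grid
        keep = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        np.add.at(img, (iy[keep], ix[keep]), 1.0)
    elif mode == "gaussian":
        if sigma_nm is None or not sigma_nm > 0:
            raise ValueError("gaussian mode requires a positive sigma_nm")
        s_px = sigma_nm / ps
        half = int(np.ceil(6.0 * s_px)) + 1
        cx = (x - xmin) / ps
        cy = (y - ymin) / ps
        for px_c, py_c in zip(cx, cy):
            j0 = max(0, int(np.floor(px_c)) - half)
            j1 = min(nx, int(np.floor(px_c)) + half + 1)
            i0 = max(0, int(np.floor(py_c)) - half)
            i1 = min(ny, int(np.floor(py_c)) + half + 1)
            if j0 >= j1 or i0 >= i1:
                continue
            ex = np.arange(j0, j1 + 1, dtype=float)
            ey = np.arange(i0, i1 + 1, dtype=float)
            wx = np.diff(ndtr((ex - px_c) / s_px))
            wy = np.diff(ndtr((ey - py_c) / s_px))
            img[i0:i1, j0:j1] += np.outer(wy, wx)
    else:
        raise ValueError(f"unknown rendering mode {mode!r}")
    return ReconstructionImage(img, ps, name=name or "rendered")


# ---------------------------------------------------------------------------
# Preconditioning
# ---------------------------------------------------------------------------


def flatten_intensity(
    img: ReconstructionImage, percentile: float = 98.0
) -> ReconstructionImage:
    """Cap intensities at a percentile of the *nonzero* intensity histogram.

    Repeated appearances of single emitters produce isolated very bright
    pixels; capping them stabilises the downstream adaptive thresholding.
    Zero-valued pixels are excluded from the histogram and left unchanged.
    The percentile is the linear-interpolation percentile of the sorted
    nonzero intensities.
    """
    if not 0 < percentile <= 100:
        raise ValueError("percentile must lie in (0, 100]")
    nonzero = img.pixels[img.pixels > 0]
    if nonzero.size == 0:
        raise ValueError(f"{img.name or 'image'}: no structure to assess (all-zero image)")
    cap = float(np.percentile(nonzero, percentile))
    return img.with_pixels(np.minimum(img.pixels, cap))


def normalise_max(img: ReconstructionImage) -> ReconstructionImage:
    """Divide by the maximum intensity so the result has maximum exactly 1."""
    m = float(img.pixels.max())
    if not m > 0:
        raise ValueError(f"{img.name or 'image'}: cannot normalise an all-zero image")
    return img.with_pixels(img.pixels / m)
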