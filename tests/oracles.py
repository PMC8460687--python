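"""Brute-force reference implementations used as independent oracles.

Everything here is written as directly as possible (explicit double loops,
dense convolution) and deliberately shares no code with the package.
"""

from __future__ import annotations

import numpy as np


def window_mean_bruteforce(img: np.ndarray, radius: int) -> np.ndarray:
    """Mean over the (2r+1)^2 window, truncated at the borders."""
    h, w = img.shape
    out = np.empty_like(img, dtype=float)
    for i in range(h):
        for j in range(w):
            i0, i1 = max(0, i - radius), min(h, i + radius + 1)
            j0, j1 = max(0, j - radius), min(w, j + radius + 1)
            out[i, j] = img[i0:i1, j0:j1].mean()
    return out


def adaptive_threshold_bruteforce(
    img: np.ndarray,
    r: int,
    r_prime: int,
    c_b: float,
    c_a: float,
    aux_coeff: float,
) -> np.ndarray:
    return (
        c_b * window_mean_bruteforce(img, r)
        + aux_coeff * window_mean_bruteforce(img, r_prime)
        + c_a
    )


def local_pcc_bruteforce(
    a: np.ndarray, b: np.ndarray, window_px: int
) -> tuple[np.ndarray, np.ndarray]:
    """Textbook windowed Pearson correlation with truncated borders."""
    side = max(int(window_px), 3)
    if side % 2 == 0:
        side -= 1
    radius = side // 2
    h, w = a.shape
    pcc = np.full((h, w), np.nan)
    defined = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            i0, i1 = max(0, i - radius), min(h, i + radius + 1)
            j0, j1 = max(0, j - radius), min(w, j + radius + 1)
            wa = a[i0:i1, j0:j1].ravel()
            wb = b[i0:i1, j0:j1].ravel()
            da = wa - wa.mean()
            db = wb - wb.mean()
            va = (da * da).mean()
            vb = (db * db).mean()
            if va <= 1e-12 or vb <= 1e-12:
                continue
            defined[i, j] = True
            pcc[i, j] = (da * db).mean() / np.sqrt(va * vb)
    return pcc, defined


def global_pcc_bruteforce(a: np.ndarray, b: np.ndarray) -> float | None:
    a = a.ravel().astype(float)
    b = b.ravel().astype(float)
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt((da * da).sum() * (db * db).sum())
    if denom == 0:
        return None
    return float((da * db).sum() / denom)


def gaussian_blur_bruteforce(img: np.ndarray, fwhm_px: float, truncate: float = 4.0) -> np.ndarray:
    """Dense 2D convolution with a truncated sampled Gaussian kernel.

    The kernel is the outer product of the 1D kernel scipy samples
    (radius int(truncate*sigma + 0.5)); zero padding is compensated by
    dividing by the convolution of a ones image (border renormalisation).
    """
    sigma = fwhm_px / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    lw = int(truncate * sigma + 0.5)
    x = np.arange(-lw, lw + 1, dtype=float)
    k1 = np.exp(-0.5 * (x / sigma) ** 2)
    k1 /= k1.sum()
    kernel = np.outer(k1, k1)

    def conv(z):
        h, w = z.shape
        padded = np.zeros((h + 2 * lw, w + 2 * lw))
        padded[lw : lw + h, lw : lw + w] = z
        out = np.empty((h, w))
        for i in range(h):
            for j in range(w):
                out[i, j] = (padded[i : i + 2 * lw + 1, j : j + 2 * lw + 1] * kernel).sum()
        return out

    return conv(img) / conv(np.ones_like(img))


def percentile_linear_bruteforce(values: np.ndarray, q: float) -> float:
    """Linear-interpolation percentile of sorted values (direct formula)."""
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 1:
        return float(v[0])
    pos = (q / 100.0) * (len(v) - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, len(v) - 1)
    frac = pos - lo
    return float(v[lo] * (1 - frac) + v[hi] * frac)
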