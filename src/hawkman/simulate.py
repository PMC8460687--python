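"""Synthetic paired test/reference reconstructions with controllable bias.

Emulates, at the localisation level, the failure mode the comparison is
built to detect: when the fluorescence profiles of two active emitters
overlap within a PSF width in the same frame, fitting algorithms localise
them towards their mutual centre.  Biased localisations show reduced
scatter ("artificial sharpening") and adjacent structures collapse towards
their midline.  The generator places ground-truth emitters on a 10 nm grid
along a chosen structure, samples blinking appearances (Poisson number of
appearances per emitter, each jittered by the localisation precision and
stamped with a random frame), and then optionally pulls a fraction of
appearances with same-frame neighbours inside the PSF FWHM towards the
centroid of those overlapping appearances.

The reference table is the unbiased sampling at a slightly degraded
precision, emulating a HAWK-preprocessed reconstruction; the test table is
the biased sampling at nominal precision.  Both are rendered at the
reconstruction pixel size.  Defaults follow common simulation practice for
this problem: a 270 nm Gaussian PSF, labelling density 100 per micron along
line structures, an average of five appearances per emitter, and 10 nm
reconstruction pixels.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from hawkman.recon_io import ReconstructionImage, render_localisations, write_localisations, save_reconstruction

STRUCTURES = ("line_pair", "crossing", "ring", "sarcomere")


@dataclass(frozen=True)
class SimulationConfig:
    """Geometry, labelling, blinking and bias parameters of one fixture.

    Length units are nm.  ``bias_fraction`` is the probability that an
    appearance with a same-frame neighbour within the PSF FWHM is biased;
    ``bias_pull`` is how far (0..1) such an appearance moves towards the
    local centroid.  ``precision_ref_nm`` is deliberately worse than
    ``precision_test_nm`` by default, emulating the small precision loss a
    HAWK reference incurs.  A fixed seed gives bit-identical output.
    """

    structure: str = "line_pair"
    separation_nm: float = 100.0
    line_width_nm: float = 0.0
    angle_deg: float = 90.0
    diameter_nm: float = 500.0
    rim_width_nm: float = 0.0
    centre_spacing_nm: float = 60.0
    field_size_nm: float = 2000.0
    labelling_density_per_um: float = 100.0
    appearances_mean: float = 5.0
    n_frames: int = 100
    precision_ref_nm: float = 25.0
    precision_test_nm: float = 15.0
    bias_fraction: float = 0.0
    bias_pull: float = 0.5
    psf_fwhm_nm: float = 270.0
    recon_pixel_nm: float = 10.0
    grid_nm: float = 10.0
    render_mode: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}; choose from {STRUCTURES}")
        for name in (
            "field_size_nm",
            "psf_fwhm_nm",
            "recon_pixel_nm",
            "grid_nm",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.bias_fraction <= 1.0:
            raise ValueError("bias_fraction must lie in [0, 1]")
        if self.labelling_density_per_um < 0 or self.appearances_mean < 0:
            raise ValueError("density and appearances_mean must be >= 0")
        if self.structure == "sarcomere" and self.line_width_nm == 0.0:
            object.__setattr__(self, "line_width_nm", 20.0)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (0.0, self.field_size_nm, 0.0, self.field_size_nm)


def _snap(values: np.ndarray, grid: float) -> np.ndarray:
    return np.round(values / grid) * grid


def _line_emitters(
    x_centre: float, y0: float, y1: float, width_nm: float, config: SimulationConfig
) -> np.ndarray:
    """Emitters along a vertical line of the given width.

    A line of width w occupies round(w / grid) + 1 adjacent grid columns,
    each labelled along its length at the configured linear density.
    """
    grid = config.grid_nm
    n_cols = int(round(width_nm / grid)) + 1
    offsets = (np.arange(n_cols) - (n_cols - 1) / 2.0) * grid
    length_um = (y1 - y0) / 1000.0
    n_per_col = int(round(config.labelling_density_per_um * length_um))
    if n_per_col <= 0:
        return np.empty((0, 2))
    ys = _snap(y0 + (np.arange(n_per_col) + 0.5) * (y1 - y0) / n_per_col, grid)
    pts = []
    for dx in offsets:
        x = _snap(np.full(n_per_col, x_centre + dx), grid)
        pts.append(np.column_stack([x, ys]))
    return np.concatenate(pts)


def place_emitters(config: SimulationConfig) -> np.ndarray:
    """Ground-truth emitter positions (nm) on a 10 nm grid along the structure.

    Linear structures are labelled at ``labelling_density_per_um`` along
    their length (per grid column for lines of nonzero width; along the
    perimeter of each rim ring for rings), so the emitter count is
    reproducible from density x structure length to within one.
    """
    f = config.field_size_nm
    margin = 0.1 * f
    y0, y1 = margin, f - margin
    cx = f / 2.0

    if config.structure in ("line_pair", "sarcomere"):
        sep = config.separation_nm if config.structure == "line_pair" else config.centre_spacing_nm
        if sep >= f - 2 * margin:
            raise ValueError("structure larger than field")
        pts = np.concatenate(
            [
                _line_emitters(cx - sep / 2.0, y0, y1, config.line_width_nm, config),
                _line_emitters(cx + sep / 2.0, y0, y1, config.line_width_nm, config),
            ]
        )
    elif config.structure == "crossing":
        half_angle = np.deg2rad(config.angle_deg) / 2.0
        half_len = (y1 - y0) / 2.0
        t_um = 2 * half_len / 1000.0
        n = int(round(config.labelling_density_per_um * t_um))
        if n <= 0:
            return np.empty((0, 2))
        t = (np.arange(n) + 0.5) * (2 * half_len) / n - half_len
        pts = []
        for sgn in (-1.0, 1.0):
            dx = np.sin(half_angle) * sgn
            dy = np.cos(half_angle)
            x = _snap(cx + t * dx, config.grid_nm)
            y = _snap(f / 2.0 + t * dy, config.grid_nm)
            pts.append(np.column_stack([x, y]))
        pts = np.concatenate(pts)
    elif config.structure == "ring":
        radius = config.diameter_nm / 2.0
        if config.diameter_nm >= f - 2 * margin:
            raise ValueError("structure larger than field")
        n_rims = int(round(config.rim_width_nm / config.grid_nm)) + 1
        radii = radius + (np.arange(n_rims) - (n_rims - 1) / 2.0) * config.grid_nm
        pts = []
        for r in radii:
            perim_um = 2 * np.pi * r / 1000.0
            n = int(round(config.labelling_density_per_um * perim_um))
            if n <= 0:
                continue
            theta = (np.arange(n) + 0.5) * 2 * np.pi / n
            x = _snap(cx + r * np.cos(theta), config.grid_nm)
            y = _snap(f / 2.0 + r * np.sin(theta), config.grid_nm)
            pts.append(np.column_stack([x, y]))
        pts = np.concatenate(pts) if pts else np.empty((0, 2))
    else:  # pragma: no cover - guarded by SimulationConfig
        raise ValueError(config.structure)

    inside = (
        (pts[:, 0] >= 0)
        & (pts[:, 0] < f)
        & (pts[:, 1] >= 0)
        & (pts[:, 1] < f)
    )
    if not inside.all():
        raise ValueError("structure larger than field")
    return pts


def sample_appearances(
    emitters: np.ndarray,
    config: SimulationConfig,
    precision_nm: float | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sample blinking appearances of the ground-truth emitters.

    Each emitter appears a Poisson(``appearances_mean``) number of times,
    each appearance on a uniformly random frame and jittered by an
    isotropic Gaussian localisation error of ``precision_nm`` (defaults to
    the test precision).  Returns a localisation table with columns
    ``x_nm``, ``y_nm``, ``frame``, ``emitter_id``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if precision_nm is None:
        precision_nm = config.precision_test_nm
    emitters = np.asarray(emitters, dtype=float).reshape(-1, 2)
    counts = rng.poisson(config.appearances_mean, size=len(emitters))
    total = int(counts.sum())
    ids = np.repeat(np.arange(len(emitters)), counts)
    pos = emitters[ids]
    frames = rng.integers(0, max(1, config.n_frames), size=total)
    if precision_nm > 0:
        pos = pos + rng.normal(0.0, precision_nm, size=(total, 2))
    else:
        pos = pos.copy()
    return pd.DataFrame(
        {
            "x_nm": pos[:, 0],
            "y_nm": pos[:, 1],
            "frame": frames.astype(int),
            "emitter_id": ids.astype(int),
        }
    )


def apply_sharpening_bias(
    table: pd.DataFrame,
    emitters: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Pull overlapping same-frame appearances towards their mutual centre.

    For each appearance with at least one same-frame neighbour within the
    PSF FWHM, with probability ``bias_fraction`` the localisation moves a
    ``bias_pull`` fraction of the way towards the centroid of all
    same-frame appearances inside that radius (itself included) — for an
    isolated pair this is the pairwise midpoint.  Distances and centroids
    use the unbiased positions; all other records are unchanged.  This is
    the density-induced fitting bias the comparison is built to detect: an
    algorithm fitting overlapping fluorescence profiles localises them
    towards the centre of the combined profile.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    out = table.copy()
    if config.bias_fraction <= 0.0 or len(table) < 2:
        return out
    xy = out[["x_nm", "y_nm"]].to_numpy(float)
    new_xy = xy.copy()
    frames = out["frame"].to_numpy(int) if "frame" in out else np.zeros(len(out), int)
    for frame in np.unique(frames):
        idx = np.flatnonzero(frames == frame)
        if len(idx) < 2:
            continue
        pts = xy[idx]
        tree = cKDTree(pts)
        balls = tree.query_ball_point(pts, config.psf_fwhm_nm)
        draws = rng.random(len(idx))
        for k, members in enumerate(balls):
            if len(members) < 2 or draws[k] >= config.bias_fraction:
                continue
            centroid = pts[members].mean(axis=0)
            new_xy[idx[k]] = pts[k] + config.bias_pull * (centroid - pts[k])
    out[["x_nm", "y_nm"]] = new_xy
    return out


@dataclass
class FixturePair:
    test: ReconstructionImage
    reference: ReconstructionImage
    truth: np.ndarray
    table_test: pd.DataFrame
    table_ref: pd.DataFrame
    manifest: dict


def _image_hash(img: ReconstructionImage) -> str:
    return hashlib.sha256(np.ascontiguousarray(img.pixels).tobytes()).hexdigest()


def generate_fixture(config: SimulationConfig) -> FixturePair:
    """Generate a paired test/reference fixture with ground truth.

    One seeded random stream drives the whole generation (reference
    sampling, then test sampling, then bias), so a fixed seed gives
    bit-identical tables and images.  The reference is the unbiased table
    at ``precision_ref_nm``; the test is the biased table at
    ``precision_test_nm``.  Rendering defaults to per-localisation
    Gaussians of sigma equal to the respective precision (the standard
    rendering of fitted localisations); ``render_mode="histogram"`` bins
    counts instead.
    """
    rng = np.random.default_rng(config.seed)
    truth = place_emitters(config)

    table_ref = sample_appearances(truth, config, config.precision_ref_nm, rng)
    table_test = sample_appearances(truth, config, config.precision_test_nm, rng)
    table_test = apply_sharpening_bias(table_test, truth, config, rng)

    def _render(table, precision_nm, name):
        if config.render_mode == "gaussian":
            sigma = max(precision_nm, config.recon_pixel_nm / 2.0)
            return render_localisations(
                table, config.recon_pixel_nm, config.extent, "gaussian", sigma, name
            )
        return render_localisations(
            table, config.recon_pixel_nm, config.extent, "histogram", name=name
        )

    test = _render(table_test, config.precision_test_nm, "test")
    reference = _render(table_ref, config.precision_ref_nm, "reference")

    manifest = {
        "config": asdict(config),
        "n_emitters": int(len(truth)),
        "n_appearances_test": int(len(table_test)),
        "n_appearances_ref": int(len(table_ref)),
        "hash_test": _image_hash(test),
        "hash_reference": _image_hash(reference),
    }
    return FixturePair(test, reference, truth, table_test, table_ref, manifest)


def write_fixture(pair: FixturePair, out_dir) -> Path:
    """Write test.tif, reference.tif, truth.csv, both tables and manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_reconstruction(pair.test, out / "test.tif")
    save_reconstruction(pair.reference, out / "reference.tif")
    pd.DataFrame(pair.truth, columns=["x_nm", "y_nm"]).to_csv(out / "truth.csv", index=False)
    write_localisations(pair.table_test, out / "table_test.csv")
    write_localisations(pair.table_ref, out / "table_ref.csv")
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(pair.manifest, indent=2, sort_keys=True) + "\n")
    return manifest_path
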