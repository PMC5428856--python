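"""Synthetic data: calibration z scans, test movies and error scoring.

The simulated study conditions follow typical astigmatism-based 3D
single-molecule imaging: 4000 photons per localization over a constant
background of 100 photons per pixel, 600 nm emission, 160 nm camera
pixels, pure Poisson shot noise with no camera read noise, and emitter z
positions within +-300 nm of focus where astigmatic localization is
precise.

Calibration movies place 4x up-sampled PSFs on an xy grid, scan z, and
block-sum down-sample by 4; test movies place emitters at arbitrary
sub-pixel positions using the spline model itself.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .fit import crlb
from .splines import EmitterParams, SplinePSF
from .stack import PSFStack

__all__ = [
    "GroundTruth",
    "uniform_emitters",
    "make_calibration_movie",
    "render_movie",
    "match_and_score",
]

DEFAULT_PHOTONS = 4000.0
DEFAULT_BACKGROUND = 100.0


@dataclasses.dataclass
class GroundTruth:
    """Known emitter positions behind a simulated movie."""

    frame: np.ndarray    # int, frame index per emitter
    x: np.ndarray        # px
    y: np.ndarray        # px
    z: np.ndarray        # nm
    photons: np.ndarray
    background: float
    pixel_size: float = 160.0
    wavelength: float = 600.0
    shape: tuple = (64, 64)
    n_frames: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("frame", "x", "y", "z", "photons"):
            setattr(self, name, np.asarray(getattr(self, name)))
        n = self.x.size
        if any(getattr(self, k).size != n for k in ("frame", "y", "z", "photons")):
            raise ValueError("ground-truth columns must have equal length")
        if np.any(self.photons <= 0):
            raise ValueError("photons must be positive")
        h, w = self.shape
        if np.any((self.x < 0) | (self.x > w - 1) | (self.y < 0)
                  | (self.y > h - 1)):
            raise ValueError("emitters must lie within the frame bounds")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": self.frame, "x": self.x, "y": self.y, "z": self.z,
            "photons": self.photons,
        })


def uniform_emitters(n: int, shape=(64, 64), n_frames: int = 1,
                     z_range: float = 300.0,
                     photons: float = DEFAULT_PHOTONS,
                     background: float = DEFAULT_BACKGROUND,
                     margin: float = 10.0, min_separation: float = 10.0,
                     pixel_size: float = 160.0, seed: int = 0,
                     max_tries: int = 10000) -> GroundTruth:
    """Random well-separated emitters, z uniform in +-``z_range`` nm.

    Emitters are spread uniformly across frames; within a frame a minimum
    pairwise separation is enforced by rejection sampling.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    xs, ys, zs, frames = [], [], [], []
    per_frame: dict[int, list] = {f: [] for f in range(n_frames)}
    tries = 0
    while len(xs) < n and tries < max_tries:
        tries += 1
        f = int(rng.integers(n_frames))
        x = rng.uniform(margin, w - 1 - margin)
        y = rng.uniform(margin, h - 1 - margin)
        if any(np.hypot(x - px, y - py) < min_separation
               for px, py in per_frame[f]):
            continue
        per_frame[f].append((x, y))
        xs.append(x)
        ys.append(y)
        zs.append(rng.uniform(-z_range, z_range))
        frames.append(f)
    if len(xs) < n:
        raise ValueError("could not place the requested emitter count; "
                         "reduce the density or separation")
    return GroundTruth(frame=np.array(frames), x=np.array(xs),
                       y=np.array(ys), z=np.array(zs),
                       photons=np.full(n, float(photons)),
                       background=float(background), pixel_size=pixel_size,
                       shape=shape, n_frames=n_frames, seed=seed)


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

def _add_emitter(frame: np.ndarray, spline_psf: SplinePSF, x: float,
                 y: float, z: float, photons: float) -> None:
    """Add one emitter's spline model into a frame, clipped at the edges."""
    size = int(round(spline_psf.support_pixels))
    half = size // 2
    ax, ay = int(np.floor(x)) - half + 1, int(np.floor(y)) - half + 1
    params = EmitterParams(x=x - ax, y=y - ay, z=z, h=photons, b=0.0)
    roi = np.clip(spline_psf.model_image(params, (size, size)), 0.0, None)
    h, w = frame.shape
    y0, y1 = max(ay, 0), min(ay + size, h)
    x0, x1 = max(ax, 0), min(ax + size, w)
    if y1 <= y0 or x1 <= x0:
        raise ValueError(f"emitter at ({x:.1f}, {y:.1f}) lies outside the "
                         "placeable range")
    frame[y0:y1, x0:x1] += roi[y0 - ay:y1 - ay, x0 - ax:x1 - ax]


def render_movie(truth: GroundTruth, spline_psf: SplinePSF,
                 noise: bool = True, seed: int | None = None) -> np.ndarray:
    """Render a movie from ground truth: background + emitters (+ Poisson).

    The expected image is the constant background plus each emitter's
    spline model at its sub-pixel position; with ``noise`` every pixel is
    an independent Poisson draw, reproducible from ``seed``.
    """
    if noise and seed is None:
        raise ValueError("a seed is required when noise is on")
    movie = np.zeros((truth.n_frames, *truth.shape))
    movie += truth.background
    for f, x, y, z, ph in zip(truth.frame, truth.x, truth.y, truth.z,
                              truth.photons):
        _add_emitter(movie[int(f)], spline_psf, float(x), float(y), float(z),
                     float(ph))
    if noise:
        rng = np.random.default_rng(seed)
        movie = rng.poisson(movie).astype(float)
    return movie


def make_calibration_movie(psf_4x: PSFStack, grid_spacing: int,
                           n_grid: int = 3, photons: float = 1e6,
                           background: float = 0.0
                           ) -> tuple[np.ndarray, GroundTruth]:
    """High-count z-scan calibration movie from a 4x up-sampled PSF.

    The 4x-sampled PSF is placed on an ``n_grid`` x ``n_grid`` xy grid of
    integer camera-pixel positions (``grid_spacing`` px apart), one frame
    per z slice; each frame is then down-sampled by summing 4x4 pixel
    blocks, which conserves the total intensity exactly.  The frames are
    noise-free; photon counts are high by construction.
    """
    up = psf_4x.data
    nz, ny, nx = up.shape
    if nx % 4 != 1 and nx % 4 != 0:
        pass  # any size is fine; placement is by the array corner
    support_px = int(np.ceil(nx / 4.0))
    if grid_spacing < support_px + 2:
        raise ValueError("grid spacing must exceed the PSF support + margin")
    margin_px = support_px // 2 + 2
    side = 2 * margin_px + (n_grid - 1) * grid_spacing + 1
    frame_hr = np.zeros((side * 4, side * 4))
    xs, ys = [], []
    for gy in range(n_grid):
        for gx in range(n_grid):
            cx = margin_px + gx * grid_spacing
            cy = margin_px + gy * grid_spacing
            xs.append(float(cx))
            ys.append(float(cy))

    movie = np.empty((nz, side, side))
    for f in range(nz):
        frame_hr[:] = 0.0
        for cx, cy in zip(xs, ys):
            # center the 4x PSF on the camera pixel center
            ax = 4 * int(cx) + 2 - nx // 2
            ay = 4 * int(cy) + 2 - ny // 2
            frame_hr[ay:ay + ny, ax:ax + nx] += photons * up[f]
        movie[f] = frame_hr.reshape(side, 4, side, 4).sum(axis=(1, 3))
        movie[f] += background

    n_emitters = len(xs)
    truth = GroundTruth(
        frame=np.repeat(np.arange(nz), n_emitters),
        x=np.tile(np.array(xs), nz),
        y=np.tile(np.array(ys), nz),
        z=np.repeat(psf_4x.z_positions, n_emitters),
        photons=np.full(nz * n_emitters, photons),
        background=background, pixel_size=psf_4x.pixel_size * 4,
        shape=(side, side), n_frames=nz)
    return movie, truth


# --------------------------------------------------------------------------
# Scoring
# --------------------------------------------------------------------------

def match_and_score(found: pd.DataFrame, truth: GroundTruth,
                    z_bin_width: float = 100.0,
                    match_radius_px: float = 2.0,
                    spline_psf: SplinePSF | None = None) -> dict:
    """Match localizations to their nearest ground-truth emitter and score.

    ``found`` needs columns frame, x, y (px) and z (nm).  Each localization
    is matched to the nearest true emitter in its frame (xy Euclidean);
    matches farther than ``match_radius_px`` count as false positives.
    Per-axis mean absolute errors (nm) are reported overall and binned by
    true z in ``z_bin_width`` bins; when a spline model is supplied the
    CRLB at each bin center is included for overlay.
    """
    if len(found) == 0 or truth.x.size == 0:
        raise ValueError("found and truth must both be non-empty")
    px = truth.pixel_size
    rows = []
    fp = 0
    for f, grp in found.groupby("frame"):
        sel = truth.frame == f
        tx, ty, tz = truth.x[sel], truth.y[sel], truth.z[sel]
        if tx.size == 0:
            fp += len(grp)
            continue
        for _, loc in grp.iterrows():
            d2 = (loc.x - tx) ** 2 + (loc.y - ty) ** 2
            j = int(np.argmin(d2))
            if np.sqrt(d2[j]) > match_radius_px:
                fp += 1
                continue
            rows.append({
                "true_z": tz[j],
                "dx_nm": abs(loc.x - tx[j]) * px,
                "dy_nm": abs(loc.y - ty[j]) * px,
                "dz_nm": abs(loc.z - tz[j]),
            })
    matched = pd.DataFrame(rows)
    result = {
        "n_matched": len(matched),
        "n_false_positive": fp,
        "recall": len(matched) / truth.x.size,
        "mean_dx_nm": float(matched.dx_nm.mean()) if len(matched) else np.nan,
        "mean_dy_nm": float(matched.dy_nm.mean()) if len(matched) else np.nan,
        "mean_dz_nm": float(matched.dz_nm.mean()) if len(matched) else np.nan,
    }
    if len(matched):
        bins = np.round(matched.true_z / z_bin_width) * z_bin_width
        per_bin = matched.groupby(bins).agg(
            n=("dx_nm", "size"), dx_nm=("dx_nm", "mean"),
            dy_nm=("dy_nm", "mean"), dz_nm=("dz_nm", "mean"))
        per_bin.index.name = "z_bin_nm"
        if spline_psf is not None:
            size = int(round(spline_psf.support_pixels))
            c = (size - 1) / 2.0
            crlbs = []
            for zc in per_bin.index:
                zc = float(np.clip(zc, spline_psf.z_min + 1,
                                   spline_psf.z_max - 1))
                r = crlb(spline_psf, c, c, zc, float(truth.photons.mean()),
                         truth.background, (size, size))
                crlbs.append((r.x_nm, r.y_nm, r.z_nm))
            per_bin[["crlb_x_nm", "crlb_y_nm", "crlb_z_nm"]] = crlbs
        result["per_bin"] = per_bin.reset_index()
    return result
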