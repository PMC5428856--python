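"""Per-frame analysis: find, fit and book-keep emitters.

Implements the iterative per-frame algorithm: estimate the background,
find peaks in the background-subtracted image by convolving with the
spline PSF at one or more z planes, fit every localization with damped
Gauss–Newton updates while all the others stay fixed (cross-terms between
overlapping emitters are deliberately ignored), discard localizations with
a brighter neighbor closer than a minimum distance (re-flagging their
neighbors as unconverged), re-estimate the background on the
localization-subtracted image, and repeat until no new peaks appear or the
repeat cap is reached.

The engine is deterministic: there is no randomness anywhere in it.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.ndimage import gaussian_filter, maximum_filter
from scipy.signal import fftconvolve

from .config import AnalysisConfig
from .fit import Localization, LMState, lm_init, lm_step, SplineFitModel
from .splines import EmitterParams, OutOfSupportError, SplinePSF

__all__ = [
    "estimate_background",
    "PeakCandidate",
    "find_peaks",
    "proximity_filter",
    "FrameState",
    "analyze_frame",
    "analyze_movie",
]

log = logging.getLogger(__name__)


def estimate_background(image: np.ndarray, sigma: float = 8.0) -> np.ndarray:
    """Smooth non-negative background field (wide Gaussian smoothing).

    On a constant image this returns that constant everywhere.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    return np.clip(gaussian_filter(image, sigma, mode="nearest"), 0.0, None)


@dataclasses.dataclass
class PeakCandidate:
    """A local maximum of the PSF-convolved residual image."""

    x: int
    y: int
    z: float      # nm, z of the convolution plane it arose from
    value: float  # convolved-image value (significance score)
    amplitude: float  # matched-filter height estimate, photons


def _finding_kernel(spline_psf: SplinePSF, z: float) -> np.ndarray:
    size = int(round(spline_psf.support_pixels))
    center = (size - 1) / 2.0
    z = float(np.clip(z, spline_psf.z_min, spline_psf.z_max))
    img = spline_psf.model_image(
        EmitterParams(x=center, y=center, z=z, h=1.0, b=0.0), (size, size))
    img = np.clip(img, 0.0, None)
    total = img.sum()
    return img / total if total > 0 else img


def find_peaks(residual: np.ndarray, spline_psf: SplinePSF, z_values,
               threshold: float, background_level: float
               ) -> list[PeakCandidate]:
    """Peak candidates from the PSF-convolved background-subtracted image.

    The residual is correlated with the unit-sum spline PSF at each
    requested z plane; candidates are strict local maxima of the resulting
    plane stack (3D maxima when several planes are used) whose value
    exceeds ``threshold`` times the expected shot-noise standard deviation
    of the convolved background.
    """
    z_values = np.atleast_1d(np.asarray(z_values, dtype=float))
    if z_values.size == 0:
        raise ValueError("need at least one z plane for finding")
    residual = np.asarray(residual, dtype=float)
    planes, k2sums = [], []
    for z in z_values:
        kern = _finding_kernel(spline_psf, z)
        planes.append(fftconvolve(residual, kern[::-1, ::-1], mode="same"))
        k2sums.append(float((kern**2).sum()))
    stack = np.stack(planes)
    sigma = np.sqrt(max(background_level, 1e-6) * np.asarray(k2sums))
    footprint = np.ones((3, 3, 3) if stack.shape[0] > 1 else (1, 3, 3))
    is_max = (stack == maximum_filter(stack, footprint=footprint,
                                      mode="nearest"))
    above = stack > sigma[:, None, None] * threshold
    out = []
    for zi, yi, xi in zip(*np.nonzero(is_max & above)):
        value = float(stack[zi, yi, xi])
        out.append(PeakCandidate(x=int(xi), y=int(yi), z=float(z_values[zi]),
                                 value=value,
                                 amplitude=value / k2sums[zi]))
    out.sort(key=lambda c: -c.value)
    return out


# --------------------------------------------------------------------------
# Frame state
# --------------------------------------------------------------------------

@dataclasses.dataclass
class _ActiveFit:
    """One localization being fitted within a frame."""

    anchor: tuple[int, int]        # (ax, ay) ROI corner in frame pixels
    state: LMState
    status: str                    # 'running' | 'converged' | 'failed'
    roi_model: np.ndarray          # cached h * spline image (baseline excluded)

    @property
    def x(self) -> float:
        return self.anchor[0] + self.state.p[1]

    @property
    def y(self) -> float:
        return self.anchor[1] + self.state.p[2]

    @property
    def photons(self) -> float:
        return float(self.state.p[0])


class FrameState:
    """Book-keeping for one frame's analysis.

    Maintains ``image = residual + background + sum(models)`` exactly: the
    residual is updated incrementally whenever a localization's model
    changes, and :meth:`check_conservation` verifies the identity.
    """

    def __init__(self, image: np.ndarray, background: np.ndarray):
        self.image = np.asarray(image, dtype=float)
        self.background = np.asarray(background, dtype=float)
        self.model_sum = np.zeros_like(self.image)
        self.fits: list[_ActiveFit] = []
        self.repeats = 0

    @property
    def residual(self) -> np.ndarray:
        return self.image - self.background - self.model_sum

    def check_conservation(self, atol: float = 1e-6) -> bool:
        recon = self.residual + self.background + self.model_sum
        return bool(np.allclose(recon, self.image, atol=atol))

    def roi_slices(self, fit: _ActiveFit) -> tuple[slice, slice]:
        ax, ay = fit.anchor
        ry, rx = fit.roi_model.shape
        return slice(ay, ay + ry), slice(ax, ax + rx)

    def add_model(self, fit: _ActiveFit) -> None:
        sy, sx = self.roi_slices(fit)
        self.model_sum[sy, sx] += fit.roi_model

    def remove_model(self, fit: _ActiveFit) -> None:
        sy, sx = self.roi_slices(fit)
        self.model_sum[sy, sx] -= fit.roi_model

    def all_converged(self) -> bool:
        return all(f.status != "running" for f in self.fits)


def proximity_filter(fits: list, min_distance: float) -> tuple[list, list]:
    """Discard localizations with a brighter neighbor closer than the cutoff.

    For every localization with a strictly brighter neighbor within
    ``min_distance`` (Euclidean, xy pixels) the localization is discarded
    and all its neighbors within the cutoff are re-marked unconverged.
    Equal heights are tied-broken by discarding the later-found one.
    Returns ``(kept, discarded)``.
    """
    if min_distance <= 0:
        raise ValueError("min_distance must be positive")
    n = len(fits)
    xs = np.array([f.x for f in fits])
    ys = np.array([f.y for f in fits])
    hs = np.array([f.photons for f in fits])
    discard = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if np.hypot(xs[i] - xs[j], ys[i] - ys[j]) >= min_distance:
                continue
            brighter = hs[j] > hs[i] or (hs[j] == hs[i] and j < i)
            if brighter:
                discard[i] = True
                break
    for i in np.nonzero(discard)[0]:
        for j in range(n):
            if j == i or discard[j]:
                continue
            if np.hypot(xs[i] - xs[j], ys[i] - ys[j]) < min_distance:
                if getattr(fits[j], "status", "running") == "converged":
                    fits[j].status = "running"
    kept = [f for f, d in zip(fits, discard) if not d]
    dropped = [f for f, d in zip(fits, discard) if d]
    return kept, dropped


# --------------------------------------------------------------------------
# Frame analysis
# --------------------------------------------------------------------------

def _start_fit(frame_state: FrameState, model: SplineFitModel,
               cand: PeakCandidate, config: AnalysisConfig) -> _ActiveFit | None:
    roi = config.fit_roi
    local = roi // 2 - 1  # candidate pixel position within its ROI
    ax, ay = cand.x - local, cand.y - local
    h_img, w_img = frame_state.image.shape
    if ax < 0 or ay < 0 or ax + roi > w_img or ay + roi > h_img:
        log.info("candidate at (%d, %d) too close to the frame edge; "
                 "skipped", cand.x, cand.y)
        return None
    sy, sx = slice(ay, ay + roi), slice(ax, ax + roi)
    b0 = max(float(frame_state.background[sy, sx].mean()), 0.0)
    p0 = np.array([max(cand.amplitude, 1.0), float(local), float(local),
                   cand.z, b0])
    data = np.clip(frame_state.image[sy, sx]
                   - (frame_state.model_sum[sy, sx]), 0.0, None)
    try:
        state = lm_init(model, data, p0)
    except OutOfSupportError:
        return None
    roi_model = state.f - state.p[4]  # h * spline part only
    return _ActiveFit(anchor=(ax, ay), state=state, status="running",
                      roi_model=roi_model)


def analyze_frame(image: np.ndarray, spline_psf: SplinePSF,
                  config: AnalysisConfig) -> list[Localization]:
    """Run the full iterative find/fit/filter loop on one frame.

    Returns the converged localizations in frame pixel coordinates.
    Failed or never-converged localizations are dropped (and logged).
    """
    image = np.asarray(image, dtype=float)
    model = SplineFitModel(spline_psf)
    background = estimate_background(image, config.background_sigma)
    fs = FrameState(image, background)

    for fs.repeats in range(config.max_repeats):
        bg_level = float(fs.background.mean())
        candidates = find_peaks(fs.residual, spline_psf, config.z_planes,
                                config.threshold, bg_level)
        new_fits = []
        for cand in candidates:
            too_close = any(
                np.hypot(f.x - cand.x, f.y - cand.y) < config.min_distance
                for f in fs.fits)
            if too_close:
                continue
            fit = _start_fit(fs, model, cand, config)
            if fit is not None:
                new_fits.append(fit)
        for fit in new_fits:
            fs.fits.append(fit)
            fs.add_model(fit)

        if not new_fits and fs.all_converged():
            break

        # per-localization damped updates, all the others held fixed
        for _ in range(config.max_iterations):
            if fs.all_converged():
                break
            for fit in fs.fits:
                if fit.status != "running":
                    continue
                sy, sx = fs.roi_slices(fit)
                data = np.clip(
                    image[sy, sx] - (fs.model_sum[sy, sx] - fit.roi_model),
                    0.0, None)
                fs.remove_model(fit)
                lm_step(model, data, fit.state)
                fit.roi_model = fit.state.f - fit.state.p[4]
                fs.add_model(fit)
                if fit.state.failed:
                    fit.status = "failed"
                elif fit.state.converged:
                    fit.status = "converged"

        kept, dropped = proximity_filter(
            [f for f in fs.fits if f.status != "failed"],
            config.min_distance)
        for fit in dropped + [f for f in fs.fits if f.status == "failed"]:
            fs.remove_model(fit)
        if dropped:
            log.info("proximity filter discarded %d localization(s)",
                     len(dropped))
        # re-flagged neighbors must resume iterating
        for fit in kept:
            if fit.status == "running":
                fit.state.converged = False
        fs.fits = kept

        fs.background = estimate_background(image - fs.model_sum,
                                            config.background_sigma)

    out = []
    for fit in fs.fits:
        if fit.status != "converged":
            log.info("dropping localization at (%.1f, %.1f): %s",
                     fit.x, fit.y, fit.status)
            continue
        h, lx, ly, z, b = fit.state.p
        out.append(Localization(
            x=fit.anchor[0] + float(lx), y=fit.anchor[1] + float(ly),
            z=float(z), photons=float(h), background=float(b),
            chi2=float(fit.state.chi2), iterations=fit.state.n_steps,
            status="converged"))
    return out


def analyze_movie(movie: np.ndarray, spline_psf: SplinePSF,
                  config: AnalysisConfig) -> list[Localization]:
    """Analyze every frame of a movie; localization records carry the frame."""
    movie = np.asarray(movie, dtype=float)
    if movie.ndim == 2:
        movie = movie[None]
    out = []
    for i, frame in enumerate(movie):
        locs = analyze_frame(frame, spline_psf, config)
        for loc in locs:
            loc.frame = i
        log.info("frame %d: %d localization(s)", i, len(locs))
        out.extend(locs)
    return out
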