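"""Measure a 3D PSF from bead / emitter z-scan stacks.

Pipeline: crop isolated emitters from each frame of a z scan, up-sample
each crop 2x laterally with 3rd-order spline interpolation, align the
crops to their intensity centroids, average them per z position, and
average the per-position images over 50 nm z bins.  The result is a
:class:`~splinepsf.stack.PSFStack` sampled at half the camera pixel —
exactly the knot grid the spline builder expects.

When true emitter locations are unknown (real bead data) they can be
estimated with the package's own Gaussian fitter
(:func:`estimate_locations`), since beads emit enough photons for that to
be precise.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage

from .stack import PSFStack

__all__ = [
    "EmitterCrop",
    "crop_emitters",
    "align_and_average",
    "bin_z",
    "measure_psf",
    "estimate_locations",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class EmitterCrop:
    """One emitter's cropped sub-image from one z frame."""

    image: np.ndarray
    location: tuple[float, float]  # nominal (x, y), frame pixels
    z: float                       # frame z position, nm


def crop_emitters(stack: np.ndarray, locations, z_per_frame, roi_size: int,
                  margin: int = 1, min_separation: float | None = None
                  ) -> list[list[EmitterCrop]]:
    """Crop every emitter from every frame of a z-scan stack.

    ``locations`` is a sequence of (x, y) nominal emitter positions in
    pixels; ``z_per_frame`` gives the z (nm) of each frame.  Emitters too
    close to a frame edge (within ``roi_size/2 + margin``) or to another
    emitter are skipped with a logged warning.  Returns one list of crops
    per frame, crop order matching the input location order.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be 3D (frame, y, x)")
    z_per_frame = np.asarray(z_per_frame, dtype=float)
    if z_per_frame.shape[0] != stack.shape[0]:
        raise ValueError("z_per_frame length must match the frame count")
    half = roi_size // 2
    need = half + margin
    if min_separation is None:
        min_separation = float(roi_size)

    locations = [(float(x), float(y)) for x, y in locations]
    keep = []
    for i, (x, y) in enumerate(locations):
        ix, iy = int(round(x)), int(round(y))
        if (ix < need or iy < need or ix >= stack.shape[2] - need
                or iy >= stack.shape[1] - need):
            log.warning("emitter %d at (%.1f, %.1f) too close to the frame "
                        "edge; skipped", i, x, y)
            continue
        close = [j for j, (x2, y2) in enumerate(locations) if j != i
                 and np.hypot(x2 - x, y2 - y) < min_separation]
        if close:
            log.warning("emitter %d at (%.1f, %.1f) within %.1f px of a "
                        "neighbor; skipped", i, x, y, min_separation)
            continue
        keep.append(i)

    out: list[list[EmitterCrop]] = []
    for f in range(stack.shape[0]):
        crops = []
        for i in keep:
            x, y = locations[i]
            ix, iy = int(round(x)), int(round(y))
            sub = stack[f, iy - half:iy - half + roi_size,
                        ix - half:ix - half + roi_size]
            crops.append(EmitterCrop(sub.copy(), (x, y), float(z_per_frame[f])))
        out.append(crops)
    return out


def _border_background(image: np.ndarray) -> float:
    return float(np.median(np.concatenate([
        image[0, :], image[-1, :], image[:, 0], image[:, -1]])))


def align_and_average(crops: list[EmitterCrop], upsample_factor: int = 2,
                      output_size: int | None = None) -> np.ndarray:
    """Up-sample, centroid-align and average the crops for one z position.

    Each crop is up-sampled ``upsample_factor`` x with 3rd-order (natural
    cubic spline) interpolation on an exact sub-pixel grid — an n-sample
    crop becomes ``factor * (n - 1) + 1`` samples with the original pixel
    centers preserved, so the result sits exactly on the half-pixel knot
    grid the spline builder expects.  Each up-sampled crop is then shifted
    (scipy ndimage, 3rd-order) so its background-subtracted intensity
    centroid lies at the image center, and the shifted images are averaged
    pixel-wise.  The centroid is computed on the border-median-subtracted
    crop to avoid the background biasing it.

    ``output_size`` trims the result to an odd size centred on the
    centroid; by default the full up-sampled size is kept.
    """
    from .splines import upsample_axis

    if len(crops) == 0:
        raise ValueError("need at least one crop")
    shapes = {c.image.shape for c in crops}
    if len(shapes) != 1:
        raise ValueError("all crops must have the same shape")

    up_shape = tuple(upsample_factor * (s - 1) + 1
                     for s in crops[0].image.shape)
    if output_size is None:
        size = up_shape[0]
    else:
        size = int(output_size)
        if size > up_shape[0]:
            raise ValueError("output_size exceeds the up-sampled crop")
    center = (size - 1) / 2.0

    acc = np.zeros((size, size))
    for crop in crops:
        img = upsample_axis(upsample_axis(crop.image, upsample_factor, 0),
                            upsample_factor, 1)
        bg = _border_background(img)
        w = np.clip(img - bg, 0.0, None)
        total = w.sum()
        if total > 0:
            ys, xs = np.indices(img.shape)
            cy = (w * ys).sum() / total
            cx = (w * xs).sum() / total
        else:  # constant crop: centroid shift is a no-op
            cy, cx = ((s - 1) / 2.0 for s in img.shape)
        shifted = ndimage.shift(img, (center - cy, center - cx), order=3,
                                mode="nearest")
        acc += shifted[:size, :size]
    return acc / len(crops)


def bin_z(images, z_tags, bin_width: float = 50.0, pixel_size: float = 80.0,
          wavelength: float = 600.0) -> PSFStack:
    """Average per-z images over z bins and assemble the PSF stack.

    Bins are half-open intervals ``[center - w/2, center + w/2)`` with
    centers at integer multiples of the bin width; a z exactly on a
    boundary belongs to the upper interval (deterministic, documented).
    Empty bins inside the covered range are flagged with a warning and
    omitted.  Output z positions are the bin centers.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    images = [np.asarray(im, dtype=float) for im in images]
    if len(images) == 0:
        raise ValueError("need at least one image")
    z_tags = np.asarray(z_tags, dtype=float)
    if z_tags.shape[0] != len(images):
        raise ValueError("one z tag per image required")

    idx = np.floor((z_tags + bin_width / 2.0) / bin_width).astype(int)
    lo, hi = idx.min(), idx.max()
    slices, centers = [], []
    for k in range(lo, hi + 1):
        members = [im for im, i in zip(images, idx) if i == k]
        if not members:
            log.warning("z bin centered at %.1f nm has no members; omitted",
                        k * bin_width)
            continue
        slices.append(np.mean(members, axis=0))
        centers.append(k * bin_width)
    return PSFStack(np.stack(slices), np.asarray(centers, dtype=float),
                    pixel_size, wavelength)


def estimate_locations(frame: np.ndarray, roi_size: int = 12,
                       threshold: float = 6.0) -> list[tuple[float, float]]:
    """Rough emitter locations from one bright frame via Gaussian fitting.

    Finds local maxima well above the background and refines each with the
    package's elliptical-Gaussian slice fitter.  Intended for bead data
    where the true locations are unknown.
    """
    from scipy.ndimage import gaussian_filter, maximum_filter

    from .gaussian import fit_gaussian_slice

    frame = np.asarray(frame, dtype=float)
    bg = gaussian_filter(frame, 8.0, mode="nearest")
    resid = frame - bg
    sigma = max(float(np.sqrt(np.clip(bg, 1.0, None).mean())), 1e-6)
    local_max = (resid == maximum_filter(resid, size=3)) & (resid > threshold * sigma)
    half = roi_size // 2
    out = []
    for iy, ix in zip(*np.nonzero(local_max)):
        if (ix < half or iy < half or ix >= frame.shape[1] - half
                or iy >= frame.shape[0] - half):
            continue
        sub = frame[iy - half:iy - half + roi_size, ix - half:ix - half + roi_size]
        res = fit_gaussian_slice(sub)
        out.append((ix - half + res["x0"], iy - half + res["y0"]))
    return out


def measure_psf(stack: np.ndarray, locations, z_per_frame, roi_size: int = 15,
                upsample_factor: int = 2, bin_width: float = 50.0,
                pixel_size: float = 160.0, wavelength: float = 600.0,
                output_size: int | None = None) -> PSFStack:
    """Full measurement pipeline: crop, align/average per frame, bin in z.

    ``pixel_size`` is the camera pixel (nm); the returned stack is sampled
    at ``pixel_size / upsample_factor``.  ``output_size`` (odd) selects the
    lateral knot count, default ``2 * (roi_size - 1) + 1``.
    """
    if output_size is None:
        output_size = 2 * (roi_size - 1) + 1
    per_frame = crop_emitters(stack, locations, z_per_frame, roi_size)
    images, tags = [], []
    for crops in per_frame:
        if not crops:
            continue
        images.append(align_and_average(crops, upsample_factor,
                                        output_size=output_size))
        tags.append(crops[0].z)
    return bin_z(images, tags, bin_width=bin_width,
                 pixel_size=pixel_size / upsample_factor,
                 wavelength=wavelength)
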