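"""Elliptical Gaussian PSF model with astigmatic z calibration.

The Gaussian model used for comparison with spline fitting is, on the ROI
pixel grid,

    f(x, y, z) = a exp(-(x - x0)^2 / w_x(z) - (y - y0)^2 / w_y(z)) + b

with the widths appearing unsquared in the denominator (so ``w`` plays the
role of ``2 sigma^2`` and carries units of pixels squared).  The defocus
calibration uses the de-facto standard astigmatism form on the width
(sigma) scale,

    s(z) = s0 sqrt(1 + r^2 + A r^3 + B r^4),   r = (z - c) / d

with ``s0`` in pixels, focal offset ``c`` and depth scale ``d`` in nm and
dimensionless higher-order terms ``A`` and ``B``; the model's denominator
follows as ``w(z) = 2 s(z)^2``.  (Fitting the sqrt form directly to the
squared-width scale would misrepresent the near-quadratic defocus law and
produce spurious extra w_x/w_y crossings.)
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "gaussian_psf",
    "gaussian_psf_z",
    "fit_gaussian_slice",
    "GaussianCalibration",
    "fit_defocus_curve",
    "fit_gaussian_calibration",
    "GaussianPSFModel",
    "FreeWidthGaussianModel",
    "mle_fit_gaussian_widths",
]

_W_FLOOR = 1e-6


def gaussian_psf(a: float, b: float, x0: float, y0: float,
                 wx: float, wy: float, roi_shape) -> np.ndarray:
    """Elliptical Gaussian image on the ROI pixel grid (see module form)."""
    if wx <= 0 or wy <= 0:
        raise ValueError("widths must be positive")
    ry, rx = roi_shape
    xs = np.arange(rx)
    ys = np.arange(ry)
    ex = np.exp(-((xs - x0) ** 2) / wx)
    ey = np.exp(-((ys - y0) ** 2) / wy)
    return a * np.outer(ey, ex) + b


def _slice_moments(image: np.ndarray):
    """Moment-based initial guess (a, b, x0, y0, wx, wy) for one slice."""
    b0 = float(np.median(np.concatenate([
        image[0, :], image[-1, :], image[:, 0], image[:, -1]])))
    w = np.clip(image - b0, 0.0, None)
    total = w.sum()
    ys, xs = np.indices(image.shape)
    if total <= 0:
        cy, cx = ((s - 1) / 2.0 for s in image.shape)
        return max(image.max() - b0, 1e-3), b0, cx, cy, 2.0, 2.0
    cx = float((w * xs).sum() / total)
    cy = float((w * ys).sum() / total)
    vx = float((w * (xs - cx) ** 2).sum() / total)
    vy = float((w * (ys - cy) ** 2).sum() / total)
    return (max(image.max() - b0, 1e-3), b0, cx, cy,
            max(2.0 * vx, 0.5), max(2.0 * vy, 0.5))


def fit_gaussian_slice(image: np.ndarray, init=None):
    """Least-squares fit of the elliptical Gaussian to one image.

    Returns a dict with keys a, b, x0, y0, wx, wy and the residual RMS.
    """
    image = np.asarray(image, dtype=float)
    p0 = np.asarray(init if init is not None else _slice_moments(image), float)

    def resid(p):
        a, b, x0, y0, wx, wy = p
        return (gaussian_psf(a, b, x0, y0, max(wx, _W_FLOOR),
                             max(wy, _W_FLOOR), image.shape)
                - image).ravel()

    lo = [0.0, -np.inf, -1.0, -1.0, _W_FLOOR, _W_FLOOR]
    hi = [np.inf, np.inf, image.shape[1], image.shape[0], np.inf, np.inf]
    p0 = np.clip(p0, lo, hi)
    sol = least_squares(resid, p0, bounds=(lo, hi), method="trf")
    a, b, x0, y0, wx, wy = sol.x
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return {"a": a, "b": b, "x0": x0, "y0": y0, "wx": wx, "wy": wy,
            "rms": rms}


# --------------------------------------------------------------------------
# Defocus calibration
# --------------------------------------------------------------------------

def _s_curve(z, s0, c, d, A, B):
    r = (np.asarray(z, dtype=float) - c) / d
    s = 1.0 + r**2 + A * r**3 + B * r**4
    return s0 * np.sqrt(np.clip(s, _W_FLOOR, None))


def _s_curve_dz(z, s0, c, d, A, B):
    r = (np.asarray(z, dtype=float) - c) / d
    s = np.clip(1.0 + r**2 + A * r**3 + B * r**4, _W_FLOOR, None)
    return s0 * (2.0 * r + 3.0 * A * r**2 + 4.0 * B * r**3) / (2.0 * d * np.sqrt(s))


def fit_defocus_curve(z, sigma) -> tuple[float, float, float, float, float]:
    """Least-squares fit of the defocus-curve form to measured widths (px)."""
    z = np.asarray(z, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    span = max(z.max() - z.min(), 1.0)
    p0 = [float(sigma.min()), float(z[np.argmin(sigma)]), span / 4.0, 0.0, 0.0]
    lo = [_W_FLOOR, z.min() - span, 1.0, -5.0, -5.0]
    hi = [np.inf, z.max() + span, 100.0 * span, 5.0, 5.0]
    sol = least_squares(lambda p: _s_curve(z, *p) - sigma,
                        np.clip(p0, lo, hi), bounds=(lo, hi), method="trf")
    return tuple(float(v) for v in sol.x)  # type: ignore[return-value]


@dataclasses.dataclass
class GaussianCalibration:
    """w_x(z), w_y(z) defocus curves for elliptical-Gaussian z fitting.

    ``sx_params`` / ``sy_params`` hold (s0, c, d, A, B) of the sigma-scale
    curves; the model denominators are ``w = 2 s(z)^2``.
    """

    sx_params: tuple  # (s0, c, d, A, B)
    sy_params: tuple
    z_min: float
    z_max: float
    rms_residual: float = float("nan")

    def sigma_x(self, z):
        return _s_curve(z, *self.sx_params)

    def sigma_y(self, z):
        return _s_curve(z, *self.sy_params)

    def wx(self, z):
        return 2.0 * self.sigma_x(z) ** 2

    def wy(self, z):
        return 2.0 * self.sigma_y(z) ** 2

    def dwx_dz(self, z):
        return 4.0 * self.sigma_x(z) * _s_curve_dz(z, *self.sx_params)

    def dwy_dz(self, z):
        return 4.0 * self.sigma_y(z) * _s_curve_dz(z, *self.sy_params)

    def in_range(self, z) -> bool:
        return bool(np.all((z >= self.z_min) & (z <= self.z_max)))

    def crossings(self, n_grid: int = 2001) -> np.ndarray:
        """z values where w_x(z) = w_y(z) inside the calibrated range."""
        zg = np.linspace(self.z_min, self.z_max, n_grid)
        diff = self.wx(zg) - self.wy(zg)
        sign_change = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
        roots = []
        for i in sign_change:
            z0, z1 = zg[i], zg[i + 1]
            f0, f1 = diff[i], diff[i + 1]
            roots.append(z0 - f0 * (z1 - z0) / (f1 - f0))
        return np.asarray(roots)


def fit_gaussian_calibration(z, wx, wy) -> GaussianCalibration:
    """Fit both defocus curves from (z, w_x, w_y) width measurements.

    ``wx`` and ``wy`` are the per-slice fitted model denominators
    (``2 sigma^2``); the curves are fitted on the sigma scale.  Requires at
    least 8 z samples.  If the data do not span the focal crossing
    (w_x - w_y never changes sign), a warning is issued and the best-effort
    fit is returned; the single-crossing invariant is also checked on the
    fitted curves.
    """
    z = np.asarray(z, dtype=float)
    wx = np.asarray(wx, dtype=float)
    wy = np.asarray(wy, dtype=float)
    if z.size < 8:
        raise ValueError("need at least 8 z samples for calibration")
    if not np.any(np.diff(np.sign(wx - wy)) != 0):
        warnings.warn("width measurements do not span the focal crossing; "
                      "calibration is a best-effort fit")
    px = fit_defocus_curve(z, np.sqrt(wx / 2.0))
    py = fit_defocus_curve(z, np.sqrt(wy / 2.0))
    cal = GaussianCalibration(px, py, float(z.min()), float(z.max()))
    resid = np.concatenate([cal.wx(z) - wx, cal.wy(z) - wy])
    cal.rms_residual = float(np.sqrt(np.mean(resid**2)))
    n_cross = len(cal.crossings())
    if n_cross != 1:
        warnings.warn(f"calibration curves cross {n_cross} times in the "
                      "calibrated range (expected exactly 1 for an "
                      "astigmatic PSF)")
    return cal


def gaussian_psf_z(a: float, b: float, x0: float, y0: float, z: float,
                   calibration: "GaussianCalibration", roi_shape) -> np.ndarray:
    """Gaussian model image at axial position z via the calibration curves."""
    if not calibration.in_range(z):
        raise ValueError(
            f"z = {z:.1f} nm outside the calibrated range "
            f"[{calibration.z_min:.1f}, {calibration.z_max:.1f}] nm")
    return gaussian_psf(a, b, x0, y0, float(calibration.wx(z)),
                        float(calibration.wy(z)), roi_shape)


# --------------------------------------------------------------------------
# Fit model (z through the calibration curves)
# --------------------------------------------------------------------------

class GaussianPSFModel:
    """Five-parameter Gaussian emitter model for the MLE fit driver.

    Parameter vector order: (a, x0, y0, z, b) with x0, y0 in ROI pixels and
    z in nm; the widths follow z through the calibration curves.
    """

    param_names = ("a", "x0", "y0", "z", "b")

    def __init__(self, calibration: GaussianCalibration, pixel_size: float):
        self.calibration = calibration
        self.pixel_size = pixel_size

    def model_image(self, p, roi_shape) -> np.ndarray:
        a, x0, y0, z, b = p
        return gaussian_psf(a, b, x0, y0,
                            float(self.calibration.wx(z)),
                            float(self.calibration.wy(z)), roi_shape)

    def model_image_with_gradient(self, p, roi_shape):
        a, x0, y0, z, b = p
        cal = self.calibration
        wx = float(cal.wx(z))
        wy = float(cal.wy(z))
        ry, rx = roi_shape
        dx = np.arange(rx) - x0
        dy = np.arange(ry) - y0
        ex = np.exp(-dx**2 / wx)
        ey = np.exp(-dy**2 / wy)
        g = np.outer(ey, ex)
        f = a * g + b
        ag = a * g
        d_x0 = ag * (2.0 * dx / wx)[None, :]
        d_y0 = ag * (2.0 * dy / wy)[:, None]
        d_z = ag * ((dx**2)[None, :] / wx**2 * float(cal.dwx_dz(z))
                    + (dy**2)[:, None] / wy**2 * float(cal.dwy_dz(z)))
        jac = np.stack([g, d_x0, d_y0, d_z, np.ones_like(g)])
        return f, jac

    def clamp(self, p, roi_shape) -> np.ndarray:
        p = np.asarray(p, dtype=float).copy()
        ry, rx = roi_shape
        p[0] = max(p[0], 1e-6)
        p[1] = np.clip(p[1], 0.5, rx - 1.5)
        p[2] = np.clip(p[2], 0.5, ry - 1.5)
        p[3] = np.clip(p[3], self.calibration.z_min + 1.0,
                       self.calibration.z_max - 1.0)
        p[4] = max(p[4], 0.0)
        return p


class FreeWidthGaussianModel:
    """Elliptical Gaussian with free widths for the MLE fit driver.

    Parameter vector order: (a, x0, y0, wx, wy, b).  Used to measure the
    w_x(z), w_y(z) calibration with exactly the same Poisson-MLE weighting
    that the z fit later applies, so the width-to-z mapping is consistent
    between calibration and fitting.
    """

    param_names = ("a", "x0", "y0", "wx", "wy", "b")
    # widths (px^2) need a much tighter step gate than an axial nm position
    step_tol = np.array([np.inf, 1e-4, 1e-4, 1e-6, 1e-6, np.inf])

    def model_image(self, p, roi_shape) -> np.ndarray:
        a, x0, y0, wx, wy, b = p
        return gaussian_psf(a, b, x0, y0, wx, wy, roi_shape)

    def model_image_with_gradient(self, p, roi_shape):
        a, x0, y0, wx, wy, b = p
        ry, rx = roi_shape
        dx = np.arange(rx) - x0
        dy = np.arange(ry) - y0
        ex = np.exp(-dx**2 / wx)
        ey = np.exp(-dy**2 / wy)
        g = np.outer(ey, ex)
        ag = a * g
        jac = np.stack([
            g,
            ag * (2.0 * dx / wx)[None, :],
            ag * (2.0 * dy / wy)[:, None],
            ag * (dx**2 / wx**2)[None, :],
            ag * (dy**2 / wy**2)[:, None],
            np.ones_like(g),
        ])
        return ag + b, jac

    def clamp(self, p, roi_shape) -> np.ndarray:
        p = np.asarray(p, dtype=float).copy()
        ry, rx = roi_shape
        p[0] = max(p[0], 1e-6)
        p[1] = np.clip(p[1], 0.5, rx - 1.5)
        p[2] = np.clip(p[2], 0.5, ry - 1.5)
        p[3] = max(p[3], 0.25)
        p[4] = max(p[4], 0.25)
        p[5] = max(p[5], 0.0)
        return p


def mle_fit_gaussian_widths(image: np.ndarray, init=None) -> dict:
    """Poisson-MLE fit of the free-width Gaussian to one image.

    Returns the same keys as :func:`fit_gaussian_slice` (minus the residual
    RMS, replaced by the final deviance).
    """
    from .fit import lm_fit  # deferred: fit imports this module

    image = np.asarray(image, dtype=float)
    if init is None:
        a, b, x0, y0, wx, wy = _slice_moments(image)
    else:
        a, b, x0, y0, wx, wy = init
    state = lm_fit(FreeWidthGaussianModel(), image,
                   [a, x0, y0, wx, wy, max(b, 0.0)])
    a, x0, y0, wx, wy, b = state.p
    return {"a": a, "b": b, "x0": x0, "y0": y0, "wx": wx, "wy": wy,
            "chi2": state.chi2, "converged": state.converged}
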