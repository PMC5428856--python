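"""Natural cubic-spline PSF models.

This module implements the core of the package: construction of 1D and 3D
natural cubic splines from sampled PSFs, and evaluation of the spline PSF
model

    f(x, y) = h * s(x - x_c, y - y_c, z_c) + b

together with its analytical partial derivatives with respect to the five
fit parameters (h, x_c, y_c, z_c, b).

Conventions (used everywhere in the package):

* pixel indices are 0-based and pixel centers sit at integer coordinates;
* lateral spline intervals are half a camera pixel long, so a spline that
  supports ``S`` pixels has ``2 S`` intervals and ``2 S + 1`` knots per
  lateral axis;
* the emitter position ``(x_c, y_c)`` is measured in ROI pixel coordinates
  from the ROI corner, and maps to the center of the spline support;
* ``z_c`` is in nm; internally z is handled in spline-interval units and
  converted at the interface.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.linalg import solve_banded

from .stack import PSFStack, resample_z

__all__ = [
    "OutOfSupportError",
    "CubicSpline1D",
    "CubicSpline3D",
    "EmitterParams",
    "SplinePSF",
    "build_spline_1d",
    "build_spline_3d",
    "upsample_stack",
    "eval_psf",
    "eval_psf_gradient",
    "spline_eval_operations",
    "gaussian_eval_operations",
    "count_eval_operations",
    "spline_sample_axis",
]


class OutOfSupportError(ValueError):
    """Requested evaluation point lies outside the spline support.

    Cubic extrapolation diverges, so evaluation outside the support is an
    error; callers (the fit driver, the engine) mark the localization as
    failed instead of extrapolating.
    """


# --------------------------------------------------------------------------
# 1D natural cubic spline
# --------------------------------------------------------------------------

def _natural_second_derivatives(y: np.ndarray) -> np.ndarray:
    """Second derivatives M_i of the natural cubic spline through ``y``.

    ``y`` has the knot axis last; knots are unit-spaced.  The natural
    boundary condition fixes M at the first and last knot to zero; interior
    values solve the classic tridiagonal system
    ``M[i-1] + 4 M[i] + M[i+1] = 6 (y[i+1] - 2 y[i] + y[i-1])``.
    """
    n = y.shape[-1]
    m = np.zeros_like(y)
    if n > 2:
        rhs = 6.0 * (y[..., 2:] - 2.0 * y[..., 1:-1] + y[..., :-2])
        k = n - 2
        ab = np.zeros((3, k))
        ab[0, 1:] = 1.0
        ab[1, :] = 4.0
        ab[2, :-1] = 1.0
        sol = solve_banded((1, 1), ab, rhs.reshape(-1, k).T)
        m[..., 1:-1] = sol.T.reshape(y[..., 1:-1].shape)
    return m


def polynomial_coefficients(y: np.ndarray, axis: int = -1) -> np.ndarray:
    """Per-interval cubic coefficients of the natural spline through ``y``.

    Returns an array with shape ``y.shape`` where the interpolation axis of
    length ``n`` is replaced by ``(n - 1, 4)``; the last axis holds
    ``(a, b, c, d)`` so that on interval ``i`` with local coordinate
    ``u = x - t_i`` (unit knot spacing)

        f_i(u) = a u^3 + b u^2 + c u + d .
    """
    y = np.moveaxis(np.asarray(y, dtype=float), axis, -1)
    m = _natural_second_derivatives(y)
    a = (m[..., 1:] - m[..., :-1]) / 6.0
    b = m[..., :-1] / 2.0
    c = y[..., 1:] - y[..., :-1] - m[..., 1:] / 6.0 - m[..., :-1] / 3.0
    d = y[..., :-1]
    return np.stack([a, b, c, d], axis=-1)


def _locate(t: np.ndarray, n_intervals: int) -> tuple[np.ndarray, np.ndarray]:
    """Interval index and fractional offset for coordinates in knot units."""
    i = np.clip(np.floor(t).astype(int), 0, n_intervals - 1)
    return i, np.asarray(t, dtype=float) - i


@dataclasses.dataclass
class CubicSpline1D:
    """Natural cubic spline on unit-spaced knots.

    ``coefficients`` has shape ``(n_intervals, 4)`` holding ``(a, b, c, d)``
    per interval in the normalized local coordinate ``(x - t_i) / dt``.
    """

    coefficients: np.ndarray
    dt: float = 1.0

    @property
    def n_intervals(self) -> int:
        return self.coefficients.shape[0]

    def __call__(self, x):
        t = np.asarray(x, dtype=float) / self.dt
        i, u = _locate(t, self.n_intervals)
        c = self.coefficients[i]
        return ((c[..., 0] * u + c[..., 1]) * u + c[..., 2]) * u + c[..., 3]

    def derivative(self, x):
        t = np.asarray(x, dtype=float) / self.dt
        i, u = _locate(t, self.n_intervals)
        c = self.coefficients[i]
        return ((3.0 * c[..., 0] * u + 2.0 * c[..., 1]) * u + c[..., 2]) / self.dt

    def second_derivative(self, x):
        t = np.asarray(x, dtype=float) / self.dt
        i, u = _locate(t, self.n_intervals)
        c = self.coefficients[i]
        return (6.0 * c[..., 0] * u + 2.0 * c[..., 1]) / self.dt**2


def build_spline_1d(knot_values, dt: float = 1.0) -> CubicSpline1D:
    """Build the natural cubic spline interpolating ``knot_values``.

    The spline passes through every sample exactly, has continuous value and
    first derivative at interior knots, and zero second derivative at the
    two outer knots.
    """
    v = np.asarray(knot_values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need at least 2 knot values")
    if not np.all(np.isfinite(v)):
        raise ValueError("knot values must be finite")
    return CubicSpline1D(polynomial_coefficients(v), dt=dt)


# --------------------------------------------------------------------------
# Up-sampling
# --------------------------------------------------------------------------

def _upsample_last_axis(y: np.ndarray, factor: int) -> np.ndarray:
    """Spline-interpolate ``y`` to a ``factor`` x denser grid (last axis).

    Output length is ``factor * (n - 1) + 1``; original samples are
    reproduced exactly at their positions.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[-1]
    if factor == 1:
        return y.copy()
    coeffs = polynomial_coefficients(y)
    out = np.empty(y.shape[:-1] + (factor * (n - 1) + 1,), dtype=float)
    idx = np.arange(n - 1) * factor
    for p in range(factor):
        u = p / factor
        vals = ((coeffs[..., 0] * u + coeffs[..., 1]) * u
                + coeffs[..., 2]) * u + coeffs[..., 3]
        out[..., idx + p] = vals
    out[..., -1] = y[..., -1]
    return out


def upsample_axis(arr: np.ndarray, factor: int, axis: int) -> np.ndarray:
    arr = np.moveaxis(np.asarray(arr, dtype=float), axis, -1)
    return np.moveaxis(_upsample_last_axis(arr, factor), -1, axis)


def spline_sample_axis(arr: np.ndarray, positions, axis: int = 0) -> np.ndarray:
    """Sample a natural spline through ``arr`` at fractional index positions."""
    y = np.moveaxis(np.asarray(arr, dtype=float), axis, -1)
    coeffs = polynomial_coefficients(y)
    i, u = _locate(np.asarray(positions, dtype=float), y.shape[-1] - 1)
    c = coeffs[..., i, :]
    vals = ((c[..., 0] * u + c[..., 1]) * u + c[..., 2]) * u + c[..., 3]
    return np.moveaxis(vals, -1, axis)


def upsample_stack(psf: PSFStack, factor) -> PSFStack:
    """Up-sample a PSF stack by integer factors per axis (z, y, x).

    ``factor`` may be a single integer (applied to every axis) or a triple
    ``(fz, fy, fx)``.  Interpolation is 3rd-order (natural cubic spline);
    values at the original sample positions are preserved.
    """
    if np.isscalar(factor):
        factors = (int(factor),) * 3
    else:
        factors = tuple(int(f) for f in factor)
        if len(factors) != 3:
            raise ValueError("factor must be an int or a (fz, fy, fx) triple")
    if any(f < 1 for f in factors):
        raise ValueError("up-sampling factors must be >= 1")
    if factors[1] != factors[2]:
        raise ValueError("lateral factors must match (isotropic xy sampling)")
    data = psf.data
    for ax, f in enumerate(factors):
        if f > 1:
            data = upsample_axis(data, f, ax)
    nz = psf.data.shape[0]
    z_new = np.interp(
        np.linspace(0.0, nz - 1.0, factors[0] * (nz - 1) + 1),
        np.arange(nz), psf.z_positions,
    )
    return PSFStack(data, z_new, psf.pixel_size / factors[2], psf.wavelength)


# --------------------------------------------------------------------------
# 3D spline
# --------------------------------------------------------------------------

# Monomial basis matrix for the 4 within-element sample positions
# u in {0, 1/4, 1/2, 3/4}: V[p, m] = (p/4)^m.  Its inverse maps 64 sampled
# values per element to the 64 polynomial coefficients.
_V4 = np.power.outer(np.arange(4) / 4.0, np.arange(4))
_IV4 = np.linalg.inv(_V4)


@dataclasses.dataclass
class CubicSpline3D:
    """Tricubic spline coefficient tensor.

    ``coefficients`` has shape ``(nz, ny, nx, 4, 4, 4)``: interval indices
    (k, j, i) for (z, y, x) followed by monomial powers (o, n, m) for
    (z, y, x), each ascending 0..3.  Within interval (k, j, i) and local
    coordinates (w, v, u) in [0, 1]:

        f = sum_{o,n,m} coefficients[k, j, i, o, n, m] w^o v^n u^m

    ``dt_nm`` is the lateral interval length (half a camera pixel) and
    ``du_nm`` the axial interval length, both in nm; ``z_min_nm`` is the
    physical z of the first axial knot.
    """

    coefficients: np.ndarray
    dt_nm: float
    du_nm: float
    z_min_nm: float

    @property
    def n_intervals(self) -> tuple[int, int, int]:
        return self.coefficients.shape[:3]  # type: ignore[return-value]

    def evaluate(self, tz, ty, tx):
        """Spline value at coordinates given in interval (knot-index) units."""
        tz, ty, tx = np.broadcast_arrays(
            np.asarray(tz, float), np.asarray(ty, float), np.asarray(tx, float))
        nzi, nyi, nxi = self.n_intervals
        iz, fz = _locate(tz, nzi)
        iy, fy = _locate(ty, nyi)
        ix, fx = _locate(tx, nxi)
        c = self.coefficients[iz, iy, ix]
        powers = np.arange(4)
        mz = fz[..., None] ** powers
        my = fy[..., None] ** powers
        mx = fx[..., None] ** powers
        return np.einsum("...onm,...o,...n,...m->...", c, mz, my, mx,
                         optimize=True)

    def evaluate_with_gradient(self, tz, ty, tx):
        """Value and (d/dtz, d/dty, d/dtx) in interval units."""
        tz, ty, tx = np.broadcast_arrays(
            np.asarray(tz, float), np.asarray(ty, float), np.asarray(tx, float))
        nzi, nyi, nxi = self.n_intervals
        iz, fz = _locate(tz, nzi)
        iy, fy = _locate(ty, nyi)
        ix, fx = _locate(tx, nxi)
        c = self.coefficients[iz, iy, ix]
        powers = np.arange(4)
        mz = fz[..., None] ** powers
        my = fy[..., None] ** powers
        mx = fx[..., None] ** powers
        one = np.ones_like(fz)
        dmz = np.stack([np.zeros_like(fz), one, 2.0 * fz, 3.0 * fz**2], axis=-1)
        dmy = np.stack([np.zeros_like(fy), one, 2.0 * fy, 3.0 * fy**2], axis=-1)
        dmx = np.stack([np.zeros_like(fx), one, 2.0 * fx, 3.0 * fx**2], axis=-1)
        val = np.einsum("...onm,...o,...n,...m->...", c, mz, my, mx,
                        optimize=True)
        gz = np.einsum("...onm,...o,...n,...m->...", c, dmz, my, mx,
                       optimize=True)
        gy = np.einsum("...onm,...o,...n,...m->...", c, mz, dmy, mx,
                       optimize=True)
        gx = np.einsum("...onm,...o,...n,...m->...", c, mz, my, dmx,
                       optimize=True)
        return val, gz, gy, gx

    # -- serialization ----------------------------------------------------

    def save(self, path, **extra_attrs) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("coefficients", data=self.coefficients)
            fh.attrs["dt_nm"] = self.dt_nm
            fh.attrs["du_nm"] = self.du_nm
            fh.attrs["z_min_nm"] = self.z_min_nm
            for k, v in extra_attrs.items():
                fh.attrs[k] = v

    @classmethod
    def load(cls, path) -> "CubicSpline3D":
        import h5py

        with h5py.File(path, "r") as fh:
            return cls(
                coefficients=fh["coefficients"][...],
                dt_nm=float(fh.attrs["dt_nm"]),
                du_nm=float(fh.attrs["du_nm"]),
                z_min_nm=float(fh.attrs["z_min_nm"]),
            )


def build_spline_3d(stack: PSFStack) -> CubicSpline3D:
    """Build the tricubic spline interpolating a PSF stack at its knots.

    The stack must have the same number of samples along every axis (callers
    resample z first; see :func:`splinepsf.stack.resample_z`).  The stack is
    up-sampled 4x per axis with 1D natural cubic splines to obtain 64 values
    within each element; applying the inverse monomial basis matrix along
    each axis turns those into the element's 64 polynomial coefficients.
    Because the within-element interpolant of the tensor-product natural
    spline *is* a single tricubic, this recovers it exactly, so the result
    inherits knot exactness and C2 continuity.
    """
    d = np.asarray(stack.data, dtype=float)
    if d.shape[0] != d.shape[1] or d.shape[1] != d.shape[2]:
        raise ValueError(
            "stack must have equal sample counts along z, y, x; "
            "resample z first (stack.resample_z)")
    if d.shape[0] < 2:
        raise ValueError("need at least 2 samples per axis")
    if not np.all(np.isfinite(d)):
        raise ValueError("stack contains non-finite values")

    dense = d
    for ax in range(3):
        dense = upsample_axis(dense, 4, ax)
    n = d.shape[0] - 1
    samples = dense[:-1, :-1, :-1].reshape(n, 4, n, 4, n, 4)
    samples = samples.transpose(0, 2, 4, 1, 3, 5)  # (k, j, i, a, b, c)
    coeffs = np.einsum("oa,nb,mc,kjiabc->kjionm", _IV4, _IV4, _IV4, samples,
                       optimize=True)
    du = stack.z_spacing()
    return CubicSpline3D(
        coefficients=np.ascontiguousarray(coeffs),
        dt_nm=stack.pixel_size,
        du_nm=du,
        z_min_nm=float(stack.z_positions[0]),
    )


# --------------------------------------------------------------------------
# Emitter-centred PSF model
# --------------------------------------------------------------------------

@dataclasses.dataclass
class EmitterParams:
    """One emitter's model parameters.

    x, y in ROI pixel coordinates (sub-pixel, measured from the ROI corner,
    pixel centers at integers); z in nm; h the height (photon-scale
    multiplier of the unit-normalized spline); b the per-pixel baseline.
    """

    x: float
    y: float
    z: float
    h: float
    b: float

    def __post_init__(self) -> None:
        if self.h < 0:
            raise ValueError("height h must be >= 0")
        if self.b < 0:
            raise ValueError("baseline b must be >= 0")

    def to_array(self) -> np.ndarray:
        # canonical parameter-vector order used by the fit driver
        return np.array([self.h, self.x, self.y, self.z, self.b], dtype=float)


_SUPPORT_TOL = 1e-9


@dataclasses.dataclass
class SplinePSF:
    """A 3D spline PSF plus the coordinate mapping used for fitting.

    Wraps a :class:`CubicSpline3D` whose lateral knots are spaced at half
    the camera pixel.  Provides the five-parameter emitter model and its
    analytical gradient.
    """

    spline: CubicSpline3D
    pixel_size: float  # camera pixel, nm

    def __post_init__(self) -> None:
        nzi, nyi, nxi = self.spline.n_intervals
        if nyi != nxi:
            raise ValueError("lateral support must be square")
        self._kpp = self.pixel_size / self.spline.dt_nm  # knots per pixel (2)
        self._c0 = nxi / 2.0  # spline center, interval units

    # -- geometry ---------------------------------------------------------

    @property
    def support_pixels(self) -> float:
        """Lateral extent of the spline support in camera pixels."""
        return self.spline.n_intervals[2] / self._kpp

    @property
    def z_min(self) -> float:
        return self.spline.z_min_nm

    @property
    def z_max(self) -> float:
        return self.spline.z_min_nm + self.spline.n_intervals[0] * self.spline.du_nm

    def position_bounds(self, roi_shape) -> tuple[tuple[float, float], tuple[float, float]]:
        """Allowed (x, y) box for an emitter so every ROI pixel stays in support."""
        ry, rx = roi_shape
        half = self._c0 / self._kpp
        return ((rx - 1 - half, half), (ry - 1 - half, half))

    # -- model ------------------------------------------------------------

    def _map(self, params: EmitterParams, roi_shape):
        ry, rx = roi_shape
        tx = self._kpp * (np.arange(rx) - params.x) + self._c0
        ty = self._kpp * (np.arange(ry) - params.y) + self._c0
        nzi, nyi, nxi = self.spline.n_intervals
        tz = (params.z - self.spline.z_min_nm) / self.spline.du_nm
        if (tx[0] < -_SUPPORT_TOL or tx[-1] > nxi + _SUPPORT_TOL
                or ty[0] < -_SUPPORT_TOL or ty[-1] > nyi + _SUPPORT_TOL):
            raise OutOfSupportError(
                f"emitter at ({params.x:.3f}, {params.y:.3f}) px maps ROI "
                f"pixels outside the spline support")
        if tz < -_SUPPORT_TOL or tz > nzi + _SUPPORT_TOL:
            raise OutOfSupportError(
                f"z = {params.z:.1f} nm outside the spline support "
                f"[{self.z_min:.1f}, {self.z_max:.1f}] nm")
        return tz, ty, tx

    def model_image(self, params: EmitterParams, roi_shape) -> np.ndarray:
        """h * spline((x - x_c, y - y_c, z_c)) + b on the ROI pixel grid."""
        tz, ty, tx = self._map(params, roi_shape)
        s = self.spline.evaluate(tz, ty[:, None], tx[None, :])
        return params.h * s + params.b

    def model_image_with_gradient(self, params: EmitterParams, roi_shape):
        """Model image and its 5 partials, ordered (h, x_c, y_c, z_c, b).

        Sign conventions follow the emitter-centred model: the x_c and y_c
        partials carry a minus sign (moving the emitter right shifts the
        pattern right), the z_c partial is positive.  x/y derivatives are
        per pixel, z per nm.
        """
        tz, ty, tx = self._map(params, roi_shape)
        s, gz, gy, gx = self.spline.evaluate_with_gradient(
            tz, ty[:, None], tx[None, :])
        h = params.h
        f = h * s + params.b
        jac = np.stack([
            s,
            -h * self._kpp * gx,
            -h * self._kpp * gy,
            h * gz / self.spline.du_nm,
            np.ones_like(s),
        ])
        return f, jac

    # -- construction -----------------------------------------------------

    @classmethod
    def from_psf_stack(cls, stack: PSFStack, pixel_size: float | None = None,
                       normalize: bool = True) -> "SplinePSF":
        """Build a fitting model from a PSF stack sampled at half-pixel knots.

        If the stack's z sample count differs from its lateral count it is
        first resampled in z (3rd-order) so the spline has an equal number
        of elements per axis.  With ``normalize`` the coefficients are
        scaled so the in-focus model image integrates to 1 over the camera
        pixel grid, making the fitted height ``h`` the photon number.
        """
        n = stack.data.shape[-1]
        if stack.data.shape[1] != n:
            raise ValueError("lateral axes must have equal sample counts")
        if stack.data.shape[0] != n:
            stack = resample_z(stack, n)
        spline = build_spline_3d(stack)
        px = pixel_size if pixel_size is not None else 2.0 * stack.pixel_size
        obj = cls(spline, px)
        if normalize:
            obj._normalize()
        return obj

    def _normalize(self) -> None:
        size = int(round(self.support_pixels))
        center = (size - 1) / 2.0
        z0 = min(max(0.0, self.z_min), self.z_max)
        img = self.model_image(
            EmitterParams(x=center, y=center, z=z0, h=1.0, b=0.0),
            (size, size))
        total = float(img.sum())
        if total <= 0:
            raise ValueError("cannot normalize: non-positive integral")
        self.spline.coefficients /= total

    # -- serialization ----------------------------------------------------

    def save(self, path) -> None:
        self.spline.save(path, pixel_size_nm=self.pixel_size)

    @classmethod
    def load(cls, path) -> "SplinePSF":
        import h5py

        spline = CubicSpline3D.load(path)
        with h5py.File(path, "r") as fh:
            px = float(fh.attrs["pixel_size_nm"])
        return cls(spline, px)


def eval_psf(spline_psf: SplinePSF, params: EmitterParams, roi_shape) -> np.ndarray:
    """Evaluate the emitter model image on a ROI pixel grid."""
    return spline_psf.model_image(params, roi_shape)


def eval_psf_gradient(spline_psf: SplinePSF, params: EmitterParams, roi_shape) -> np.ndarray:
    """The five partial-derivative images, ordered (h, x_c, y_c, z_c, b)."""
    return spline_psf.model_image_with_gradient(params, roi_shape)[1]


# --------------------------------------------------------------------------
# Operation counting
# --------------------------------------------------------------------------

def spline_eval_operations(order: int = 3, ndim: int = 3) -> int:
    """Multiply+add count of one spline-model point evaluation.

    With the monomial products precomputed (they are identical at the same
    within-interval offset), evaluating the polynomial costs one multiply
    and one accumulate per coefficient: ``2 * (order + 1)**ndim``, i.e. 128
    for the tricubic used here and 8 for a plain 1D cubic.
    """
    if order < 0 or ndim < 1:
        raise ValueError("order must be >= 0 and ndim >= 1")
    return 2 * (order + 1) ** ndim


def gaussian_eval_operations() -> int:
    """Multiply+add count of one elliptical-Gaussian point evaluation.

    With the z-dependent widths precomputed, the per-point cost enumerates
    as: (x - x0), square, divide by w_x, (y - y0), square, divide by w_y,
    add the two exponent terms, exponential, multiply by the amplitude, add
    the baseline -- 10 operations.
    """
    return 10


def count_eval_operations(model: str = "spline", order: int = 3, ndim: int = 3) -> int:
    """Operation count for a single-point model evaluation.

    ``model`` is ``"spline"`` (default tricubic: 128) or ``"gaussian"``
    (elliptical Gaussian: 10).
    """
    if model == "spline":
        return spline_eval_operations(order=order, ndim=ndim)
    if model == "gaussian":
        return gaussian_eval_operations()
    raise ValueError(f"unknown model {model!r}")
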