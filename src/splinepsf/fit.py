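"""Poisson maximum-likelihood fitting and the Cramér–Rao lower bound.

The fit minimizes the Poisson deviance

    chi2_mle = 2 sum_i (f_i - x_i) - 2 sum_{i: x_i != 0} x_i ln(f_i / x_i)

over the five emitter parameters with a damped (Levenberg–Marquardt)
Gauss–Newton scheme.  The gradient is
``2 sum (1 - x_i/f_i) df_i/dp_k`` and the approximate Hessian drops the
second-derivative terms, leaving the weighted Gram matrix
``2 sum (df/dp_k)(df/dp_l) x_i / f_i^2`` — symmetric and positive
semi-definite by construction.

Damping schedule: the damped system is ``H + lambda * diag(H)``; lambda
starts at 1, is divided by 10 on an accepted step and multiplied by 10 on
a rejected one.  Convergence is declared on an accepted step whose
relative deviance change is below 1e-6, or whose parameter step is below
(1e-4 px, 1e-4 px, 0.1 nm) in (x, y, z).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .gaussian import GaussianCalibration, GaussianPSFModel
from .splines import EmitterParams, OutOfSupportError, SplinePSF

__all__ = [
    "MODEL_FLOOR",
    "chi2_mle",
    "chi2_gradient_hessian",
    "Localization",
    "CRLBResult",
    "SplineFitModel",
    "LMState",
    "lm_init",
    "lm_step",
    "lm_fit",
    "fit_spline",
    "fit_gaussian",
    "crlb",
]

MODEL_FLOOR = 1e-6  # photons; the deviance is undefined at f = 0

_LAMBDA_INIT = 1.0
_LAMBDA_UP = 10.0
_LAMBDA_DOWN = 10.0
_LAMBDA_MIN = 1e-12
_LAMBDA_MAX = 1e15
_CHI2_RTOL = 1e-6
# default per-parameter step tolerances for the (h, x, y, z, b) layout:
# 1e-4 px laterally, 0.1 nm axially; h and b are not step-gated
_DEFAULT_STEP_TOL = np.array([np.inf, 1e-4, 1e-4, 0.1, np.inf])


def chi2_mle(f: np.ndarray, x: np.ndarray) -> float:
    """Poisson MLE deviance between a model image f and data x.

    Pixels with zero counts are excluded from the log term exactly as the
    summation bound requires.  ``f`` must be strictly positive (callers
    clamp to :data:`MODEL_FLOOR` first); ``x`` must be non-negative.
    """
    f = np.asarray(f, dtype=float)
    x = np.asarray(x, dtype=float)
    if f.shape != x.shape:
        raise ValueError("model and data shapes differ")
    if np.any(f <= 0):
        raise ValueError("model image must be strictly positive")
    if np.any(x < 0):
        raise ValueError("data must be non-negative")
    term1 = 2.0 * float(np.sum(f - x))
    mask = x > 0
    term2 = 2.0 * float(np.sum(x[mask] * np.log(f[mask] / x[mask])))
    return term1 - term2


def chi2_gradient_hessian(f: np.ndarray, x: np.ndarray,
                          jac: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gradient and Gauss–Newton Hessian of the deviance.

    ``jac`` holds the model partials, shape ``(n_params, ry, rx)``.
    """
    f = np.asarray(f, dtype=float)
    x = np.asarray(x, dtype=float)
    jac = np.asarray(jac, dtype=float)
    if jac.shape[1:] != f.shape or f.shape != x.shape:
        raise ValueError("dimension mismatch between model, data and partials")
    r = 1.0 - x / f
    grad = 2.0 * np.einsum("kij,ij->k", jac, r)
    w = x / f**2
    hess = 2.0 * np.einsum("kij,lij,ij->kl", jac, jac, w, optimize=True)
    return grad, hess


# --------------------------------------------------------------------------
# Records
# --------------------------------------------------------------------------

@dataclasses.dataclass
class Localization:
    """One fitted emitter."""

    x: float            # pixels, frame coordinates
    y: float
    z: float            # nm
    photons: float      # fitted height h (photon number for a unit-sum spline)
    background: float   # per-pixel baseline b
    chi2: float
    iterations: int
    status: str         # 'converged' | 'max_iterations' | 'failed'
    frame: int = 0


@dataclasses.dataclass
class CRLBResult:
    """Per-parameter lower-bound standard deviations of an ideal estimator."""

    x_nm: float
    y_nm: float
    z_nm: float
    photons: float
    background: float


# --------------------------------------------------------------------------
# Models
# --------------------------------------------------------------------------

class SplineFitModel:
    """Spline emitter model exposed with the fit driver's interface.

    Parameter vector order: (h, x, y, z, b); x, y in ROI pixels, z in nm.
    """

    param_names = ("h", "x", "y", "z", "b")

    def __init__(self, spline_psf: SplinePSF):
        self.spline_psf = spline_psf

    def _params(self, p) -> EmitterParams:
        return EmitterParams(x=p[1], y=p[2], z=p[3], h=max(p[0], 0.0),
                             b=max(p[4], 0.0))

    def model_image(self, p, roi_shape) -> np.ndarray:
        return self.spline_psf.model_image(self._params(p), roi_shape)

    def model_image_with_gradient(self, p, roi_shape):
        return self.spline_psf.model_image_with_gradient(
            self._params(p), roi_shape)

    def clamp(self, p, roi_shape) -> np.ndarray:
        p = np.asarray(p, dtype=float).copy()
        (xlo, xhi), (ylo, yhi) = self.spline_psf.position_bounds(roi_shape)
        eps = 1e-3
        p[0] = max(p[0], 1e-3)
        p[1] = np.clip(p[1], xlo + eps, xhi - eps)
        p[2] = np.clip(p[2], ylo + eps, yhi - eps)
        zpad = 0.5  # nm, keeps the model differentiable inside the support
        p[3] = np.clip(p[3], self.spline_psf.z_min + zpad,
                       self.spline_psf.z_max - zpad)
        p[4] = max(p[4], 0.0)
        return p


# --------------------------------------------------------------------------
# Levenberg–Marquardt
# --------------------------------------------------------------------------

@dataclasses.dataclass
class LMState:
    """Mutable state of one emitter's LM optimization."""

    p: np.ndarray
    f: np.ndarray
    jac: np.ndarray
    chi2: float
    lam: float = _LAMBDA_INIT
    converged: bool = False
    failed: bool = False
    n_steps: int = 0


def lm_init(model, data: np.ndarray, p0) -> LMState:
    data = np.asarray(data, dtype=float)
    if np.any(data < 0):
        raise ValueError("data must be non-negative")
    p = model.clamp(np.asarray(p0, dtype=float), data.shape)
    f, jac = model.model_image_with_gradient(p, data.shape)
    f = np.maximum(f, MODEL_FLOOR)
    return LMState(p=p, f=f, jac=jac, chi2=chi2_mle(f, data))


def lm_step(model, data: np.ndarray, state: LMState) -> bool:
    """One damped update of the fit parameters; returns True if accepted.

    The deviance is re-evaluated against ``data`` at entry so the state
    stays correct when the data changed between calls (as in the engine,
    where neighboring localizations move).
    """
    data = np.asarray(data, dtype=float)
    state.n_steps += 1
    state.chi2 = chi2_mle(state.f, data)
    grad, hess = chi2_gradient_hessian(state.f, data, state.jac)
    damped = hess + state.lam * np.diag(np.diag(hess))
    try:
        step = np.linalg.solve(damped, -grad)
    except np.linalg.LinAlgError:
        state.lam = min(state.lam * _LAMBDA_UP, _LAMBDA_MAX)
        return False
    if not np.all(np.isfinite(step)):
        state.lam = min(state.lam * _LAMBDA_UP, _LAMBDA_MAX)
        return False
    p_try = model.clamp(state.p + step, data.shape)
    try:
        f_try, jac_try = model.model_image_with_gradient(p_try, data.shape)
    except OutOfSupportError:
        state.failed = True
        return False
    f_try = np.maximum(f_try, MODEL_FLOOR)
    chi2_try = chi2_mle(f_try, data)
    if chi2_try <= state.chi2 + 1e-12:
        dp = np.abs(p_try - state.p)
        rel = (state.chi2 - chi2_try) / max(state.chi2, 1e-30)
        state.p, state.f, state.jac, state.chi2 = p_try, f_try, jac_try, chi2_try
        state.lam = max(state.lam / _LAMBDA_DOWN, _LAMBDA_MIN)
        step_tol = getattr(model, "step_tol", _DEFAULT_STEP_TOL)
        if rel < _CHI2_RTOL or np.all(dp < step_tol):
            state.converged = True
        return True
    state.lam = min(state.lam * _LAMBDA_UP, _LAMBDA_MAX)
    return False


def lm_fit(model, data: np.ndarray, p0, max_iterations: int = 200) -> LMState:
    """Run LM updates until convergence or the iteration cap."""
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    state = lm_init(model, data, p0)
    for _ in range(max_iterations):
        lm_step(model, data, state)
        if state.converged or state.failed:
            break
    return state


def _localization_from_state(state: LMState, frame: int = 0) -> Localization:
    if state.failed:
        status = "failed"
    elif state.converged:
        status = "converged"
    else:
        status = "max_iterations"
    h, x, y, z, b = state.p
    return Localization(x=float(x), y=float(y), z=float(z), photons=float(h),
                        background=float(b), chi2=float(state.chi2),
                        iterations=state.n_steps, status=status, frame=frame)


def _default_spline_init(spline_psf: SplinePSF, image: np.ndarray) -> np.ndarray:
    b0 = float(np.median(np.concatenate([
        image[0, :], image[-1, :], image[:, 0], image[:, -1]])))
    b0 = max(b0, 0.0)
    peak = float(image.max())
    center = EmitterParams(x=(image.shape[1] - 1) / 2.0,
                           y=(image.shape[0] - 1) / 2.0,
                           z=float(np.clip(0.0, spline_psf.z_min,
                                           spline_psf.z_max)),
                           h=1.0, b=0.0)
    model_peak = float(spline_psf.model_image(center, image.shape).max())
    h0 = max((peak - b0) / max(model_peak, 1e-9), 1.0)
    iy, ix = np.unravel_index(int(np.argmax(image)), image.shape)
    return np.array([h0, float(ix), float(iy), center.z, b0])


def fit_spline(spline_psf: SplinePSF, image: np.ndarray, p0=None,
               max_iterations: int = 200, frame: int = 0) -> Localization:
    """MLE fit of one emitter image against the spline PSF model.

    ``p0`` is (h, x, y, z, b); when omitted, the height and position are
    seeded from the brightest pixel and the baseline from the ROI border.
    """
    model = SplineFitModel(spline_psf)
    if p0 is None:
        p0 = _default_spline_init(spline_psf, np.asarray(image, dtype=float))
    state = lm_fit(model, image, p0, max_iterations=max_iterations)
    return _localization_from_state(state, frame=frame)


def fit_gaussian(image: np.ndarray, calibration: GaussianCalibration,
                 pixel_size: float, p0=None, max_iterations: int = 200,
                 frame: int = 0) -> Localization:
    """MLE fit of the elliptical Gaussian (z via the calibration curves).

    ``p0`` is (a, x0, y0, z, b).  The reported ``photons`` field holds the
    fitted amplitude ``a`` (the Gaussian is not unit-normalized).
    """
    image = np.asarray(image, dtype=float)
    model = GaussianPSFModel(calibration, pixel_size)
    if p0 is None:
        b0 = float(np.median(np.concatenate([
            image[0, :], image[-1, :], image[:, 0], image[:, -1]])))
        iy, ix = np.unravel_index(int(np.argmax(image)), image.shape)
        zmid = np.clip(0.0, calibration.z_min, calibration.z_max)
        p0 = [max(image.max() - b0, 1e-3), float(ix), float(iy), float(zmid),
              max(b0, 0.0)]
    state = lm_fit(model, image, p0, max_iterations=max_iterations)
    return _localization_from_state(state, frame=frame)


# --------------------------------------------------------------------------
# Cramér–Rao lower bound
# --------------------------------------------------------------------------

def crlb(spline_psf: SplinePSF, x: float, y: float, z: float,
         photons: float, background: float, roi_shape) -> CRLBResult:
    """CRLB of the five emitter parameters under the Poisson imaging model.

    The Fisher information is ``I_kl = sum_i (1/f_i) (df_i/dp_k)
    (df_i/dp_l)`` evaluated with the spline PSF; the bounds are the square
    roots of the diagonal of its inverse, with x and y converted to nm.
    """
    params = EmitterParams(x=x, y=y, z=z, h=photons, b=background)
    f, jac = spline_psf.model_image_with_gradient(params, roi_shape)
    f = np.maximum(f, MODEL_FLOOR)
    info = np.einsum("kij,lij,ij->kl", jac, jac, 1.0 / f, optimize=True)
    diag = np.diag(info)
    names = ("photons", "x", "y", "z", "background")
    bad = [names[i] for i in range(5) if diag[i] <= 0 or not np.isfinite(diag[i])]
    if bad:
        raise np.linalg.LinAlgError(
            f"Fisher information is degenerate in parameter(s): {', '.join(bad)}")
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        cond = np.abs(diag) / np.abs(diag).max()
        worst = names[int(np.argmin(cond))]
        raise np.linalg.LinAlgError(
            f"singular Fisher information (weakest parameter: {worst})") from exc
    sd = np.sqrt(np.diag(cov))
    px = spline_psf.pixel_size
    return CRLBResult(x_nm=sd[1] * px, y_nm=sd[2] * px, z_nm=sd[3],
                      photons=sd[0], background=sd[4])
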