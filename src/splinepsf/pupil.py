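"""Scalar pupil-function PSF simulation.

Generates analytic 3D PSFs (astigmatic, saddle-point, or any Zernike
recipe) by propagating a back-focal-plane pupil field to the image plane.
Defocus is applied as the standard angular-spectrum phase
``exp(i 2 pi z sqrt((n/lambda)^2 - k^2))``.

The image-plane field is computed by an explicit Fourier sum at the
requested pixel positions rather than an FFT, which decouples the image
sampling from the pupil grid and avoids wrap-around artefacts.

Zernike convention: unit-amplitude (not RMS-normalized) polynomials on the
unit pupil disk, coefficients in radians of phase.  Modes are addressed by
``(n, m)`` index pairs or by Noll index.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np

from .stack import PSFStack

__all__ = [
    "zernike",
    "zernike_phase",
    "noll_to_nm",
    "PupilFunction",
    "astigmatic_pupil",
    "saddlepoint_pupil",
    "make_astigmatic_psf",
    "make_saddlepoint_psf",
    "DEFAULT_SADDLE_RECIPE",
]


# --------------------------------------------------------------------------
# Zernike polynomials
# --------------------------------------------------------------------------

def noll_to_nm(j: int) -> tuple[int, int]:
    """Convert a Noll index (1-based) to the (n, m) index pair."""
    if j < 1:
        raise ValueError("Noll index starts at 1")
    n, j1 = 0, j - 1
    while j1 > n:
        n += 1
        j1 -= n
    m = (-1) ** j * ((n % 2) + 2 * ((j1 + ((n + 1) % 2)) // 2))
    return n, m


def _zernike_radial(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    m = abs(m)
    if (n - m) % 2:
        return np.zeros_like(rho)
    out = np.zeros_like(rho)
    for s in range((n - m) // 2 + 1):
        c = ((-1) ** s * math.factorial(n - s)
             / (math.factorial(s)
                * math.factorial((n + m) // 2 - s)
                * math.factorial((n - m) // 2 - s)))
        out = out + c * rho ** (n - 2 * s)
    return out


def zernike(n: int, m: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Unit-amplitude Zernike polynomial Z_n^m on the unit disk."""
    if n < 0 or abs(m) > n:
        raise ValueError(f"invalid Zernike mode (n={n}, m={m})")
    r = _zernike_radial(n, m, rho)
    if m > 0:
        return r * np.cos(m * theta)
    if m < 0:
        return r * np.sin(-m * theta)
    return r


def zernike_phase(mode, coefficient: float, rho: np.ndarray,
                  theta: np.ndarray) -> np.ndarray:
    """Phase contribution of one Zernike mode, zero outside the unit disk.

    ``mode`` is an ``(n, m)`` pair or a Noll index; ``coefficient`` is in
    radians (unit-amplitude convention).
    """
    if np.isscalar(mode):
        n, m = noll_to_nm(int(mode))
    else:
        n, m = (int(mode[0]), int(mode[1]))
    phase = coefficient * zernike(n, m, rho, theta)
    return np.where(rho <= 1.0, phase, 0.0)


# --------------------------------------------------------------------------
# Pupil function
# --------------------------------------------------------------------------

@dataclasses.dataclass
class PupilFunction:
    """Complex pupil amplitude with Zernike phase aberrations.

    Defaults model typical oil-immersion SMLM optics: NA 1.4, immersion
    index 1.518.  ``zernike_modes`` maps ``(n, m)`` pairs to coefficients
    in radians; ``rotation_deg`` rotates the whole aberration pattern in
    the pupil plane.
    """

    na: float = 1.4
    wavelength: float = 600.0
    n_immersion: float = 1.518
    grid_size: int = 256
    zernike_modes: dict = dataclasses.field(default_factory=dict)
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if not (0 < self.na < self.n_immersion):
            raise ValueError("need 0 < NA < immersion index")
        if self.grid_size < 16:
            raise ValueError("pupil grid too small")

    def _grids(self):
        kmax = self.na / self.wavelength
        k = np.linspace(-kmax, kmax, self.grid_size)
        kx, ky = np.meshgrid(k, k)
        k2 = kx**2 + ky**2
        mask = k2 <= kmax**2 * (1 + 1e-12)
        rho = np.sqrt(k2) / kmax
        theta = np.arctan2(ky, kx) - np.deg2rad(self.rotation_deg)
        return k, k2, mask, rho, theta

    def pupil_field(self) -> np.ndarray:
        """Complex pupil amplitude on the k grid (zero outside the NA disk)."""
        _, _, mask, rho, theta = self._grids()
        phase = np.zeros_like(rho)
        for mode, coeff in self.zernike_modes.items():
            phase += zernike_phase(mode, coeff, rho, theta)
        return np.where(mask, np.exp(1j * phase), 0.0)

    def psf_stack(self, z_positions, pixel_size: float,
                  roi_size: int) -> PSFStack:
        """Noise-free PSF images at the given z positions.

        The emitter sits at the geometric center of the ``roi_size`` x
        ``roi_size`` grid sampled at ``pixel_size`` nm.  All slices share a
        single normalization such that the slice closest to focus
        integrates to 1.
        """
        if pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        z_positions = np.atleast_1d(np.asarray(z_positions, dtype=float))
        k, k2, mask, _, _ = self._grids()
        pupil = self.pupil_field()
        kz = np.sqrt(np.clip((self.n_immersion / self.wavelength) ** 2 - k2,
                             0.0, None))
        x = (np.arange(roi_size) - (roi_size - 1) / 2.0) * pixel_size
        basis = np.exp(2j * np.pi * np.outer(x, k))  # (roi, N)
        data = np.empty((z_positions.size, roi_size, roi_size))
        for i, z in enumerate(z_positions):
            field = pupil * np.exp(2j * np.pi * z * kz)
            image = basis @ field @ basis.T  # rows: y, cols: x
            data[i] = np.abs(image) ** 2
        focus = int(np.argmin(np.abs(z_positions)))
        total = data[focus].sum()
        if total > 0:
            data /= total
        return PSFStack(data, z_positions, pixel_size, self.wavelength)


# --------------------------------------------------------------------------
# Standard engineered PSFs
# --------------------------------------------------------------------------

def astigmatic_pupil(z22: float = 1.3, **kwargs) -> PupilFunction:
    """Purely astigmatic pupil (Zernike mode z22, default 1.3 rad)."""
    return PupilFunction(zernike_modes={(2, 2): z22}, **kwargs)


# Package-default saddle-point recipe: oblique primary + secondary
# astigmatism, rotated 45 degrees so the two lobes stretch along the x and
# y axes.  This is a configurable stand-in recipe chosen for its lobe
# geometry; any Zernike dictionary may be supplied instead.
DEFAULT_SADDLE_RECIPE: dict = {(2, -2): 1.0, (4, -2): 1.0}


def saddlepoint_pupil(recipe: dict | None = None, rotation_deg: float = 45.0,
                      **kwargs) -> PupilFunction:
    if recipe is None:
        recipe = dict(DEFAULT_SADDLE_RECIPE)
    if not any(abs(c) > 0 for c in recipe.values()):
        warnings.warn("saddle-point recipe has all-zero coefficients; "
                      "the PSF degenerates to the unaberrated spot")
    return PupilFunction(zernike_modes=dict(recipe),
                         rotation_deg=rotation_deg, **kwargs)


def make_astigmatic_psf(z_positions, pixel_size: float = 160.0,
                        roi_size: int = 57, z22: float = 1.3,
                        **kwargs) -> PSFStack:
    return astigmatic_pupil(z22=z22, **kwargs).psf_stack(
        z_positions, pixel_size, roi_size)


def make_saddlepoint_psf(z_positions, pixel_size: float = 160.0,
                         roi_size: int = 57, recipe: dict | None = None,
                         rotation_deg: float = 45.0, **kwargs) -> PSFStack:
    return saddlepoint_pupil(recipe=recipe, rotation_deg=rotation_deg,
                             **kwargs).psf_stack(z_positions, pixel_size,
                                                 roi_size)
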