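"""PSF stack container.

A :class:`PSFStack` holds a 3D array of PSF intensities over (z, y, x)
together with the physical z position of every slice and the lateral
sampling interval.  It is the common currency between the pupil-function
simulator, the bead-scan measurement pipeline and the spline builder.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["PSFStack", "resample_z"]


@dataclasses.dataclass
class PSFStack:
    """A sampled 3D point spread function.

    Parameters
    ----------
    data:
        Intensities, shape ``(nz, ny, nx)``.  Dimensionless (normalization
        is applied downstream when the stack becomes a fitting model).
    z_positions:
        Physical z position of each slice in nm, length ``nz``.
    pixel_size:
        Lateral sampling interval of the stack in nm.  Note this is the
        sampling of *this array*, which for spline knots is half the camera
        pixel, and for 4x up-sampled simulation inputs a quarter of it.
    wavelength:
        Emission wavelength in nm (metadata).
    """

    data: np.ndarray
    z_positions: np.ndarray
    pixel_size: float
    wavelength: float = 600.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.z_positions = np.asarray(self.z_positions, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("PSFStack data must be 3D (z, y, x)")
        if self.z_positions.shape != (self.data.shape[0],):
            raise ValueError("z_positions length must match number of slices")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("PSFStack data contains non-finite values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def focus_index(self) -> int:
        """Index of the slice closest to z = 0."""
        return int(np.argmin(np.abs(self.z_positions)))

    def z_spacing(self) -> float:
        """Uniform z spacing in nm; raises if the sampling is not uniform."""
        dz = np.diff(self.z_positions)
        if dz.size == 0:
            raise ValueError("stack has a single slice, no z spacing")
        if not np.allclose(dz, dz[0], rtol=1e-6, atol=1e-6):
            raise ValueError("z sampling is not uniform")
        return float(dz[0])


def resample_z(stack: PSFStack, n_slices: int) -> PSFStack:
    """Resample a stack in z to ``n_slices`` uniformly spaced slices.

    Uses 3rd-order (natural cubic spline) interpolation along z, matching
    the interpolation order used laterally.  The output spans the same
    physical z range as the input.
    """
    from .splines import spline_sample_axis  # local import, avoids cycle

    if n_slices < 2:
        raise ValueError("need at least 2 output slices")
    nz = stack.data.shape[0]
    if nz < 2:
        raise ValueError("need at least 2 input slices to resample")
    positions = np.linspace(0.0, nz - 1.0, n_slices)
    data = spline_sample_axis(stack.data, positions, axis=0)
    z_new = np.interp(positions, np.arange(nz), stack.z_positions)
    return PSFStack(data, z_new, stack.pixel_size, stack.wavelength)
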