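"""Shared fixtures: small but realistic PSF models built once per session."""

import numpy as np
import pytest

from splinepsf.evaluation import reference_psf, spline_from_reference
from splinepsf.gaussian import fit_gaussian_calibration, mle_fit_gaussian_widths
from splinepsf.splines import EmitterParams


@pytest.fixture(scope="session")
def ref_astig():
    """Astigmatic pupil PSF sampled directly on the half-pixel knot grid.

    Covers the 14 px spline support at 80 nm lateral sampling, z from
    -600 to +600 nm in 50 nm steps (25 slices).
    """
    return reference_psf("astigmatic", z_half=600.0, z_step=50.0,
                         oversample=2)


@pytest.fixture(scope="session")
def spline_astig(ref_astig):
    """Normalized spline fitting model (photons = h) for the astigmatic PSF."""
    return spline_from_reference(ref_astig, oversample=2, normalize=True)


@pytest.fixture(scope="session")
def spline_symmetric():
    """Unaberrated (symmetric) PSF spline, for symmetry-sensitive checks."""
    ref = reference_psf("astigmatic", z_half=600.0, z_step=50.0,
                        oversample=2, z22=0.0)
    return spline_from_reference(ref, oversample=2, normalize=True)


@pytest.fixture(scope="session")
def gauss_calib(spline_astig):
    """Gaussian w_x/w_y calibration measured from the astigmatic spline."""
    zs = np.arange(-500.0, 501.0, 50.0)
    wx, wy = [], []
    for z in zs:
        img = np.clip(spline_astig.model_image(
            EmitterParams(x=7.0, y=7.0, z=float(z), h=4000.0, b=100.0),
            (15, 15)), 0.0, None)
        res = mle_fit_gaussian_widths(img)
        wx.append(res["wx"])
        wy.append(res["wy"])
    return fit_gaussian_calibration(zs, wx, wy)
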