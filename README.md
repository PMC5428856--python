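# splinepsf

3D single-molecule localization microscopy (SMLM) analysis with cubic-spline
PSF models.

In SMLM the achievable resolution depends on how well the fitting model
matches the microscope's point spread function (PSF). Analytical models such
as the elliptical Gaussian are cheap but cannot capture engineered 3D PSFs
(astigmatic, saddle-point, double-helix); pupil-function models are accurate
but expensive to evaluate. `splinepsf` takes the middle road: it represents
*any* measured or simulated 3D PSF as a piecewise tricubic polynomial

```
f(x, y, z) = h · Σ_{m,n,o=0..3} a_{ijk,mno} u^m v^n w^o + b
```

on half-pixel lateral intervals (u, v, w are the normalized within-interval
offsets; h is the height in photons, b the per-pixel baseline), and localizes
emitters by maximizing the Poisson likelihood

```
χ²_mle = 2 Σ_i (f_i − x_i) − 2 Σ_{i: x_i≠0} x_i ln(f_i / x_i)
```

with a damped Gauss–Newton (Levenberg–Marquardt) scheme driven by the
spline's analytical partial derivatives. A point evaluation of the tricubic
costs 128 multiply/adds versus 10 for the Gaussian, so spline fitting stays
within a small constant factor of Gaussian fitting while modeling arbitrary
PSF shapes. Cramér–Rao lower bounds (CRLB) are computed from the same model
via the Poisson Fisher information.

The package is aimed at microscopists who want accurate 3D fitting for
engineered PSFs without GPU pupil-function fitting: it measures a PSF from
bead z-scans (crop, 2× up-sample, centroid-align, average, 50 nm z-bins),
builds the spline, runs a full find/fit/filter analysis engine on movies, and
ships a pupil-function simulator (Zernike aberrations, scalar diffraction)
plus a synthetic-data generator for validation.

## Worked example

Simulate a sparse astigmatic-PSF field (50 emitters at 4000 photons over a
constant background of 100 photons/pixel, 160 nm pixels, z within ±300 nm),
analyze it blind, and score against the ground truth:

```python
import numpy as np
from splinepsf.evaluation import reference_psf, spline_from_reference
from splinepsf.simulate import uniform_emitters, render_movie, match_and_score
from splinepsf.engine import analyze_movie
from splinepsf.config import AnalysisConfig
from splinepsf.io import localizations_to_frame

ref = reference_psf("astigmatic")            # pupil PSF, z22 = 1.3 rad
spline = spline_from_reference(ref)          # half-pixel-knot spline model
truth = uniform_emitters(50, shape=(256, 256), z_range=300,
                         photons=4000, background=100, seed=5)
movie = render_movie(truth, spline, noise=True, seed=5)
locs = analyze_movie(movie, spline, AnalysisConfig())
df = localizations_to_frame(locs, 160.0).rename(
    columns={"x_px": "x", "y_px": "y", "z_nm": "z"})
res = match_and_score(df, truth)
print(f"recall {res['recall']:.3f}  false positives {res['n_false_positive']}")
print(f"mean |error|: x {res['mean_dx_nm']:.2f}  y {res['mean_dy_nm']:.2f} "
      f"z {res['mean_dz_nm']:.2f} nm")
```

Output:

```
recall 1.000  false positives 0
mean |error|: x 1.69  y 1.95 z 5.86 nm
```

All 50 emitters are recovered with no false detections; the mean lateral
errors of ~2 nm and axial error of ~6 nm are at the CRLB for these photon
counts (compare `splinepsf.fit.crlb`).

The same pipeline is available from the shell:

```bash
splinepsf simulate --out sim --n-emitters 50 --seed 5
splinepsf analyze --movie sim/movie.tif --spline sim/spline.h5 --out locs.csv
splinepsf evaluate --found locs.csv --truth sim/truth.csv
```

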