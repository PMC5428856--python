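# Methods

## The spline PSF model

A 1D natural cubic spline approximates a function by per-interval cubics
`f_i(t) = a_i t³ + b_i t² + c_i t + d_i` (t the normalized offset within
interval i) with value and first derivative continuous at interval
boundaries and zero second derivative at the two outer knots. The
coefficients come from the classic tridiagonal system for the knot second
derivatives; the solver is implemented in-package (and is cross-checked in
the tests against `scipy.interpolate.CubicSpline(bc_type="natural")` and a
dense linear-system oracle).

The 3D model is the tensor-product extension: within element (i, j, k) the
PSF is a tricubic with 64 coefficients `a_{ijk,mno}`. Construction follows
the sample-then-solve route: the knot grid is up-sampled 4× per axis with
sequential 1D natural splines, giving 64 values inside each element, and a
precomputed inverse monomial basis matrix (4×4 per axis, applied as a
tensor contraction) maps those values to the 64 coefficients. Because the
within-element interpolant of the tensor-product natural spline *is* a
single tricubic, this recovers it exactly — the result interpolates every
knot to machine precision and is C² across element boundaries.

Conventions: lateral intervals are half a camera pixel (a spline supporting
S pixels has 2S intervals per lateral axis; default S = 14, sensible range
12–16); the axial sampling is resampled (3rd-order, in-package) so the
element count matches the lateral one, with the physical interval Δu
recorded in nm. Pixel centers sit at integer coordinates; the emitter
position maps to the center of the spline support; evaluation outside the
support raises instead of extrapolating (cubic extrapolation diverges).
The emitter model is `f = h·s(x−x_c, y−y_c, z_c) + b` with analytical
partials in (h, x_c, y_c, z_c, b); the spline coefficients are normalized
so the in-focus model image integrates to 1 over the camera grid, making
`h` the photon number.

A note on a boundary-condition subtlety: a *natural* spline cannot
reproduce a generic cubic polynomial exactly — the zero-curvature end
condition injects an error that decays geometrically (≈0.27× per interval)
away from the boundary. The property tests therefore assert exact knot
interpolation and exact linear reproduction everywhere, and cubic
reproduction on interior intervals only.

## Pupil-function simulation

Engineered PSFs are generated from a scalar pupil model: a uniform
amplitude on the NA-limited disk with Zernike phase aberrations
(unit-amplitude polynomials, coefficients in radians), defocus applied as
the angular-spectrum phase `exp(i·2π·z·sqrt((n/λ)² − k²))`. Defaults model
oil-immersion SMLM optics: NA 1.4, immersion index 1.518, 600 nm emission,
160 nm camera pixels. The image-plane field is computed by an explicit
Fourier sum at the requested pixel positions (matrix DFT, pupil grid 256
samples across the disk) rather than an FFT — this decouples image sampling
from the pupil grid, avoids wrap-around, and allows arbitrary over-sampling
for reference grids. Stacks share one normalization (in-focus slice sums
to 1).

The astigmatic PSF uses Zernike mode (2, 2) with coefficient 1.3 rad. The
saddle-point PSF is generated from a configurable Zernike recipe; the
package default — oblique primary plus secondary astigmatism,
{(2,−2): 1.0, (4,−2): 1.0}, rotated 45° so the lobes stretch along the x
and y axes — is this package's own choice of a lobed, z-degenerate-free
profile, not a published prescription; any recipe dictionary can be
supplied instead.

## Gaussian comparison model and z calibration

The comparison model is the elliptical Gaussian
`f = a·exp(−(x−x₀)²/w_x(z) − (y−y₀)²/w_y(z)) + b` with the width terms
appearing unsquared in the denominator, so `w` plays the role of `2σ²`
(px²). The defocus calibration is applied on the σ scale with the standard
astigmatism form `s(z) = s₀·sqrt(1 + r² + A r³ + B r⁴)`, `r = (z−c)/d`
(s₀ in px; c, d in nm; A, B dimensionless), and `w(z) = 2 s(z)²`. Fitting
the sqrt form directly to the squared-width scale misrepresents the
near-quadratic defocus law and produces spurious extra w_x/w_y crossings.

Calibration widths are measured with a *free-width Poisson-MLE* Gaussian
fit at the study photon and background levels, not by least squares: the
z fit later applies Poisson weighting, and a least-squares calibration is
inconsistent with it at the image tails, which we measured to bias z by
tens of nm. The z fit itself optimizes (a, x₀, y₀, z, b) with z driving
both widths through the calibration curves, using the same deviance
machinery as the spline fit.

## MLE fitting

The objective is the Poisson deviance (zero-count pixels excluded from the
log term); its gradient uses the model partials and the approximate Hessian
drops second-derivative terms, giving a symmetric PSD weighted Gram matrix.
The damped update solves `(H + λ·diag(H)) δ = −g` with λ starting at 1,
÷10 on accepted and ×10 on rejected steps. Convergence is declared on an
accepted step with relative deviance change below 1e-6 or with the
parameter step below per-parameter gates (1e-4 px laterally, 0.1 nm
axially for the emitter models; width-scale gates for the free-width
Gaussian). Model images are floored at 1e-6 photons before logs and
divisions; positions are clamped to the spline support. The iteration cap
defaults to 200; isolated emitters with truth-adjacent starts converge in
a median of ~6 updates.

The CRLB uses the Poisson Fisher information
`I_kl = Σ_i (1/f_i)(∂f_i/∂p_k)(∂f_i/∂p_l)` evaluated with the spline
model; bounds are square roots of the inverse's diagonal, lateral entries
converted to nm by the pixel size.

## Analysis engine

Per frame: estimate the background (wide Gaussian smoothing, σ = 8 px —
the method is an implementation choice); find candidates as strict local
maxima of the residual correlated with the unit-sum spline PSF at one or
more z planes (3D maxima across planes when several are used), thresholded
at 6× the shot-noise standard deviation of the convolved background;
iterate per-localization damped updates with all other localizations held
fixed (cross-terms between overlapping emitters are deliberately ignored,
trading convergence speed for simplicity) with add-back/subtract
bookkeeping on a shared model image; discard localizations with a strictly
brighter neighbor within 5 px (ties discard the later-found one) and
re-flag their neighbors as unconverged; re-estimate the background on the
localization-subtracted image; repeat up to 3 times or until no new peaks
appear. The residual + background + Σ models = raw-image identity is
maintained exactly and asserted in tests. The engine contains no
randomness. Multi-plane finding is off by default — it only helps PSFs
that are not z-degenerate (e.g. double-helix, supported as a user-supplied
PSF stack).

## PSF measurement pipeline

From a bead/emitter z-scan movie: crop isolated emitters around nominal
locations (skipping those near edges or neighbors), up-sample each crop 2×
laterally, shift each to its background-subtracted intensity centroid,
average per z position, and average again over 50 nm z bins (half-open
intervals centered on multiples of the bin width). The 2× up-sampling uses
the package's exact half-pixel natural-spline interpolation (original
pixel centers preserved); the centroid shift uses `scipy.ndimage.shift`.
When true locations are unknown, `estimate_locations` seeds them with the
package's own Gaussian fitter, which is sufficient for bright beads.

Averaging emitters at *staggered sub-pixel phases* is essential, not
cosmetic: the pixel-sampled PSF is under-sampled at the camera pitch, and
a single-phase measurement aliases into a phase-dependent model error that
biases sub-pixel fits by several nm. The residual cost of interpolating
camera-pitch samples onto half-pixel knots, measured against an ideal
spline of the analytic pixel-integrated PSF under identical data, is a
5.6 ± 1.1 % increase in mean lateral error (paired test in the suite).

## Synthetic data and validation design

The simulated study conditions are those of typical astigmatism-based 3D
SMLM: 4000 photons per localization, constant background 100 photons/px,
600 nm emission, 160 nm pixels, pure Poisson noise (no camera read noise,
gain or photophysics), emitter z within ±300 nm of focus. Two renderers
ship: spline-model sub-pixel placement (used by the engine tests), and
calibration-style placement of a 4×-up-sampled PSF followed by 4×4
block-sum down-sampling, which approximates pixel integration and
conserves flux exactly.

The benchmark localization study is deliberately end-to-end realistic:
test emitters are rendered by integrated placement (lateral positions on
the quarter-pixel lattice, z on the scanned 10 nm grid), while the fitting
spline and the Gaussian calibration come from the measurement pipeline run
on a synthetic calibration scan (4×4 grid, staggered quarter-pixel
phases). Rendering and fitting with the same exact spline would let the
spline fitter attain the CRLB exactly and overstate its advantage; the
measured-model route carries realistic calibration error, reproducing both
the spline's advantage over the Gaussian (≈20 % in mean |z| error within
±300 nm, ≈3–6 % laterally at ±300 nm defocus) and its slight departure
from the CRLB at large defocus. What passing these tests does *not* show:
robustness to read noise, gain miscalibration, field-dependent PSFs,
emitter blinking within a frame, or drift — none of which the generator
emulates.

Scoring matches each localization to its nearest ground-truth emitter
(lateral Euclidean, 2 px match radius; farther matches count as false
positives) and reports per-axis mean absolute errors, binned by true z in
100 nm bins, with optional CRLB overlay.

## Problem sizes and numerical choices

The shipped benchmark uses 2000 emitters for the accuracy comparison, 500
for the convergence study, 250 repeats per fixed truth for CRLB
attainment, and 201 z slices for the ±1 µm fidelity scans — sizes chosen
so the whole validation runs in well under a minute on one CPU while
keeping Monte-Carlo error a few percent. Model-fidelity percentages are
measured on a 4×-oversampled lateral grid so between-knot interpolation
error is visible (at the knots themselves the spline is exact by
construction, and the in-focus core — the sharpest feature — sets the
maximum). Seeds enter every stochastic step through
`numpy.random.default_rng`; identical seeds give bitwise-identical movies
and results.

## Known limitations

* Scalar diffraction only: no vectorial high-NA effects, polarization, or
  index-mismatch aberration in the simulator.
* Poisson noise only: no sCMOS per-pixel noise model or EM-gain excess
  noise in either the generator or the likelihood.
* The per-localization update ignores cross-terms between overlapping
  emitters; very dense data converges slowly or not at all.
* The spline covers a finite support (default 14 px laterally, the
  calibrated z range axially); emitters outside it are reported failed
  rather than extrapolated.
* The natural boundary condition slightly perturbs the outermost spline
  intervals; keep the support a pixel or two larger than the PSF core.
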