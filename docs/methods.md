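# Methods

`contourscope` models a flat, lensless fluorescence microscope in which a
quantized-relief phase mask, a few millimetres above a monochrome CMOS
sensor, turns every point source into a sparse pattern of high-contrast
contours.  Because the pattern varies with source depth, one 2D capture
carries both lateral and axial information, and reconstruction is a
deconvolution problem rather than imaging through a lens.  This note
records the models, the numerical choices, and what the synthetic studies
do and do not demonstrate.

## Contour PSF design

The target PSF is the Canny edge set of a band of Perlin noise, masked to a
circular support and normalized to unit sum.  Perlin noise is the classic
gradient-lattice construction with quintic smoothstep interpolation;
octave k uses lattice spacing `spacing / 2**k` and amplitude
`persistence**k`, and the octave sum is divided by the amplitude sum so any
configuration stays within [-1, 1].  The Canny detector is pinned down to
deterministic semantics so designs are reproducible bit-for-bit and
checkable against brute-force oracles: central-difference gradients,
non-maximum suppression in four quantized directions (a pixel survives when
strictly greater than its negative-side neighbour and at least equal to its
positive-side neighbour, which keeps symmetric step-edge plateaus one pixel
wide), and 8-connected hysteresis with thresholds expressed as fractions of
the maximum gradient magnitude.  Defaults: lattice spacing = size/16, two
octaves, persistence 0.5, sigma 1 px, thresholds 0.1/0.3.  None of these
values is dictated by the physical system; they produce contour fills of
3-15% of the support, inside the intended 2-20% band.

Spectral quality is quantified by the radially averaged modulus of the
PSF's DFT (integer-radius bins, frequencies up to the sensor Nyquist
1000/(2·pitch) cycles/mm) and summarized by a flatness score: the fraction
of radial bins with magnitude at or above a floor.  The reporting default
floor is one LSB of a 12-bit range (1/4096).  For *comparing* binary
patterns of equal fill, that floor does not discriminate: the radial mean
of the spectral modulus of any M-pixel binary pattern sits at the speckle
plateau ~1/sqrt(M), far above 1/4096, so every such pattern scores 1.0.
The comparison tests therefore score both patterns against the common
plateau floor 1/sqrt(M), which asks which design holds genuinely
structured spectral content across the band; the contour design beats an
equal-fill separable (outer-product) pattern on every tested seed.

## Phase mask retrieval

The mask is a phase-only surface relief quantized to six 200 nm levels over
0-1 um, with refractive index 1.55 assumed for the photoresist (not printed
anywhere authoritative) and design wavelength 0.525 um.  Free-space
propagation uses the band-limited angular-spectrum method: the exact scalar
transfer function with evanescent components zeroed and the Matsushima
frequency limit applied; fields are zero-padded 2x by default (trading
exact unitarity, which holds to machine precision at pad factor 1, for
wrap-around suppression at ~1e-7).

Retrieval alternates two projections, Gerchberg-Saxton style, for a point
source at the mid working distance (4 mm): phase-only modulation of the
spherical illumination at the mask plane, and amplitude = sqrt(target) at
the sensor plane.  Two details matter:

- The iteration runs on a 2x padded canvas in which the mask aperture and
  the target window are the central region, and the sensor amplitude is
  constrained *only inside the window*.  Without the free outer region the
  projection pair is inconsistent (the crop discards diffracted light) and
  even a mask that exactly produces the target is not a fixed point.
- Initialization defaults to back-propagating the target amplitude to the
  mask plane.  At these short throws that starts the alternation close to
  a consistent solution; from a uniform-random phase the alternation
  stagnates at intensity correlation ~0.85, while the warm start reaches
  ~0.97 on planted-mask targets even after quantization.  Random seeded
  initialization remains available (`init="random"`).

The minimum fabricable feature width (~6 um) is enforced softly by
low-pass filtering the complex phasor exp(i*phi) (wrap-aware; filtering the
wrapped height map itself would corrupt every 0/2pi seam) before
quantization, which rounds to the nearest 200 nm level with ties up.  The
sensor-plane amplitude error is recorded each iteration (non-increasing for
this projection pair), and the quantized design's propagated intensity is
scored by Pearson correlation against the target (warning below 0.7).

## Forward model and synthetic scenes

Per depth d the system is shift-invariant: b = sum_d p_d * i_d.  Unit
lateral magnification is assumed between scene and sensor grids; geometric
magnification is absorbed into the calibration PSFs, exactly as the
reconstruction formalism treats it.  PSF stacks are simulated by
propagating a spherical wave from each depth through the mask phase,
squaring, and box-integrating (exact area-weighted rebinning, any pitch
ratio) onto the 2.4 um sensor grid; every PSF is normalized to unit sum.
The simulated PSF decorrelates monotonically with depth separation —
asserted, not assumed, since it is the mechanism that makes single-shot 3D
possible.

The virtual sensor covers the scene extent plus half the PSF extent on
each side, so all diffracted light is recorded (the physical 6 MP sensor
likewise exceeds the scene FOV); the scene window's offset travels in the
measurement metadata.  The sensor model is Poisson shot noise at
`photon_scale` counts per unit intensity, additive Gaussian read noise,
clipping to the bit range (default 16) and rounding; the noiseless path is
exactly linear.  In the study pipelines the exposure is auto-scaled so the
clean peak hits one intensity unit, making `photon_scale` the photon count
at the brightest pixel — mirroring the exposure-adjusted, frame-averaged
bench protocol.

Scene generators and their defaults are the study conditions: a three-bar
USAF-style target (bar width 500/2^(g+(e-1)/6) um, length 5x width, both
orientations, probe coordinates in metadata); fluorescent bead volumes at
3.6e4 beads/ml in 3 x 3 x 0.5 mm (Poisson count, expectation 162; uniform
spheres of 10 um rasterized onto 20 um depth slices); a ballistic+diffuse
scattering layer exp(-mu_s z)·I + (1-exp(-mu_s z))·(I*G_z) with mu_s =
1/mm and a Gaussian diffusion kernel growing 100 um of sigma per mm —
only the ballistic law is physics, the diffuse term is a deliberately
simple stand-in; calcium movies as an exact rank-r background (baseline
included in the rank budget) plus Gaussian-blob cells with instant-rise,
exponential-decay transients (tau 0.5 s) grouped into clusters sharing
event times, optionally stimulus-locked within 0.1 s jitter, at 20 Hz; and
microvessel scenes as smooth random walks (boundary-reflecting) rasterized
dark-on-bright with exact centreline and diameter ground truth.

## 2D reconstruction

The Tikhonov-regularized estimate has the closed Wiener form
i = IFT(conj(P)·B / (|P|^2 + gamma)) on a padded circulant canvas; `gamma`
is defined as the denominator constant (equivalently the weight of a plain
quadratic penalty; a formulation with gamma/2 on the penalty corresponds to
doubling it).  The solver is verified against an explicit dense circulant
solve to 1e-8.  Simulated PSFs are embedded at their geometric centre;
centre-of-mass registration — needed for measured calibration frames whose
bead is only approximately centred — lives in `preprocess_calibration`,
because applying it inside the solver shifts the reconstruction relative
to the simulated forward model.  gamma = 0 with spectral zeros raises an
explicit division-guard error.  `gamma` defaults are chosen per study by
maximizing PSNR on a separate synthetic validation scene rendered through
the same PSF and noise model (no regularization weight is printed for the
physical system).

Refocusing reconstructs one capture against each calibrated depth and
selects the depth maximizing Tenengrad sharpness (sum of squared Sobel
magnitudes) in an ROI, ties to the smaller depth.  Bar resolution is the
finest element whose three-bar Michelson contrast — sampled at the bar and
gap centres, averaged along 80% of the bar length — reaches 0.2 in both
orientations (between the Rayleigh ~0.26 and Sparrow 0 conventions).
FWHM interpolates linearly between the samples bracketing half-maximum
(zero baseline) on each side of the peak.

## 3D reconstruction

The multi-depth estimate minimizes ||b - sum_d p_d * i_d||_F^2 +
gamma1 sum_d ||Psi(i_d)||_1 + gamma2 ||i||_1 over i >= 0, with Psi the
circular forward-difference gradient (anisotropic TV) and its exact
adjoint.  Scaled-form ADMM with one penalty rho splits TV, L1 and
non-negativity; the quadratic step is solved exactly per spatial
frequency, where the depth coupling is the rank-one matrix
2 conj(p) p^T + c I inverted by Sherman-Morrison in O(D) — verified
against a dense normal-equation solve to 1e-8.  Stopping uses relative
primal/dual residual norms; hitting the iteration cap returns the iterate
with a false convergence flag rather than raising.  With both weights zero
and non-negativity off the solver reproduces the Wiener solution in the
small-gamma limit to 1e-4 (tested on a well-conditioned system; near
spectral zeros the fixed-point iteration converges arbitrarily slowly, so
small rho ~ 1e-3, which weights the data term, is the practical default
for clean data).

`gamma1 = 1e-5`, `gamma2 = 3e-3`, `rho = 1e-3` and 80 iterations were set
by a grid search maximizing bead-volume F1 (voxels above 10% of peak
against the planted bead) on a fixture bead simulation.  Axial bead width
is measured from the 3x3 lateral max-pooled profile, cubic-spline
interpolated 8x along depth; a bead confined to a single plane reports the
plane spacing with a warning.

## Calcium analysis

Delta F/F uses a per-pixel temporal-percentile baseline (default 10th;
pre-stimulus-window mean available) with an epsilon guard for empty
pixels.  RPCA is the inexact augmented-Lagrange-multiplier iteration —
singular-value thresholding for the low-rank part, soft-thresholding for
the sparse part, dual update, penalty growth 1.5x — with lambda defaulting
to 1/sqrt(max(n_pixels, n_frames)) and stopping at relative residual tol;
it recovers planted rank-2 + 5%-sparse models to 1e-4.  Active pixels
(RMS energy above 3x the MAD of the sparse component — a deliberately
conservative gate that favours precision over recall; the end-to-end test
shows precision 1.0 with core-only recall) are clustered by K-means on
L2-normalized time courses, initialized by deterministic farthest-point
seeding from the seed; clusters below `min_pixels` fall back to
background.  Peak-time maps report the per-pixel argmax time (ms, earliest
tie) in a stimulus-locked window; windowed correlations report per-window
Pearson r with median and IQR using linear-interpolation quartiles
(the convention matters because IQRs are reported); zero-variance windows
are excluded with a warning.  Cluster areas are pixel counts times
(pitch/1000)^2.

## Vessel density

Counting operates on traced centreline polylines, matching the manual
procedure.  The default grid is 2 mm of horizontal plus 2 mm of vertical
line (two 1 mm lines each), and density = crossings of vessels with
diameter strictly below 20 um divided by 4 mm.  Degenerate-contact
conventions (the procedure is silent): a transversal pass-through counts
one, including through a vertex exactly on the line; a touch-and-retreat
counts zero; a collinear overlap adds one per (vessel, grid line).  The
counter is verified against an independently coded geometric oracle and
against shapely in general position.  Aggregation averages raters within a
region, then regions, reporting the s.e.m. (ddof = 1) across regions.

## Study scales and what the tests show

The end-to-end studies run at desk scale: 384 px contour targets, masks at
2 um pitch (~0.9 mm aperture), 26-plane stacks for the bead study, PSFs
cropped to 256 px (the designed support plus margin; sub-percent energy
loss) — sizes chosen so a full study completes in minutes on one CPU.  At
this scale the simulated twin is photon-limited rather than optics-limited:
the reconstruction model matches the rendering model exactly, so the USAF
study resolves to the finest rendered element at realistic photon budgets,
and the measured axial FWHM (~66 um) sits above the ~50 um physical
benchmark because aperture, crop and solver scale are approximations.
Passing these studies demonstrates the correctness and conditioning of the
computational chain — not the aberrations, calibration drift, scattering
background or model mismatch of a physical instrument, which the synthetic
twin deliberately omits.
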