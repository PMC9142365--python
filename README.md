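# contourscope

Computational stack for lensless fluorescence microscopy with an engineered
**contour PSF**: a phase mask a few millimetres above a bare CMOS sensor
turns every point source into a sparse pattern of high-contrast contours
whose spectrum stays flat out to high spatial frequencies.  Because the
pattern changes with source depth, a single 2D capture supports
computational refocusing and 3D reconstruction — the properties that make
flat, lens-free microscopes attractive for in vivo calcium imaging and
clinical microvascular imaging.

The package is aimed at computational-imaging researchers who want a
complete, testable reference for this class of instrument:

- **`contour_psf`** — target PSF synthesis (Perlin noise → Canny edges) and
  MTF/flatness metrology;
- **`mask_design`** — band-limited angular-spectrum propagation and
  near-field phase retrieval producing a fabricable 6-level (200 nm step,
  1 µm total) height map;
- **`optics_sim`** — depth-indexed PSF stacks, the per-depth convolutional
  sensor model `b = Σ_d p_d ∗ i_d` with Poisson/read noise, and synthetic
  scenes: USAF-style bar targets, 10 µm bead phantoms (3.6·10⁴ beads/ml in
  3×3×0.5 mm³), a scattering layer (µs ≈ 1 mm⁻¹), calcium movies, vessel
  scenes;
- **`recon2d`** — closed-form Wiener/Tikhonov deconvolution
  `î = F⁻¹(conj(F p)·F b / (|F p|² + γ))`, computational refocusing,
  bar-contrast resolution and FWHM metrology;
- **`recon3d`** — the multi-depth estimate
  `min_{i≥0} ‖b − Σ_d p_d ∗ i_d‖²_F + γ₁ Σ_d ‖Ψ i_d‖₁ + γ₂ ‖i‖₁`
  solved by scaled-form ADMM with an exact per-frequency
  (Sherman–Morrison) quadratic step, plus axial-profile FWHM;
- **`calcium_analysis`** — ΔF/F, robust PCA (inexact augmented Lagrange
  multipliers), K-means activity clustering, peak-time maps, windowed
  Pearson correlation statistics;
- **`vessel_density`** — grid-crossing capillary density: crossings of
  sub-20 µm vessels over a 2 mm + 2 mm grid, divided by grid length.

## Worked example

```python
import numpy as np
from contourscope.config import OpticalConfig
from contourscope.contour_psf import make_contour_psf, mtf, mtf_flatness_score
from contourscope.mask_design import retrieve_phase
from contourscope.optics_sim import psf_stack_from_mask

cfg = OpticalConfig(mask_pitch_um=2.0)
psf = make_contour_psf(psf_size_px=256, pitch_um=2.4, support_radius_um=150.0, seed=7)
print(f"contour PSF: fill {(psf.intensity > 0).mean():.3f}, "
      f"MTF flatness {mtf_flatness_score(mtf(psf)):.3f}")

result = retrieve_phase(psf, cfg, iterations=60, seed=7)
print(f"mask: {result.height_map.heights_um.shape} px at {cfg.mask_pitch_um} um, "
      f"correlation {result.correlation:.3f}")

stack = psf_stack_from_mask(result.height_map, cfg, [3.9, 4.0, 4.1])
c = [np.corrcoef(stack.psfs[1].ravel(), p.ravel())[0, 1] for p in stack.psfs]
print(f"PSF depth correlation vs 4.0 mm: {c[0]:.3f} (3.9), {c[1]:.3f} (4.0), {c[2]:.3f} (4.1)")
```

prints

```
contour PSF: fill 0.034, MTF flatness 1.000
mask: (307, 307) px at 2.0 um, correlation 0.954
PSF depth correlation vs 4.0 mm: 0.712 (3.9), 1.000 (4.0), 0.726 (4.1)
```

The flatness score of 1.0 says every radial frequency bin up to the sensor
Nyquist carries at least one 12-bit LSB of MTF — the design goal that makes
dense, low-contrast scenes invertible.  The retrieval correlation 0.954 is
the Pearson agreement between the quantized mask's simulated diffraction
pattern and the target.  The depth correlations (~0.7 at ±100 µm) are the
mechanism behind refocusing: PSFs decorrelate with depth, so each depth
plane can be distinguished in reconstruction.

A command-line interface mirrors the library:

```bash
contourscope design-psf --size 384 --support-um 250 --seed 1 --out psf.tif
contourscope design-mask --target psf.tif --iters 60 --seed 1 --out mask.tif
contourscope simulate usaf --mask mask.tif --seed 1 --out run/
contourscope reconstruct2d --measurement run/measurement.tif \
    --psf run/psf_stack.tif --gamma 1e-5 --out recon.tif
contourscope vessels --traces traces.csv
```

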