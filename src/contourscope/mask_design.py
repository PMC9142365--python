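"""Phase-mask design: near-field propagation and iterative phase retrieval.

A phase-only surface-relief mask a few millimetres above the sensor shapes
the diffraction pattern of an incoherent point source into the designed
contour PSF.  The design loop alternates between two constraint sets
(Gerchberg-Saxton style): a phase-only mask illuminated by a spherical wave
at the mask plane, and the square root of the target intensity at the sensor
plane, connected by band-limited angular-spectrum propagation.  The retrieved
continuous phase profile is finally converted to a fabricable height map
quantized to six 200 nm levels spanning 0-1 um.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import OpticalConfig
from .contour_psf import TargetPSF
from .errors import InvalidArgumentError, SamplingError

__all__ = [
    "HeightMap",
    "ComplexField",
    "RetrievalResult",
    "DEFAULT_LEVELS_UM",
    "height_to_phase",
    "propagate",
    "retrieve_phase",
    "quantize_heights",
]

DEFAULT_LEVELS_UM: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass(frozen=True)
class HeightMap:
    """Quantized surface-relief profile of the phase mask."""

    heights_um: np.ndarray
    pitch_um: float
    levels: tuple[float, ...] = DEFAULT_LEVELS_UM

    def __post_init__(self) -> None:
        h = np.asarray(self.heights_um, dtype=float)
        if h.ndim != 2:
            raise InvalidArgumentError("heights_um must be 2D")
        if self.pitch_um <= 0:
            raise InvalidArgumentError("pitch_um must be positive")
        lv = np.asarray(self.levels, dtype=float)
        dist = np.min(np.abs(h[..., None] - lv[None, None, :]), axis=-1)
        if np.any(dist > 1e-9):
            raise InvalidArgumentError("heights must belong to the quantized level set")
        object.__setattr__(self, "heights_um", h)


@dataclass(frozen=True)
class ComplexField:
    """A sampled complex scalar wavefront."""

    values: np.ndarray
    pitch_um: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=complex)
        if v.ndim != 2:
            raise InvalidArgumentError("field must be 2D")
        if not np.all(np.isfinite(v)):
            raise InvalidArgumentError("field values must be finite")
        if self.pitch_um <= 0:
            raise InvalidArgumentError("pitch_um must be positive")
        object.__setattr__(self, "values", v)


@dataclass
class RetrievalResult:
    """Output of :func:`retrieve_phase`.

    ``amplitude_errors[k]`` is the relative sensor-plane amplitude mismatch
    before the k-th projection; for ideal alternating projections it is
    non-increasing.  ``correlation`` is the Pearson correlation between the
    propagated intensity of the quantized mask and the target.
    """

    height_map: HeightMap
    amplitude_errors: list[float] = field(default_factory=list)
    correlation: float = float("nan")
    converged: bool = False


def height_to_phase(heights_um: HeightMap | np.ndarray, wavelength_um: float, n_material: float) -> np.ndarray:
    """Phase delay (radians, mod 2pi) of a relief profile: 2pi (n-1) h / lambda."""
    if n_material <= 1:
        raise InvalidArgumentError("n_material must exceed 1")
    h = heights_um.heights_um if isinstance(heights_um, HeightMap) else np.asarray(heights_um, dtype=float)
    return np.mod(2.0 * np.pi * (n_material - 1.0) * h / wavelength_um, 2.0 * np.pi)


def _transfer_function(shape: tuple[int, int], pitch_um: float, distance_um: float, wavelength_um: float) -> np.ndarray:
    """Band-limited angular-spectrum transfer function (evanescent part zeroed)."""
    fy = np.fft.fftfreq(shape[0], d=pitch_um)
    fx = np.fft.fftfreq(shape[1], d=pitch_um)
    fy2 = fy[:, None] ** 2
    fx2 = fx[None, :] ** 2
    under = 1.0 / wavelength_um**2 - fy2 - fx2
    propagating = under > 0
    kz = np.sqrt(np.where(propagating, under, 0.0))
    h = np.where(propagating, np.exp(2j * np.pi * np.abs(distance_um) * kz), 0.0)
    if distance_um < 0:
        h = np.conj(h)
    # Matsushima band limit suppresses aliased high angles for long throws
    z = np.abs(distance_um)
    if z > 0:
        dfy = 1.0 / (shape[0] * pitch_um)
        dfx = 1.0 / (shape[1] * pitch_um)
        fy_lim = 1.0 / (wavelength_um * np.sqrt((2.0 * dfy * z) ** 2 + 1.0))
        fx_lim = 1.0 / (wavelength_um * np.sqrt((2.0 * dfx * z) ** 2 + 1.0))
        h = np.where((fy2 <= fy_lim**2) & (fx2 <= fx_lim**2), h, 0.0)
    if not np.any(h != 0):
        raise SamplingError("band limit removed every spatial frequency; grid too coarse")
    return h


def propagate(
    wavefront: ComplexField,
    distance_mm: float,
    wavelength_um: float,
    pad_factor: int = 2,
) -> ComplexField:
    """Free-space propagation by the band-limited angular-spectrum method.

    The field is zero-padded by ``pad_factor`` to suppress wrap-around,
    multiplied in the Fourier domain by the exact scalar transfer function
    with evanescent components zeroed, and cropped back.  Propagation of the
    retained (propagating, band-limited) components is unitary, so forward
    followed by backward propagation restores a band-limited field.
    """
    if distance_mm == 0:
        return wavefront
    if pad_factor < 1:
        raise InvalidArgumentError("pad_factor must be >= 1")
    v = wavefront.values
    h0, w0 = v.shape
    if pad_factor > 1:
        ph, pw = h0 * pad_factor, w0 * pad_factor
        padded = np.zeros((ph, pw), dtype=complex)
        oy, ox = (ph - h0) // 2, (pw - w0) // 2
        padded[oy : oy + h0, ox : ox + w0] = v
    else:
        padded = v
        oy = ox = 0
    tf = _transfer_function(padded.shape, wavefront.pitch_um, distance_mm * 1000.0, wavelength_um)
    out = np.fft.ifft2(np.fft.fft2(padded) * tf)
    out = out[oy : oy + h0, ox : ox + w0]
    return ComplexField(values=out, pitch_um=wavefront.pitch_um)


def quantize_heights(
    h_continuous: np.ndarray,
    step_um: float = 0.2,
    max_um: float = 1.0,
    pitch_um: float = 1.0,
) -> HeightMap:
    """Round heights to the nearest fabrication level; ties round up; clamp to [0, max]."""
    if step_um <= 0:
        raise InvalidArgumentError("step_um must be positive")
    n_steps = max_um / step_um
    if abs(round(n_steps) - n_steps) > 1e-12:
        raise InvalidArgumentError("step_um must divide max_um")
    h = np.asarray(h_continuous, dtype=float)
    # floor(x + 0.5) rounds half-way cases up, as fabrication prefers
    idx = np.floor(h / step_um + 0.5)
    idx = np.clip(idx, 0, round(n_steps))
    levels = tuple(np.round(np.arange(round(n_steps) + 1) * step_um, 12))
    return HeightMap(heights_um=idx * step_um, pitch_um=pitch_um, levels=levels)


def _spherical_wave(shape: tuple[int, int], pitch_um: float, z_um: float, wavelength_um: float) -> np.ndarray:
    """Unit-amplitude spherical wavefront from an on-axis point source at distance z."""
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.indices(shape)
    r2 = ((yy - cy) * pitch_um) ** 2 + ((xx - cx) * pitch_um) ** 2
    path = np.sqrt(z_um**2 + r2)
    return np.exp(2j * np.pi * path / wavelength_um)


def _resample_to_pitch(img: np.ndarray, pitch_in: float, pitch_out: float) -> np.ndarray:
    if pitch_in == pitch_out:
        return img.copy()
    zoom = pitch_in / pitch_out
    out = ndimage.zoom(img, zoom, order=1, mode="constant", cval=0.0, grid_mode=True)
    return np.clip(out, 0, None)


def retrieve_phase(
    target: TargetPSF,
    config: OpticalConfig,
    iterations: int = 100,
    seed: int = 0,
    correlation_threshold: float = 0.7,
    min_feature_um: float = 6.0,
    init: str = "backpropagate",
) -> RetrievalResult:
    """Design a quantized phase mask whose near-field diffraction matches a target PSF.

    Alternating projections: at the mask plane the field is constrained to a
    phase-only modulation of the spherical illumination from an on-axis point
    source at the mid working distance; at the sensor plane (one
    mask-to-sensor throw away) the amplitude is constrained to the square
    root of the target intensity.  By default the phase is initialized by
    back-propagating the target amplitude to the mask plane
    (``init="backpropagate"``), which at these short throws starts the
    alternation close to a consistent solution; ``init="random"`` draws a
    uniform phase from ``seed`` instead.  Before quantization, the
    continuous height map is
    low-pass filtered to respect the minimum fabricable feature width
    (``min_feature_um``, default 6 um; 0 disables the constraint); the final
    heights are quantized to 200 nm levels up to 1 um.

    A Pearson correlation between the quantized mask's propagated intensity
    and the target below ``correlation_threshold`` emits a warning (not an
    error) carrying the achieved value.
    """
    if iterations < 1:
        raise InvalidArgumentError("iterations must be >= 1")
    lam = config.wavelength_um
    z1_um = config.mid_working_distance_mm * 1000.0
    z2_mm = config.mask_to_sensor_mm

    amp_target = np.sqrt(_resample_to_pitch(target.intensity, target.pitch_um, config.mask_pitch_um))
    amp_target /= np.linalg.norm(amp_target)
    shape = amp_target.shape

    # The iteration runs on a 2x padded canvas: the mask aperture and the
    # target window are its central region, and the sensor amplitude is
    # constrained only inside that window (light diffracted past the target
    # grid is left free).  This keeps any mask that truly produces the
    # target an exact fixed point of the alternation.
    ch, cw = 2 * shape[0], 2 * shape[1]
    oy, ox = (ch - shape[0]) // 2, (cw - shape[1]) // 2
    win = (slice(oy, oy + shape[0]), slice(ox, ox + shape[1]))
    aperture = np.zeros((ch, cw), dtype=bool)
    aperture[win] = True

    illum = _spherical_wave((ch, cw), config.mask_pitch_um, z1_um, lam)

    def mask_field(ph: np.ndarray) -> ComplexField:
        return ComplexField(np.where(aperture, illum * np.exp(1j * ph), 0.0), config.mask_pitch_um)

    if init == "backpropagate":
        u0 = np.zeros((ch, cw), dtype=complex)
        u0[win] = amp_target
        back0 = propagate(ComplexField(u0, config.mask_pitch_um), -z2_mm, lam, pad_factor=1).values
        phase = np.angle(back0 * np.conj(illum))
    elif init == "random":
        rng = np.random.default_rng(seed)
        phase = rng.uniform(0.0, 2.0 * np.pi, size=(ch, cw))
    else:
        raise InvalidArgumentError("init must be 'backpropagate' or 'random'")

    errors: list[float] = []
    for _ in range(iterations):
        u_sens = propagate(mask_field(phase), z2_mm, lam, pad_factor=1).values
        amp_win = np.abs(u_sens[win])
        norm = np.linalg.norm(amp_win)
        errors.append(float(np.linalg.norm(amp_win / norm - amp_target)))
        u_sens[win] = amp_target * norm * np.exp(1j * np.angle(u_sens[win]))
        u_back = propagate(ComplexField(u_sens, config.mask_pitch_um), -z2_mm, lam, pad_factor=1).values
        phase = np.angle(u_back * np.conj(illum))

    phase = phase[win]
    if min_feature_um > 0:
        # soft minimum-feature-width constraint: low-pass the complex phasor
        # (wrap-aware) with cutoff ~1/min_feature
        sigma_px = min_feature_um / (2.0 * np.pi * config.mask_pitch_um)
        phasor = np.exp(1j * phase)
        phasor = ndimage.gaussian_filter(phasor.real, sigma_px, mode="nearest") + 1j * ndimage.gaussian_filter(
            phasor.imag, sigma_px, mode="nearest"
        )
        phase = np.angle(phasor)
    phase = np.mod(phase, 2.0 * np.pi)
    full_wave_um = lam / (config.n_material - 1.0)
    h_cont = phase / (2.0 * np.pi) * full_wave_um
    hmap = quantize_heights(h_cont, 0.2, 1.0, pitch_um=config.mask_pitch_um)

    # assess the quantized design
    phi_q = np.zeros((ch, cw))
    phi_q[win] = height_to_phase(hmap, lam, config.n_material)
    u_q = propagate(mask_field(phi_q), z2_mm, lam, pad_factor=1).values
    intensity = np.abs(u_q[win]) ** 2
    corr = float(np.corrcoef(intensity.ravel(), (amp_target**2).ravel())[0, 1])
    converged = corr >= correlation_threshold
    if not converged:
        warnings.warn(
            f"phase retrieval correlation {corr:.3f} below threshold {correlation_threshold}",
            stacklevel=2,
        )
    return RetrievalResult(height_map=hmap, amplitude_errors=errors, correlation=corr, converged=converged)
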