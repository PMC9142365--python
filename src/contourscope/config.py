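"""Shared configuration objects for optics, sensing and solvers.

The optical geometry mirrors a flat lensless fluorescence microscope: a
quantized-relief phase mask sits a few millimetres above a monochrome CMOS
sensor, and the scene lies a few millimetres above the mask.  All modules
(design, simulation, reconstruction) consume the same :class:`OpticalConfig`
so that geometry cannot drift between stages.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml


@dataclass(frozen=True)
class OpticalConfig:
    """Geometry and physics constants of the lensless imager.

    Parameters
    ----------
    wavelength_um : emission wavelength in micrometres (green fluorescence).
    mask_pitch_um : phase-mask pixel size in micrometres.
    sensor_pitch_um : sensor pixel size in micrometres.
    mask_to_sensor_mm : distance from the mask plane to the sensor plane.
    scene_to_mask_mm_range : (near, far) working-distance span in millimetres.
    n_material : refractive index of the mask photoresist.
    aperture_mm : illuminated mask extent; 0 means "full designed mask".
    """

    wavelength_um: float = 0.525
    mask_pitch_um: float = 1.0
    sensor_pitch_um: float = 2.4
    mask_to_sensor_mm: float = 3.5
    scene_to_mask_mm_range: tuple[float, float] = (2.0, 7.0)
    n_material: float = 1.55
    aperture_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.wavelength_um <= 0:
            raise ValueError("wavelength_um must be positive")
        if self.mask_pitch_um <= 0 or self.sensor_pitch_um <= 0:
            raise ValueError("pixel pitches must be positive")
        if self.mask_pitch_um > self.sensor_pitch_um:
            raise ValueError("mask_pitch_um must not exceed sensor_pitch_um")
        if self.mask_to_sensor_mm <= 0:
            raise ValueError("mask_to_sensor_mm must be positive")
        lo, hi = self.scene_to_mask_mm_range
        if not (0 < lo < hi):
            raise ValueError("scene_to_mask_mm_range must be an increasing positive pair")

    @property
    def mid_working_distance_mm(self) -> float:
        lo, hi = self.scene_to_mask_mm_range
        return 0.5 * (lo + hi)


@dataclass(frozen=True)
class NoiseParams:
    """Sensor noise model: Poisson shot noise, Gaussian read noise, quantization.

    ``photon_scale`` converts unit scene intensity into expected photoelectron
    counts; 0 disables shot noise.  ``read_noise_sd`` is in counts.
    """

    photon_scale: float = 0.0
    read_noise_sd: float = 0.0
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.photon_scale < 0 or self.read_noise_sd < 0:
            raise ValueError("noise magnitudes must be non-negative")
        if self.bit_depth < 1:
            raise ValueError("bit_depth must be >= 1")

    @property
    def noiseless(self) -> bool:
        return self.photon_scale == 0 and self.read_noise_sd == 0


@dataclass(frozen=True)
class ReconParams2D:
    """Tikhonov/Wiener 2D reconstruction parameters.

    ``gamma`` is the constant added to the PSF power spectrum in the
    closed-form Wiener denominator; it equals the L2 penalty weight of the
    regularized least-squares objective written with a plain (not halved)
    quadratic term.
    """

    gamma: float = 1e-4
    pad_px: int = 0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.pad_px < 0:
            raise ValueError("pad_px must be non-negative")


@dataclass(frozen=True)
class ReconParams3D:
    """ADMM parameters for the multi-depth TV + L1 + non-negativity problem."""

    gamma1: float = 1e-4
    gamma2: float = 1e-4
    rho: float = 1.0
    max_iters: int = 200
    tol_primal: float = 1e-4
    tol_dual: float = 1e-4
    nonneg: bool = True

    def __post_init__(self) -> None:
        if self.gamma1 < 0 or self.gamma2 < 0:
            raise ValueError("gamma1/gamma2 must be non-negative")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.tol_primal <= 0 or self.tol_dual <= 0:
            raise ValueError("tolerances must be positive")


_OPTICAL_KEYS = {
    "wavelength_um",
    "mask_pitch_um",
    "sensor_pitch_um",
    "mask_to_sensor_mm",
    "scene_to_mask_mm_range",
    "n_material",
    "aperture_mm",
}


def load_optical_config(path: str | Path) -> OpticalConfig:
    """Load an :class:`OpticalConfig` from a YAML file, rejecting unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of config keys")
    unknown = set(raw) - _OPTICAL_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "scene_to_mask_mm_range" in raw:
        raw["scene_to_mask_mm_range"] = tuple(raw["scene_to_mask_mm_range"])
    return OpticalConfig(**raw)


def save_optical_config(config: OpticalConfig, path: str | Path) -> None:
    data = asdict(config)
    data["scene_to_mask_mm_range"] = list(data["scene_to_mask_mm_range"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
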