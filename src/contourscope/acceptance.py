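"""Headline desk-scale studies, shared by the validation suite and scripts.

Each function runs one complete study from scratch — design, simulation,
reconstruction, metrology — and returns the measured quantity together with
the problem size it was measured at.
"""

from __future__ import annotations

import warnings

from .workflows import (
    DesignedSystem,
    bead_axial_study,
    design_contour_system,
    usaf_resolution_study,
)

__all__ = ["lateral_resolution_um", "axial_fwhm_um", "shared_system"]


def shared_system(seed: int) -> DesignedSystem:
    """Design the contour-mask system used by both headline studies."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return design_contour_system(seed=seed)


def lateral_resolution_um(seed: int, system: DesignedSystem | None = None) -> dict:
    """Finest resolved USAF bar width (um) through the full simulated chain."""
    system = system or shared_system(seed)
    res = usaf_resolution_study(seed=seed, system=system)
    return {"value": float(res["resolution_um"]), "n": len(res["elements"]), "gamma": res["gamma"]}


def axial_fwhm_um(seed: int, system: DesignedSystem | None = None) -> dict:
    """Axial FWHM (um) of one reconstructed 10 um bead over a 2.8-3.3 mm stack."""
    system = system or shared_system(seed)
    res = bead_axial_study(seed=seed, system=system)
    return {"value": float(res["fwhm_um"]), "n": len(res["depths_mm"])}
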