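"""Shared fixtures: a designed contour-mask system and a cheap speckle system.

The designed system (contour PSF -> phase retrieval -> mask) is expensive to
build, so it is session-scoped and shared by the end-to-end tests.  The
speckle system replaces the designed mask with a random quantized mask; its
PSFs decorrelate with depth just as the engineered ones do, which makes it a
fast stand-in for depth-discrimination tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from contourscope.config import OpticalConfig
from contourscope.mask_design import quantize_heights
from contourscope.optics_sim import psf_stack_from_mask


@pytest.fixture(scope="session")
def optical_config() -> OpticalConfig:
    return OpticalConfig(mask_pitch_um=2.0)


@pytest.fixture(scope="session")
def designed_system():
    from contourscope.workflows import design_contour_system

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return design_contour_system(seed=1)


@pytest.fixture(scope="session")
def speckle_mask(optical_config):
    rng = np.random.default_rng(11)
    # 256 px at 2 um = 512 um aperture: axial PSF decorrelation ~ lambda (z/a)^2
    # ~ 18 um at z = 3 mm, well below the 20 um calibration spacing
    return quantize_heights(rng.uniform(0.0, 1.0, (256, 256)), pitch_um=optical_config.mask_pitch_um)


@pytest.fixture(scope="session")
def speckle_stack_factory(optical_config, speckle_mask):
    """Factory building (and caching) PSF stacks of the speckle mask."""
    cache: dict[tuple, object] = {}

    def build(depths_mm):
        key = tuple(np.round(depths_mm, 9))
        if key not in cache:
            cache[key] = psf_stack_from_mask(speckle_mask, optical_config, list(depths_mm))
        return cache[key]

    return build
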