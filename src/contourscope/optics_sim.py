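"""Forward optical model and synthetic scene generators.

This module turns a designed phase mask into a depth-indexed PSF stack (the
simulated analogue of the one-time bead calibration, acquired every 20 um
over the 2-7 mm working range) and renders sensor measurements of synthetic
scenes through the per-depth convolutional forward model

    b = sum_d p_d * i_d  (+ shot noise, read noise, quantization)

It also provides the study phantoms: USAF-style three-bar resolution
targets, 10 um fluorescent bead volumes at the nominal density of
3.6e4 beads/ml in a 3 x 3 x 0.5 mm volume, an optional ballistic+diffuse
scattering layer (mu_s ~ 1/mm), widefield calcium movies with a low-rank
background plus sparse transients, and microvessel scenes with known
centerlines.  Every generator is deterministic given its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft
from scipy import ndimage

from .calcium_analysis import CalciumMovie
from .config import NoiseParams, OpticalConfig
from .errors import InvalidArgumentError
from .mask_design import ComplexField, HeightMap, _spherical_wave, height_to_phase, propagate
from .vessel_density import Vessel, VesselSet

__all__ = [
    "PSFStack",
    "SensorImage",
    "SceneVolume",
    "rebin_area",
    "psf_stack_from_mask",
    "render_sensor",
    "make_usaf_target",
    "usaf_bar_width_um",
    "make_bead_phantom",
    "apply_scattering",
    "make_calcium_movie",
    "CalciumGroundTruth",
    "make_vessel_scene",
]


@dataclass(frozen=True)
class PSFStack:
    """Depth-indexed unit-sum PSFs at sensor pitch (the system calibration)."""

    depths_mm: np.ndarray
    psfs: np.ndarray  # (D, H, W)
    pitch_um: float

    def __post_init__(self) -> None:
        d = np.asarray(self.depths_mm, dtype=float)
        p = np.asarray(self.psfs, dtype=float)
        if p.ndim != 3 or len(d) != p.shape[0]:
            raise InvalidArgumentError("psfs must be (D, H, W) matching depths")
        if np.any(np.diff(d) <= 0):
            raise InvalidArgumentError("depths must be strictly increasing")
        if np.any(p < 0):
            raise InvalidArgumentError("PSFs must be non-negative")
        sums = p.sum(axis=(1, 2))
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise InvalidArgumentError("each PSF must sum to 1 within 1e-9")
        object.__setattr__(self, "depths_mm", d)
        object.__setattr__(self, "psfs", p)

    def __len__(self) -> int:
        return len(self.depths_mm)


@dataclass(frozen=True)
class SensorImage:
    """A single sensor measurement (float counts on a 16-bit scale)."""

    counts: np.ndarray
    exposure_ms: float = 15.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2:
            raise InvalidArgumentError("counts must be 2D")
        if np.any(c < 0):
            raise InvalidArgumentError("counts must be non-negative")
        object.__setattr__(self, "counts", c)


@dataclass(frozen=True)
class SceneVolume:
    """Ground-truth scene: one non-negative slice per depth, at sensor pitch."""

    slices: np.ndarray  # (D, H, W)
    depths_mm: np.ndarray
    pitch_um: float

    def __post_init__(self) -> None:
        s = np.asarray(self.slices, dtype=float)
        d = np.asarray(self.depths_mm, dtype=float)
        if s.ndim != 3 or s.shape[0] != len(d):
            raise InvalidArgumentError("slices must be (D, H, W) matching depths")
        if np.any(s < 0):
            raise InvalidArgumentError("scene must be non-negative")
        object.__setattr__(self, "slices", s)
        object.__setattr__(self, "depths_mm", d)


# ---------------------------------------------------------------------------
# PSF stack generation
# ---------------------------------------------------------------------------

def _rebin_matrix(n_in: int, pitch_in: float, pitch_out: float) -> np.ndarray:
    """Exact area-average rebinning matrix from a fine to a coarse pixel grid."""
    extent = n_in * pitch_in
    n_out = int(np.floor(extent / pitch_out + 1e-9))
    mat = np.zeros((n_out, n_in))
    edges_in = np.arange(n_in + 1) * pitch_in
    for o in range(n_out):
        lo, hi = o * pitch_out, (o + 1) * pitch_out
        i0 = int(np.searchsorted(edges_in, lo, side="right")) - 1
        i1 = int(np.searchsorted(edges_in, hi, side="left"))
        for i in range(max(i0, 0), min(i1, n_in)):
            overlap = min(hi, edges_in[i + 1]) - max(lo, edges_in[i])
            if overlap > 0:
                mat[o, i] = overlap / pitch_out
    return mat


def rebin_area(intensity: np.ndarray, pitch_in: float, pitch_out: float) -> np.ndarray:
    """Box-integrate a fine-pitch intensity map onto a coarser pixel grid.

    Each coarse pixel is the area-weighted average of the fine pixels it
    covers (exact for any pitch ratio); a trailing partial pixel is dropped.
    """
    if pitch_out < pitch_in:
        raise InvalidArgumentError("rebin_area only coarsens the grid")
    if pitch_out == pitch_in:
        return intensity.copy()
    ry = _rebin_matrix(intensity.shape[0], pitch_in, pitch_out)
    rx = _rebin_matrix(intensity.shape[1], pitch_in, pitch_out)
    return ry @ intensity @ rx.T


def psf_stack_from_mask(
    mask: HeightMap,
    config: OpticalConfig,
    depths_mm: list[float] | np.ndarray,
) -> PSFStack:
    """Simulate the depth calibration: one sensor-plane PSF per source depth.

    For each depth, a unit-amplitude spherical wave from an on-axis point
    source is propagated to the mask plane (expressed analytically at the
    mask), modulated by the mask's phase profile, propagated the
    mask-to-sensor distance by the angular-spectrum method, squared, box
    integrated to sensor pitch and normalized to unit sum.
    """
    depths = np.asarray(depths_mm, dtype=float)
    lo, hi = config.scene_to_mask_mm_range
    if np.any(depths < lo - 1e-9) or np.any(depths > hi + 1e-9):
        raise InvalidArgumentError("depths outside the configured working range")
    phi = height_to_phase(mask, config.wavelength_um, config.n_material)
    transmission = np.exp(1j * phi)
    if config.aperture_mm > 0:
        h, w = phi.shape
        yy, xx = np.indices((h, w))
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        r_um = np.hypot(yy - cy, xx - cx) * mask.pitch_um
        transmission = transmission * (r_um <= config.aperture_mm * 500.0)

    psfs = []
    for z in depths:
        illum = _spherical_wave(phi.shape, mask.pitch_um, z * 1000.0, config.wavelength_um)
        u = ComplexField(illum * transmission, mask.pitch_um)
        u_s = propagate(u, config.mask_to_sensor_mm, config.wavelength_um).values
        intensity = np.abs(u_s) ** 2
        coarse = rebin_area(intensity, mask.pitch_um, config.sensor_pitch_um)
        coarse = np.clip(coarse, 0, None)
        psfs.append(coarse / coarse.sum())
    return PSFStack(depths_mm=depths, psfs=np.stack(psfs), pitch_um=config.sensor_pitch_um)


# ---------------------------------------------------------------------------
# Measurement rendering
# ---------------------------------------------------------------------------

def _match_depths(vol_depths: np.ndarray, stack_depths: np.ndarray) -> np.ndarray:
    idx = np.empty(len(vol_depths), dtype=int)
    for k, z in enumerate(vol_depths):
        j = int(np.argmin(np.abs(stack_depths - z)))
        if abs(stack_depths[j] - z) > 1e-6:
            raise InvalidArgumentError(f"scene depth {z} mm absent from the PSF stack")
        idx[k] = j
    return idx


def render_sensor(volume: SceneVolume, stack: PSFStack, noise: NoiseParams | None = None) -> SensorImage:
    """Render a measurement b = sum_d p_d * i_d, then apply the sensor model.

    The virtual sensor covers the scene extent plus a margin of half the PSF
    extent on each side, so all light diffracted by the mask lands on the
    sensor (as on the physical 6 MP sensor, whose active area exceeds the
    scene FOV).  Convolution is circular on that canvas; the scene window's
    offset and shape are recorded in ``meta["scene_offset"]`` /
    ``meta["scene_shape"]``.  Noiseless rendering (photon_scale = 0,
    read_noise_sd = 0) is exactly linear in the scene; otherwise Poisson
    shot noise at ``photon_scale`` counts per unit intensity, Gaussian read
    noise, clipping to the bit range and rounding are applied,
    deterministically in ``noise.seed``.
    """
    noise = noise or NoiseParams()
    idx = _match_depths(volume.depths_mm, stack.depths_mm)
    hs, ws = volume.slices.shape[1:]
    hp, wp = stack.psfs.shape[1:]
    pad_y, pad_x = hp // 2, wp // 2
    ch = sfft.next_fast_len(hs + 2 * pad_y)
    cw = sfft.next_fast_len(ws + 2 * pad_x)
    pad_y, pad_x = (ch - hs) // 2, (cw - ws) // 2

    clean_f = np.zeros((ch, cw), dtype=complex)
    for k, j in enumerate(idx):
        sl = volume.slices[k]
        if not np.any(sl):
            continue
        scene_pad = np.zeros((ch, cw))
        scene_pad[pad_y : pad_y + hs, pad_x : pad_x + ws] = sl
        kern = np.zeros((ch, cw))
        oy, ox = ch // 2 - hp // 2, cw // 2 - wp // 2
        kern[oy : oy + hp, ox : ox + wp] = stack.psfs[j]
        kern = np.fft.ifftshift(kern)
        clean_f += sfft.fft2(kern) * sfft.fft2(scene_pad)
    clean = np.real(sfft.ifft2(clean_f))
    clean = np.clip(clean, 0, None) if not noise.noiseless else clean

    meta = {
        "seed": noise.seed,
        "photon_scale": noise.photon_scale,
        "read_noise_sd": noise.read_noise_sd,
        "scene_offset": (pad_y, pad_x),
        "scene_shape": (hs, ws),
    }
    if noise.noiseless:
        return SensorImage(counts=np.clip(clean, 0, None), meta=meta)
    rng = np.random.default_rng(noise.seed)
    out = clean.astype(float)
    if noise.photon_scale > 0:
        out = rng.poisson(out * noise.photon_scale).astype(float)
    if noise.read_noise_sd > 0:
        out = out + rng.normal(0.0, noise.read_noise_sd, size=out.shape)
    out = np.clip(out, 0, 2**noise.bit_depth - 1)
    return SensorImage(counts=np.round(out), meta=meta)


# ---------------------------------------------------------------------------
# USAF-style resolution target
# ---------------------------------------------------------------------------

def usaf_bar_width_um(group: int, element: int) -> float:
    """Bar width of a 1951 USAF element: 500 / 2**(group + (element-1)/6) um."""
    return 500.0 / 2.0 ** (group + (element - 1) / 6.0)


def make_usaf_target(
    group_range: tuple[int, int],
    config: OpticalConfig,
    depth_mm: float = 4.0,
    margin_um: float = 30.0,
) -> tuple[SceneVolume, list[dict]]:
    """Synthesize a bright-bars-on-dark three-bar resolution target.

    Each element renders a horizontal and a vertical three-bar pattern
    (bar length 5x width, 1:1 duty cycle).  Elements whose bar width falls
    below one scene pixel are skipped with a warning.  Metadata lists, for
    every rendered element, the bar width and probe coordinates (bar and gap
    centres in micrometres) for both orientations, which the resolution
    metrology consumes.
    """
    pitch = config.sensor_pitch_um
    elements = []
    for g in range(group_range[0], group_range[1] + 1):
        for e in range(1, 7):
            w = usaf_bar_width_um(g, e)
            if w < pitch:
                warnings.warn(f"group {g} element {e} ({w:.2f} um) below one pixel; skipped", stacklevel=2)
                continue
            elements.append((g, e, w))
    # lay elements out vertically, finest last
    elements.sort(key=lambda t: -t[2])

    rows: list[dict] = []
    y_cursor = margin_um
    x0 = margin_um
    max_x = 0.0
    for g, e, w in elements:
        ext = 5.0 * w  # both triplet footprint and bar length
        h_origin = (y_cursor, x0)  # horizontal bars: stripes along x, stacked in y
        v_origin = (y_cursor, x0 + ext + 2.0 * w)  # vertical bars
        bar_centers_h = [y_cursor + (2 * k + 0.5) * w for k in range(3)]
        gap_centers_h = [y_cursor + (2 * k + 1.5) * w for k in range(2)]
        bar_centers_v = [v_origin[1] + (2 * k + 0.5) * w for k in range(3)]
        gap_centers_v = [v_origin[1] + (2 * k + 1.5) * w for k in range(2)]
        rows.append(
            {
                "group": g,
                "element": e,
                "width_um": w,
                "h": {
                    "axis": 0,
                    "bar_centers_um": bar_centers_h,
                    "gap_centers_um": gap_centers_h,
                    "along_center_um": x0 + ext / 2.0,
                    "along_halflen_um": 0.4 * ext,
                    "origin_um": h_origin,
                },
                "v": {
                    "axis": 1,
                    "bar_centers_um": bar_centers_v,
                    "gap_centers_um": gap_centers_v,
                    "along_center_um": y_cursor + ext / 2.0,
                    "along_halflen_um": 0.4 * ext,
                    "origin_um": v_origin,
                },
            }
        )
        max_x = max(max_x, v_origin[1] + ext)
        y_cursor += ext + margin_um

    height_px = int(np.ceil((y_cursor + margin_um) / pitch))
    width_px = int(np.ceil((max_x + margin_um) / pitch))
    img = np.zeros((height_px, width_px))
    yc = (np.arange(height_px) + 0.5) * pitch
    xc = (np.arange(width_px) + 0.5) * pitch
    for row in rows:
        w = row["width_um"]
        ext = 5.0 * w
        hy, hx = row["h"]["origin_um"]
        for k in range(3):
            ys = (yc >= hy + 2 * k * w) & (yc < hy + (2 * k + 1) * w)
            xs = (xc >= hx) & (xc < hx + ext)
            img[np.ix_(ys, xs)] = 1.0
        vy, vx = row["v"]["origin_um"]
        for k in range(3):
            ys = (yc >= vy) & (yc < vy + ext)
            xs = (xc >= vx + 2 * k * w) & (xc < vx + (2 * k + 1) * w)
            img[np.ix_(ys, xs)] = 1.0

    vol = SceneVolume(slices=img[None], depths_mm=np.array([depth_mm]), pitch_um=pitch)
    return vol, rows


# ---------------------------------------------------------------------------
# Bead phantom and scattering
# ---------------------------------------------------------------------------

def make_bead_phantom(
    config: OpticalConfig,
    density_per_ml: float = 3.6e4,
    bead_diameter_um: float = 10.0,
    extent_mm: tuple[float, float, float] = (3.0, 3.0, 0.5),
    z_start_mm: float = 2.8,
    slice_spacing_um: float = 20.0,
    seed: int = 0,
    lateral_pitch_um: float | None = None,
) -> tuple[SceneVolume, dict]:
    """Uniformly random fluorescent beads in a clear volume.

    The bead count is Poisson(density x volume); at the nominal density of
    3.6e4 beads/ml in 3 x 3 x 0.5 mm (= 4.5e-3 ml) the expectation is 162.
    Beads are uniform spheres rasterized onto the depth slices at
    ``lateral_pitch_um`` (default: sensor pitch; a coarse pitch keeps
    count-statistics studies cheap).
    """
    if min(extent_mm) <= 0:
        raise InvalidArgumentError("extent must be positive")
    rng = np.random.default_rng(seed)
    ex, ey, ez = extent_mm
    volume_ml = ex * ey * ez / 1000.0  # mm^3 -> ml
    n = int(rng.poisson(density_per_ml * volume_ml))
    centers = rng.uniform(size=(n, 3)) * np.array([ey * 1000.0, ex * 1000.0, ez * 1000.0])

    pitch = lateral_pitch_um if lateral_pitch_um is not None else config.sensor_pitch_um
    h = int(np.ceil(ey * 1000.0 / pitch))
    w = int(np.ceil(ex * 1000.0 / pitch))
    depths_um = np.arange(0.0, ez * 1000.0 + slice_spacing_um / 2, slice_spacing_um)
    slices = np.zeros((len(depths_um), h, w))
    radius = bead_diameter_um / 2.0
    yc = (np.arange(h) + 0.5) * pitch
    xc = (np.arange(w) + 0.5) * pitch
    for cy, cx, cz in centers:
        for k, z in enumerate(depths_um):
            dz = z - cz
            if abs(dz) > radius:
                continue
            r_slice = np.sqrt(radius**2 - dz**2)
            ys = np.abs(yc - cy) <= r_slice
            xs = np.abs(xc - cx) <= r_slice
            if not ys.any() or not xs.any():
                continue
            yy = yc[ys][:, None] - cy
            xx = xc[xs][None, :] - cx
            disc = yy**2 + xx**2 <= r_slice**2
            block = slices[k][np.ix_(ys, xs)]
            block[disc] = 1.0
            slices[k][np.ix_(ys, xs)] = block
    depths_mm = z_start_mm + depths_um / 1000.0
    meta = {"n_beads": n, "centers_um": centers, "z_start_mm": z_start_mm, "seed": seed}
    return SceneVolume(slices=slices, depths_mm=depths_mm, pitch_um=pitch), meta


def apply_scattering(
    stack_or_image: PSFStack | np.ndarray,
    mu_s_per_mm: float = 1.0,
    depth_mm: float = 0.0,
    diffusion_um_per_mm: float = 100.0,
) -> PSFStack | np.ndarray:
    """Two-component scattering model: ballistic attenuation plus diffuse blur.

    out = exp(-mu_s z) * in + (1 - exp(-mu_s z)) * (in (*) G_z) with a
    Gaussian diffusion kernel whose sigma grows linearly with the traversed
    depth (``diffusion_um_per_mm`` um of sigma per mm).  Wrap-around
    filtering keeps the total energy exactly conserved.  This is a
    deliberately simple stand-in for tissue scattering: only the ballistic
    law exp(-mu_s z) is taken from physics.
    """
    if mu_s_per_mm < 0 or depth_mm < 0:
        raise InvalidArgumentError("mu_s and depth must be non-negative")

    def _blur(img: np.ndarray, z_mm: float, pitch_um: float) -> np.ndarray:
        if mu_s_per_mm == 0 or z_mm == 0:
            return img.copy()
        ballistic = np.exp(-mu_s_per_mm * z_mm)
        sigma_px = diffusion_um_per_mm * z_mm / pitch_um
        diffuse = ndimage.gaussian_filter(img, sigma_px, mode="wrap")
        return ballistic * img + (1.0 - ballistic) * diffuse

    if isinstance(stack_or_image, PSFStack):
        z0 = stack_or_image.depths_mm[0]
        blurred = np.stack(
            [
                _blur(p, float(z - z0) + depth_mm, stack_or_image.pitch_um)
                for p, z in zip(stack_or_image.psfs, stack_or_image.depths_mm)
            ]
        )
        sums = blurred.sum(axis=(1, 2), keepdims=True)
        return PSFStack(depths_mm=stack_or_image.depths_mm, psfs=blurred / sums, pitch_um=stack_or_image.pitch_um)
    img = np.asarray(stack_or_image, dtype=float)
    return _blur(img, depth_mm, 1.0)


# ---------------------------------------------------------------------------
# Calcium movie generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalciumGroundTruth:
    """Planted structure behind a synthetic calcium movie."""

    cell_masks: np.ndarray  # (n_cells, H, W) boolean
    cell_traces: np.ndarray  # (n_cells, T)
    event_times_s: list[list[float]]
    cluster_labels: np.ndarray  # per-cell integer cluster id
    label_map: np.ndarray  # (H, W) integer map, -1 background


def make_calcium_movie(
    n_frames: int = 2400,
    frame_rate_hz: float = 20.0,
    shape: tuple[int, int] = (64, 64),
    n_cells: int = 6,
    n_clusters: int = 2,
    cell_sigma_px: float = 2.0,
    amplitude: float = 1.0,
    baseline: float = 1.0,
    background_rank: int = 3,
    background_amplitude: float = 0.1,
    transient_tau_s: float = 0.5,
    stimulus_times_s: list[float] | None = None,
    jitter_s: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[CalciumMovie, CalciumGroundTruth]:
    """Synthesize a widefield calcium movie: low-rank background + sparse transients.

    The background (including the constant baseline) is an exact sum of
    ``background_rank`` spatial-temporal outer products, so with no cells and
    no noise the (pixels x time) matrix has rank <= background_rank.  Cells
    are Gaussian blobs grouped into ``n_clusters`` clusters; cells within a
    cluster share event times.  When ``stimulus_times_s`` is given, cluster 0
    fires within ``jitter_s`` after each stimulus; other clusters (and the
    no-stimulus case) fire at Poisson-random times.  Transients rise
    instantly and decay exponentially with ``transient_tau_s``.
    """
    if background_rank < 1:
        raise InvalidArgumentError("background_rank must be >= 1")
    rng = np.random.default_rng(seed)
    h, w = shape
    t = np.arange(n_frames) / frame_rate_hz
    duration = n_frames / frame_rate_hz

    # background: component 0 is the constant baseline; remaining components
    # are smooth random spatial maps times smooth random temporal modulations
    spatial = [np.full((h, w), baseline)]
    temporal = [np.ones(n_frames)]
    for _ in range(background_rank - 1):
        sp = ndimage.gaussian_filter(rng.standard_normal((h, w)), min(h, w) / 8.0, mode="wrap")
        tp = ndimage.gaussian_filter1d(rng.standard_normal(n_frames), max(n_frames / 20.0, 1.0), mode="wrap")
        sp_norm = np.max(np.abs(sp)) or 1.0
        tp_norm = np.max(np.abs(tp)) or 1.0
        spatial.append(background_amplitude * baseline * sp / sp_norm)
        temporal.append(tp / tp_norm)
    movie = np.zeros((n_frames, h, w))
    for sp, tp in zip(spatial, temporal):
        movie += tp[:, None, None] * sp[None]

    # cells
    masks = np.zeros((n_cells, h, w), dtype=bool)
    traces = np.zeros((n_cells, n_frames))
    labels = np.arange(n_cells) % max(n_clusters, 1)
    event_times: list[list[float]] = []
    cluster_events: dict[int, list[float]] = {}
    for c in range(max(n_clusters, 1)):
        if stimulus_times_s and c == 0:
            ev = [s + rng.uniform(0.0, jitter_s) for s in stimulus_times_s]
        else:
            n_ev = max(int(rng.poisson(duration / 10.0)), 1)
            ev = sorted(rng.uniform(0.0, duration * 0.9, size=n_ev).tolist())
        cluster_events[c] = ev
    yy, xx = np.indices((h, w))
    centers = np.stack(
        [rng.uniform(0.15 * h, 0.85 * h, n_cells), rng.uniform(0.15 * w, 0.85 * w, n_cells)], axis=1
    )
    label_map = np.full((h, w), -1, dtype=int)
    for i in range(n_cells):
        cy, cx = centers[i]
        blob = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * cell_sigma_px**2)))
        masks[i] = blob > 0.3
        ev = cluster_events[int(labels[i])]
        event_times.append(list(ev))
        tr = np.zeros(n_frames)
        for te in ev:
            active = t >= te
            tr[active] += amplitude * np.exp(-(t[active] - te) / transient_tau_s)
        traces[i] = tr
        movie += tr[:, None, None] * (blob * masks[i])[None]
        label_map[masks[i]] = labels[i]

    if noise_sd > 0:
        movie = movie + rng.normal(0.0, noise_sd, size=movie.shape)
    movie = np.clip(movie, 0, None)

    cm = CalciumMovie(frames=movie, frame_rate_hz=frame_rate_hz, stimulus_times_s=list(stimulus_times_s or []))
    gt = CalciumGroundTruth(
        cell_masks=masks,
        cell_traces=traces,
        event_times_s=event_times,
        cluster_labels=labels,
        label_map=label_map,
    )
    return cm, gt


# ---------------------------------------------------------------------------
# Vessel scene generator
# ---------------------------------------------------------------------------

def make_vessel_scene(
    extent_mm: tuple[float, float] = (1.0, 1.0),
    n_vessels: int = 10,
    width_range_um: tuple[float, float] = (8.0, 30.0),
    pixel_pitch_um: float = 2.4,
    seed: int = 0,
    n_points: int = 40,
    contrast: float = 0.7,
) -> tuple[np.ndarray, VesselSet]:
    """Random smooth dark-on-bright vessels with exact centreline ground truth.

    Each vessel is a smooth random walk across the field, rasterized as a
    dark stroke of its diameter on a bright background.  The returned
    :class:`~contourscope.vessel_density.VesselSet` carries the exact
    polylines (in micrometres) and diameters for grid-crossing counting.
    """
    if width_range_um[0] <= 0:
        raise InvalidArgumentError("vessel widths must be positive")
    rng = np.random.default_rng(seed)
    ex_um = extent_mm[0] * 1000.0
    ey_um = extent_mm[1] * 1000.0
    h = int(round(ey_um / pixel_pitch_um))
    w = int(round(ex_um / pixel_pitch_um))
    img = np.ones((h, w))
    vessels: list[Vessel] = []
    for _ in range(n_vessels):
        diameter = rng.uniform(*width_range_um)
        start = np.array([rng.uniform(0, ey_um), rng.uniform(0, ex_um)])
        heading = rng.uniform(0, 2 * np.pi)
        step = max(ex_um, ey_um) / n_points
        pts = [start]
        for _ in range(n_points - 1):
            heading += rng.normal(0.0, 0.3)
            nxt = pts[-1] + step * np.array([np.sin(heading), np.cos(heading)])
            # reflect off the field boundary so polylines stay smooth inside
            if not (0.0 <= nxt[0] <= ey_um):
                heading = -heading
                nxt = pts[-1] + step * np.array([np.sin(heading), np.cos(heading)])
            if not (0.0 <= nxt[1] <= ex_um):
                heading = np.pi - heading
                nxt = pts[-1] + step * np.array([np.sin(heading), np.cos(heading)])
            nxt = np.clip(nxt, [0.0, 0.0], [ey_um, ex_um])
            pts.append(nxt)
        poly = np.array(pts)  # (N, 2) as (y_um, x_um)
        vessels.append(Vessel(polyline_um=poly, diameter_um=float(diameter)))

    if n_vessels:
        yc = (np.arange(h) + 0.5) * pixel_pitch_um
        xc = (np.arange(w) + 0.5) * pixel_pitch_um
        for v in vessels:
            half = v.diameter_um / 2.0
            for (y0, x0), (y1, x1) in zip(v.polyline_um[:-1], v.polyline_um[1:]):
                ylo = max(int((min(y0, y1) - half) / pixel_pitch_um) - 1, 0)
                yhi = min(int((max(y0, y1) + half) / pixel_pitch_um) + 2, h)
                xlo = max(int((min(x0, x1) - half) / pixel_pitch_um) - 1, 0)
                xhi = min(int((max(x0, x1) + half) / pixel_pitch_um) + 2, w)
                if ylo >= yhi or xlo >= xhi:
                    continue
                yy = yc[ylo:yhi][:, None]
                xx = xc[xlo:xhi][None, :]
                dy, dx = y1 - y0, x1 - x0
                seg2 = dy * dy + dx * dx
                if seg2 == 0:
                    dist = np.hypot(yy - y0, xx - x0)
                else:
                    tpar = np.clip(((yy - y0) * dy + (xx - x0) * dx) / seg2, 0.0, 1.0)
                    dist = np.hypot(yy - (y0 + tpar * dy), xx - (x0 + tpar * dx))
                block = img[ylo:yhi, xlo:xhi]
                block[dist <= half] = 1.0 - contrast
                img[ylo:yhi, xlo:xhi] = block
    return img, VesselSet(vessels=vessels)
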