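"""Multi-depth 3D reconstruction by ADMM with TV, L1 and non-negativity.

A single 2D capture constrains a whole volume because the PSF varies with
depth.  The estimate solves

    min_{i >= 0} ||b - sum_d p_d * i_d||_F^2
                 + gamma1 sum_d ||Psi(i_d)||_1 + gamma2 ||i||_1

where Psi is the 2D spatial gradient (anisotropic TV).  The problem is split
(scaled-form ADMM, one penalty rho) into a quadratic data subproblem —
solved in closed form per spatial frequency, where the depth coupling is a
rank-one matrix inverted by the Sherman-Morrison identity — plus
soft-thresholding for the TV and L1 splits and projection for
non-negativity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft
from scipy.interpolate import CubicSpline

from .config import ReconParams3D
from .errors import InvalidArgumentError
from .optics_sim import PSFStack, SceneVolume, SensorImage
from .recon2d import _registered_kernel, fwhm

__all__ = [
    "ADMMState",
    "gradient2d",
    "gradient2d_adjoint",
    "soft_threshold",
    "admm_reconstruct3d",
    "objective3d",
    "axial_profile_fwhm",
]


@dataclass
class ADMMState:
    """Solver diagnostics: residual and objective histories, convergence flag."""

    primal_residuals: list[float] = field(default_factory=list)
    dual_residuals: list[float] = field(default_factory=list)
    objectives: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False


def gradient2d(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward differences with circular boundary: (gx along columns, gy along rows)."""
    gx = np.roll(img, -1, axis=1) - img
    gy = np.roll(img, -1, axis=0) - img
    return gx, gy


def gradient2d_adjoint(gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    """Exact transpose of :func:`gradient2d` (negative circular divergence)."""
    return (np.roll(gx, 1, axis=1) - gx) + (np.roll(gy, 1, axis=0) - gy)


def soft_threshold(x: np.ndarray | float, tau: float) -> np.ndarray | float:
    """Elementwise shrinkage sign(x) * max(|x| - tau, 0)."""
    if tau < 0:
        raise InvalidArgumentError("tau must be non-negative")
    return np.sign(x) * np.maximum(np.abs(x) - tau, 0.0)


def objective3d(
    b: np.ndarray,
    stack: PSFStack,
    volume: np.ndarray,
    gamma1: float,
    gamma2: float,
) -> float:
    """Evaluate the TV+L1 regularized data-fit objective at a candidate volume.

    Uses the same circulant forward model as the solver (volume and b on a
    common canvas).
    """
    d, h, w = volume.shape
    forward = np.zeros((h, w))
    for k in range(d):
        kern = _registered_kernel(stack.psfs[k], (h, w), register_com=False)
        forward += np.real(sfft.ifft2(sfft.fft2(kern) * sfft.fft2(volume[k])))
    data = np.sum((b - forward) ** 2)
    tv = sum(np.abs(gradient2d(volume[k])[0]).sum() + np.abs(gradient2d(volume[k])[1]).sum() for k in range(d))
    return float(data + gamma1 * tv + gamma2 * np.abs(volume).sum())


def admm_reconstruct3d(
    b: SensorImage | np.ndarray,
    stack: PSFStack,
    params: ReconParams3D | None = None,
    pad_px: int | None = None,
    objective_every: int = 0,
) -> tuple[SceneVolume, ADMMState]:
    """Reconstruct a multi-depth volume from one capture with ADMM.

    The quadratic step solves, per spatial frequency f, the D x D system
    (2 conj(p_f) p_f^T + c_f I) x = r_f with c_f = rho (|G_f|^2 + n_splits),
    which the Sherman-Morrison identity reduces to O(D) work.  TV and L1 splits
    use soft-thresholding with thresholds gamma1/rho and gamma2/rho; the
    non-negativity split is a projection.  Iterations stop when the relative
    primal and dual residual norms drop below the tolerances; hitting
    ``max_iters`` first returns the current iterate with ``converged=False``
    (not an exception).
    """
    params = params or ReconParams3D()
    meas = b.counts if isinstance(b, SensorImage) else np.asarray(b, dtype=float)
    n_d = len(stack)
    if n_d == 0:
        raise InvalidArgumentError("empty PSF stack")
    hs, ws = meas.shape
    if pad_px is None:
        pad_px = max(stack.psfs.shape[1:]) // 2
    ch = sfft.next_fast_len(hs + 2 * pad_px) if pad_px else hs
    cw = sfft.next_fast_len(ws + 2 * pad_px) if pad_px else ws
    oy, ox = (ch - hs) // 2, (cw - ws) // 2
    b_pad = np.zeros((ch, cw))
    b_pad[oy : oy + hs, ox : ox + ws] = meas

    # Fourier kernels per depth
    p_hat = np.stack(
        [sfft.fft2(_registered_kernel(stack.psfs[k], (ch, cw), register_com=False)) for k in range(n_d)]
    )  # (D, ch, cw)
    b_hat = sfft.fft2(b_pad)
    atb = np.real(sfft.ifft2(np.conj(p_hat) * b_hat[None]))  # (D, ch, cw) = A^T b per depth

    # gradient filter power spectrum |Gx|^2 + |Gy|^2 (shared by all depths)
    gx_kernel = np.zeros((ch, cw))
    gx_kernel[0, 0] = -1.0
    gx_kernel[0, -1] = 1.0  # circular forward difference as a convolution kernel
    gy_kernel = np.zeros((ch, cw))
    gy_kernel[0, 0] = -1.0
    gy_kernel[-1, 0] = 1.0
    grad_power = np.abs(sfft.fft2(gx_kernel)) ** 2 + np.abs(sfft.fft2(gy_kernel)) ** 2

    rho = params.rho
    # identity splits coupled to i: the L1 split, plus the non-negativity split
    n_splits = 1.0 + (1.0 if params.nonneg else 0.0)
    c_f = rho * (grad_power + n_splits)  # (ch, cw), > 0 everywhere
    pp = np.sum(np.abs(p_hat) ** 2, axis=0)  # ||p_f||^2

    vol = np.zeros((n_d, ch, cw))
    u_x = np.zeros_like(vol)
    u_y = np.zeros_like(vol)
    du_x = np.zeros_like(vol)
    du_y = np.zeros_like(vol)
    w_l1 = np.zeros_like(vol)
    dw = np.zeros_like(vol)
    v_nn = np.zeros_like(vol)
    dv = np.zeros_like(vol)

    state = ADMMState()
    for it in range(1, params.max_iters + 1):
        # --- quadratic step ---
        rhs = 2.0 * atb.copy()
        for k in range(n_d):
            rhs[k] += rho * gradient2d_adjoint(u_x[k] - du_x[k], u_y[k] - du_y[k])
        rhs += rho * (w_l1 - dw)
        if params.nonneg:
            rhs += rho * (v_nn - dv)
        r_hat = np.stack([sfft.fft2(rhs[k]) for k in range(n_d)])
        # normal matrix per frequency: 2 conj(p) p^T + c I (Sherman-Morrison)
        pt_r = np.sum(p_hat * r_hat, axis=0)  # p^T r, no conjugation
        coef = 2.0 * pt_r / (c_f * (c_f + 2.0 * pp))
        x_hat = r_hat / c_f[None] - np.conj(p_hat) * coef[None]
        vol = np.stack([np.real(sfft.ifft2(x_hat[k])) for k in range(n_d)])

        # --- splits ---
        gx = np.stack([gradient2d(vol[k])[0] for k in range(n_d)])
        gy = np.stack([gradient2d(vol[k])[1] for k in range(n_d)])
        u_x_old, u_y_old, w_old, v_old = u_x, u_y, w_l1, v_nn
        u_x = soft_threshold(gx + du_x, params.gamma1 / rho)
        u_y = soft_threshold(gy + du_y, params.gamma1 / rho)
        w_l1 = soft_threshold(vol + dw, params.gamma2 / rho)
        if params.nonneg:
            v_nn = np.maximum(vol + dv, 0.0)

        # --- duals ---
        du_x = du_x + gx - u_x
        du_y = du_y + gy - u_y
        dw = dw + vol - w_l1
        if params.nonneg:
            dv = dv + vol - v_nn

        # --- residuals (relative, Boyd-style) ---
        prim2 = np.sum((gx - u_x) ** 2) + np.sum((gy - u_y) ** 2) + np.sum((vol - w_l1) ** 2)
        ref2 = np.sum(gx**2) + np.sum(gy**2) + 2.0 * np.sum(vol**2)
        split2 = np.sum(u_x**2) + np.sum(u_y**2) + np.sum(w_l1**2)
        if params.nonneg:
            prim2 += np.sum((vol - v_nn) ** 2)
            split2 += np.sum(v_nn**2)
        prim = np.sqrt(prim2) / max(np.sqrt(max(ref2, split2)), 1e-12)

        dual_field = np.stack(
            [gradient2d_adjoint(u_x[k] - u_x_old[k], u_y[k] - u_y_old[k]) for k in range(n_d)]
        ) + (w_l1 - w_old)
        if params.nonneg:
            dual_field = dual_field + (v_nn - v_old)
        dual_ref2 = np.sum(du_x**2) + np.sum(du_y**2) + np.sum(dw**2)
        if params.nonneg:
            dual_ref2 += np.sum(dv**2)
        dual = np.linalg.norm(dual_field) / max(np.sqrt(dual_ref2), 1e-12)

        state.primal_residuals.append(float(prim))
        state.dual_residuals.append(float(dual))
        state.iterations = it
        if objective_every and it % objective_every == 0:
            state.objectives.append(objective3d(b_pad, stack, vol, params.gamma1, params.gamma2))
        if prim <= params.tol_primal and dual <= params.tol_dual:
            state.converged = True
            break

    result = v_nn if params.nonneg else vol
    cropped = result[:, oy : oy + hs, ox : ox + ws]
    if params.nonneg:
        cropped = np.clip(cropped, 0, None)
    else:
        cropped = cropped - min(cropped.min(), 0.0) if np.any(cropped < 0) else cropped
    volume = SceneVolume(slices=cropped, depths_mm=stack.depths_mm, pitch_um=stack.pitch_um)
    return volume, state


def axial_profile_fwhm(
    volume: SceneVolume,
    bead_xy: tuple[int, int],
    interp_factor: int = 8,
) -> float:
    """Axial FWHM (um) of a reconstructed bead.

    Extracts the axial intensity profile at the bead's lateral position
    (3 x 3 lateral max-pool per plane), upsamples it axially by cubic
    interpolation and measures the full width at half maximum.  A bead
    confined to a single plane (no neighbours above half maximum) reports
    the plane spacing with a warning.
    """
    r, c = bead_xy
    d, h, w = volume.slices.shape
    if d < 3:
        raise InvalidArgumentError("need at least 3 depth planes")
    if not (0 <= r < h and 0 <= c < w):
        raise InvalidArgumentError("bead position outside the volume")
    r0, r1 = max(r - 1, 0), min(r + 2, h)
    c0, c1 = max(c - 1, 0), min(c + 2, w)
    profile = volume.slices[:, r0:r1, c0:c1].max(axis=(1, 2))
    depths_um = np.asarray(volume.depths_mm, dtype=float) * 1000.0
    spacing = float(np.mean(np.diff(depths_um)))

    above = profile > profile.max() / 2.0
    if above.sum() <= 1:
        warnings.warn("bead confined to a single plane; reporting the plane spacing", stacklevel=2)
        return spacing

    if interp_factor < 1:
        raise InvalidArgumentError("interp_factor must be >= 1")
    spline = CubicSpline(depths_um, profile)
    fine = np.linspace(depths_um[0], depths_um[-1], (d - 1) * interp_factor + 1)
    fine_profile = np.clip(spline(fine), 0, None)
    return fwhm(fine_profile, sample_pitch=float(fine[1] - fine[0]))
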