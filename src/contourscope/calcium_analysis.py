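"""Calcium-signal extraction: dF/F, robust PCA, activity clustering, timing maps.

Widefield calcium recordings mix a smooth, slowly varying global background
with sharp, spatially sparse transients from active cells.  The pipeline
separates the two with robust principal component analysis (RPCA, solved by
inexact augmented Lagrange multipliers): the low-rank component captures the
global intensity, the sparse component the calcium activity.  Active pixels
are then grouped by K-means on their normalized time courses, and per-window
Pearson correlations quantify agreement between imaging modalities around
stimulus events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .errors import InvalidArgumentError

__all__ = [
    "CalciumMovie",
    "RPCADecomposition",
    "ClusterResult",
    "delta_f_over_f",
    "rpca",
    "cluster_activity",
    "peak_time_map",
    "windowed_correlation",
    "WindowedCorrelation",
    "cluster_area_mm2",
]


@dataclass(frozen=True)
class CalciumMovie:
    """A time-lapse fluorescence recording (frames indexed time, row, column)."""

    frames: np.ndarray  # (T, H, W)
    frame_rate_hz: float = 20.0
    stimulus_times_s: list[float] = field(default_factory=list)
    velocity_trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        if f.ndim != 3 or f.shape[0] < 2:
            raise InvalidArgumentError("frames must be (T>=2, H, W)")
        if self.frame_rate_hz <= 0:
            raise InvalidArgumentError("frame_rate_hz must be positive")
        dur = f.shape[0] / self.frame_rate_hz
        if any(not (0 <= s <= dur) for s in self.stimulus_times_s):
            raise InvalidArgumentError("stimulus times must lie within the recording")
        object.__setattr__(self, "frames", f)

    @property
    def duration_s(self) -> float:
        return self.frames.shape[0] / self.frame_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.frames.shape[0]) / self.frame_rate_hz


@dataclass
class RPCADecomposition:
    low_rank: np.ndarray
    sparse: np.ndarray
    lam: float
    iterations: int
    converged: bool


@dataclass
class ClusterResult:
    """Activity clusters: per-pixel labels (-1 = background) and mean traces."""

    labels: np.ndarray  # (H, W) int
    k: int
    mean_traces: np.ndarray  # (k, T)


def delta_f_over_f(
    movie: CalciumMovie | np.ndarray,
    baseline_percentile: float = 10.0,
    pre_stimulus_window_s: tuple[float, float] | None = None,
    eps: float = 1e-6,
    frame_rate_hz: float | None = None,
) -> np.ndarray:
    """Fractional fluorescence change (F - F0) / max(F0, eps), per pixel.

    F0 is the per-pixel temporal percentile (default 10th) or, when
    ``pre_stimulus_window_s`` is given, the mean over that time window.
    All-zero pixels yield zero traces thanks to the eps guard.
    """
    if eps <= 0:
        raise InvalidArgumentError("eps must be positive")
    if isinstance(movie, CalciumMovie):
        frames = movie.frames
        frame_rate_hz = movie.frame_rate_hz
    else:
        frames = np.asarray(movie, dtype=float)
    if pre_stimulus_window_s is not None:
        if frame_rate_hz is None:
            raise InvalidArgumentError("frame_rate_hz required for a window baseline")
        t0, t1 = pre_stimulus_window_s
        i0, i1 = int(round(t0 * frame_rate_hz)), int(round(t1 * frame_rate_hz))
        if i1 <= i0:
            raise InvalidArgumentError("empty baseline window")
        f0 = frames[i0:i1].mean(axis=0)
    else:
        f0 = np.percentile(frames, baseline_percentile, axis=0)
    return (frames - f0) / np.maximum(f0, eps)


def rpca(
    m_matrix: np.ndarray,
    lam: float | None = None,
    tol: float = 1e-7,
    max_iters: int = 1000,
) -> RPCADecomposition:
    """Robust PCA by inexact augmented Lagrange multipliers.

    Solves min ||L||_* + lam ||S||_1 s.t. M = L + S by alternating
    singular-value thresholding on L and soft-thresholding on S with a dual
    update and geometrically growing penalty, stopping when
    ||M - L - S||_F / ||M||_F <= tol.  The default lam is
    1/sqrt(max(n_rows, n_cols)).
    """
    m_arr = np.asarray(m_matrix, dtype=float)
    if m_arr.ndim != 2 or not np.all(np.isfinite(m_arr)):
        raise InvalidArgumentError("M must be a finite 2D matrix")
    nr, nc = m_arr.shape
    if lam is None:
        lam = 1.0 / np.sqrt(max(nr, nc))
    if lam <= 0:
        raise InvalidArgumentError("lam must be positive")
    norm_f = np.linalg.norm(m_arr)
    if norm_f == 0:
        return RPCADecomposition(np.zeros_like(m_arr), np.zeros_like(m_arr), lam, 0, True)

    norm_two = np.linalg.norm(m_arr, 2)
    norm_inf = np.abs(m_arr).max() / lam
    y_dual = m_arr / max(norm_two, norm_inf)
    mu = 1.25 / norm_two
    mu_bar = mu * 1e7
    rho = 1.5
    s_sparse = np.zeros_like(m_arr)
    low = np.zeros_like(m_arr)
    converged = False
    it = 0
    for it in range(1, max_iters + 1):
        u, sv, vt = np.linalg.svd(m_arr - s_sparse + y_dual / mu, full_matrices=False)
        sv_shrunk = np.maximum(sv - 1.0 / mu, 0.0)
        r = int(np.count_nonzero(sv_shrunk))
        low = (u[:, :r] * sv_shrunk[:r]) @ vt[:r]
        resid = m_arr - low + y_dual / mu
        s_sparse = np.sign(resid) * np.maximum(np.abs(resid) - lam / mu, 0.0)
        z = m_arr - low - s_sparse
        y_dual = y_dual + mu * z
        mu = min(mu * rho, mu_bar)
        if np.linalg.norm(z) / norm_f <= tol:
            converged = True
            break
    return RPCADecomposition(low_rank=low, sparse=s_sparse, lam=lam, iterations=it, converged=converged)


def _farthest_point_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Deterministic greedy farthest-point seeding (first point drawn from rng)."""
    n = x.shape[0]
    centers = [int(rng.integers(n))]
    d2 = np.sum((x - x[centers[0]]) ** 2, axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(d2))
        centers.append(nxt)
        d2 = np.minimum(d2, np.sum((x - x[nxt]) ** 2, axis=1))
    return x[centers]


def cluster_activity(
    s_movie: np.ndarray,
    k: int,
    min_pixels: int = 1,
    seed: int = 0,
    energy_mad_factor: float = 3.0,
) -> ClusterResult:
    """K-means clustering of active pixels by their normalized time courses.

    A pixel is active when the RMS of its sparse-component trace exceeds
    ``energy_mad_factor`` times the median absolute deviation of the whole
    sparse component.  Active traces are L2-normalized and clustered with
    K-means initialized by deterministic farthest-point seeding from the
    seed.  Clusters smaller than ``min_pixels`` are dropped to background
    (-1) and the remaining labels are renumbered compactly.
    """
    if k < 1:
        raise InvalidArgumentError("K must be >= 1")
    s3 = np.asarray(s_movie, dtype=float)
    if s3.ndim != 3:
        raise InvalidArgumentError("s_movie must be (T, H, W)")
    n_t, h, w = s3.shape
    flat = s3.reshape(n_t, -1).T  # (pixels, T)
    energy = np.sqrt(np.mean(flat**2, axis=1))
    med = np.median(s3)
    mad = np.median(np.abs(s3 - med))
    active = energy > energy_mad_factor * mad
    labels = np.full(h * w, -1, dtype=int)
    if not np.any(active) or mad == 0 and not np.any(energy > 0):
        warnings.warn("no active pixels above the noise floor", stacklevel=2)
        return ClusterResult(labels=labels.reshape(h, w), k=0, mean_traces=np.zeros((0, n_t)))

    traces = flat[active]
    norms = np.linalg.norm(traces, axis=1, keepdims=True)
    normed = traces / np.maximum(norms, 1e-12)
    k_eff = min(k, normed.shape[0])
    rng = np.random.default_rng(seed)
    init = _farthest_point_init(normed, k_eff, rng)
    km = KMeans(n_clusters=k_eff, init=init, n_init=1, random_state=0)
    raw = km.fit_predict(normed)

    # drop small clusters, renumber survivors compactly
    final = np.full(raw.shape, -1, dtype=int)
    next_id = 0
    mean_traces = []
    for c in range(k_eff):
        m = raw == c
        if m.sum() >= min_pixels:
            final[m] = next_id
            mean_traces.append(traces[m].mean(axis=0))
            next_id += 1
    labels[np.flatnonzero(active)] = final
    return ClusterResult(
        labels=labels.reshape(h, w),
        k=next_id,
        mean_traces=np.array(mean_traces) if mean_traces else np.zeros((0, n_t)),
    )


def peak_time_map(
    dff_movie: np.ndarray,
    frame_rate_hz: float,
    window_start_s: float,
    window_len_s: float = 0.4,
) -> np.ndarray:
    """Per-pixel time (ms, relative to window start) of the peak dF/F response.

    Ties resolve to the earliest frame.  The window must lie within the
    recording.
    """
    frames = np.asarray(dff_movie, dtype=float)
    i0 = int(round(window_start_s * frame_rate_hz))
    i1 = int(round((window_start_s + window_len_s) * frame_rate_hz))
    if i0 < 0 or i1 > frames.shape[0] or i1 <= i0:
        raise InvalidArgumentError("window outside the recording")
    window = frames[i0:i1]
    peak_frame = np.argmax(window, axis=0)
    return peak_frame * 1000.0 / frame_rate_hz


@dataclass
class WindowedCorrelation:
    r_values: list[float]
    median: float
    iqr: float
    excluded_windows: int = 0


def windowed_correlation(
    trace_a: np.ndarray,
    trace_b: np.ndarray,
    windows_s: list[tuple[float, float]],
    frame_rate_hz: float,
) -> WindowedCorrelation:
    """Pearson correlation of two traces over time-aligned windows.

    ``windows_s`` is a list of (start_s, length_s) pairs; each window needs
    at least 3 samples and must lie in both records.  Zero-variance windows
    are excluded with a warning.  The summary reports the median and the
    interquartile range (Q3 - Q1, linear-interpolation quartiles) across
    windows.
    """
    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    n = min(len(a), len(b))
    rs: list[float] = []
    excluded = 0
    for start, length in windows_s:
        i0 = int(round(start * frame_rate_hz))
        i1 = int(round((start + length) * frame_rate_hz))
        if i0 < 0 or i1 > n:
            raise InvalidArgumentError(f"window ({start}, {length}) outside the records")
        if i1 - i0 < 3:
            raise InvalidArgumentError("windows need at least 3 samples")
        wa, wb = a[i0:i1], b[i0:i1]
        if wa.std() == 0 or wb.std() == 0:
            excluded += 1
            continue
        rs.append(float(np.corrcoef(wa, wb)[0, 1]))
    if excluded:
        warnings.warn(f"{excluded} zero-variance window(s) excluded", stacklevel=2)
    if not rs:
        return WindowedCorrelation([], float("nan"), float("nan"), excluded)
    q1, med, q3 = np.percentile(rs, [25, 50, 75])
    return WindowedCorrelation(rs, float(med), float(q3 - q1), excluded)


def cluster_area_mm2(result: ClusterResult, pixel_pitch_um: float) -> np.ndarray:
    """Per-cluster area in mm^2: pixel count times (pitch/1000)^2."""
    if pixel_pitch_um <= 0:
        raise InvalidArgumentError("pixel pitch must be positive")
    counts = np.array([(result.labels == c).sum() for c in range(result.k)])
    return counts * (pixel_pitch_um / 1000.0) ** 2
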