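"""Occupancy and firing-rate maps, spatial statistics and stability.

The arena is discretized into square pixels (2.5 x 2.5 cm).  The occupancy
of pixel x is the kernel-smoothed time spent near it,

    z(x) = sum_t w(|x - x_t|) * dt,

with w a 2D Gaussian of sigma = 1 pixel, truncated at 4 sigma and normalized
per sample over the in-grid pixels of its support so that sum_x z(x) equals
the included tracking time exactly.  The firing rate of pixel x divides the
identically smoothed spike count by occupancy,

    r(x) = sum_i w(|x - x_i|) / z(x),

where x_i is the animal's position at spike i.  Pixels occupied for less
than 20 ms are masked.

From the maps, with p_n the occupancy probability of pixel n, lambda_n its
rate and lambda = sum_n p_n lambda_n the overall mean rate (valid pixels
only, p renormalized):

    I_spike  = sum_n p_n (lambda_n / lambda) log2(lambda_n / lambda)
    sparsity = (sum_n p_n lambda_n)^2 / sum_n p_n lambda_n^2

I_spike is the Skaggs information in bits per spike (0 for spatially uniform
firing); sparsity lies in (0, 1], 1 for uniform firing and 1/N for firing
confined to one of N equally occupied pixels, so *higher* sparsity means
*more diffuse* firing.  Stability is the Pearson correlation between
linearized (1D, circular) rate maps of the two temporal halves of a session.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.stats import pearsonr

from .config import AnalysisConfig
from .core import SessionRecord, TrackingTrace
from .geometry import (EllipseModel, MazeGeometry, count_laps, fit_ellipse,
                       linearize)


class SpatialError(ValueError):
    pass


@dataclass
class OccupancyMap:
    """Smoothed seconds-per-pixel over the arena grid (row = y, col = x)."""

    z: np.ndarray
    pixel_size_cm: float
    dt: float
    sigma_px: float
    valid: np.ndarray  # z >= occupancy threshold

    @property
    def total_time_s(self) -> float:
        return float(self.z.sum())


@dataclass
class RateMap:
    """Smoothed firing rate per pixel (Hz), defined on the occupancy mask."""

    rate: np.ndarray
    valid: np.ndarray
    n_spikes: int


@dataclass
class LinearizedMap:
    """Circular 1D rate map over arc-length bins along the track."""

    bin_edges_cm: np.ndarray
    rate: np.ndarray
    occupancy_s: np.ndarray
    valid: np.ndarray
    normalized: bool = False


@dataclass
class SpatialMetrics:
    information_bits_per_spike: float
    sparsity_index: float
    peak_rate_hz: float
    stability_r: float
    n_spikes_included: int
    n_laps: int
    mean_rate_movement_hz: float
    mean_rate_overall_hz: float


# ---------------------------------------------------------------------------
# position and speed


def midpoint_position(tracking: TrackingTrace):
    """Per-sample midpoint of the two head LEDs.

    Samples with either LED missing are dropped.  Returns (times, xy).
    """
    ok = ~(np.isnan(tracking.led1_xy).any(axis=1)
           | np.isnan(tracking.led2_xy).any(axis=1))
    if not ok.any():
        raise SpatialError("no tracking sample has both LEDs")
    xy = 0.5 * (tracking.led1_xy[ok] + tracking.led2_xy[ok])
    return tracking.t[ok], xy


def compute_speed(positions: np.ndarray, dt: float,
                  smooth_window_s: float = 0.25) -> np.ndarray:
    """Instantaneous speed (cm/s) by central differences, boxcar-smoothed.

    Edge samples use one-sided differences; the output has the same length
    as ``positions``.  A smoothing window of one sample (or less) leaves the
    raw finite differences untouched.
    """
    xy = np.asarray(positions, dtype=float)
    if xy.ndim != 2 or xy.shape[0] < 2:
        raise SpatialError("speed requires at least two position samples")
    disp = np.empty(xy.shape[0])
    disp[1:-1] = np.linalg.norm(xy[2:] - xy[:-2], axis=1) / (2 * dt)
    disp[0] = np.linalg.norm(xy[1] - xy[0]) / dt
    disp[-1] = np.linalg.norm(xy[-1] - xy[-2]) / dt
    window = max(1, int(round(smooth_window_s / dt)))
    if window > 1:
        disp = uniform_filter1d(disp, size=window, mode="nearest")
    return disp


# ---------------------------------------------------------------------------
# 2D maps


def _grid_shape(arena: MazeGeometry, pixel_cm: float):
    w, h = arena.bounding_box_cm
    nx = int(np.ceil(w / pixel_cm - 1e-9))
    ny = int(np.ceil(h / pixel_cm - 1e-9))
    return ny, nx


def _deposit(points: np.ndarray, shape, pixel_cm: float, sigma_px: float,
             truncate: float, weights: np.ndarray) -> np.ndarray:
    """Scatter per-point mass onto the grid through the Gaussian kernel.

    Each point's kernel is evaluated at pixel centers within the truncation
    radius and renormalized over the in-grid part of its support, so the
    deposited mass equals ``weights`` exactly (mass conservation at arena
    boundaries included).
    """
    ny, nx = shape
    # continuous pixel coordinates of the points (pixel center k at k)
    gx = points[:, 0] / pixel_cm - 0.5
    gy = points[:, 1] / pixel_cm - 0.5
    R = int(np.ceil(truncate * sigma_px))
    offs = np.arange(-R, R + 1)
    ox, oy = np.meshgrid(offs, offs)
    ox, oy = ox.ravel(), oy.ravel()

    ix = np.round(gx).astype(int)[:, None] + ox[None, :]
    iy = np.round(gy).astype(int)[:, None] + oy[None, :]
    dx = ix - gx[:, None]
    dy = iy - gy[:, None]
    d2 = dx * dx + dy * dy
    w = np.exp(-d2 / (2.0 * sigma_px ** 2))
    w[d2 > (truncate * sigma_px) ** 2] = 0.0
    w[(ix < 0) | (ix >= nx) | (iy < 0) | (iy >= ny)] = 0.0
    norm = w.sum(axis=1)
    if np.any(norm <= 0):
        raise SpatialError("a sample lies entirely outside the arena grid")
    w *= (weights / norm)[:, None]

    grid = np.zeros(shape)
    flat = np.clip(iy, 0, ny - 1) * nx + np.clip(ix, 0, nx - 1)
    np.add.at(grid.ravel(), flat.ravel(), w.ravel())
    return grid


def compute_occupancy(positions: np.ndarray, dt: float, arena: MazeGeometry,
                      config: Optional[AnalysisConfig] = None) -> OccupancyMap:
    """Kernel-smoothed occupancy map from speed-filtered positions."""
    config = config or AnalysisConfig()
    xy = np.asarray(positions, dtype=float)
    if xy.ndim != 2 or xy.shape[0] == 0:
        raise SpatialError("occupancy requires at least one position sample")
    shape = _grid_shape(arena, config.pixel_size_cm)
    z = _deposit(xy, shape, config.pixel_size_cm, config.kernel_sigma_px,
                 config.kernel_truncate_sigma, np.full(xy.shape[0], dt))
    return OccupancyMap(z=z, pixel_size_cm=config.pixel_size_cm, dt=dt,
                        sigma_px=config.kernel_sigma_px,
                        valid=z >= config.occupancy_mask_s)


def compute_ratemap(spike_positions: np.ndarray, occupancy: OccupancyMap,
                    config: Optional[AnalysisConfig] = None) -> RateMap:
    """Firing-rate map: identically smoothed spike counts over occupancy."""
    config = config or AnalysisConfig()
    if occupancy.valid is None:
        raise SpatialError("occupancy map lacks a validity mask")
    xy = np.asarray(spike_positions, dtype=float).reshape(-1, 2)
    if xy.shape[0]:
        num = _deposit(xy, occupancy.z.shape, occupancy.pixel_size_cm,
                       occupancy.sigma_px, config.kernel_truncate_sigma,
                       np.ones(xy.shape[0]))
    else:
        num = np.zeros_like(occupancy.z)
    rate = np.full_like(occupancy.z, np.nan)
    rate[occupancy.valid] = num[occupancy.valid] / occupancy.z[occupancy.valid]
    return RateMap(rate=rate, valid=occupancy.valid, n_spikes=int(xy.shape[0]))


# ---------------------------------------------------------------------------
# pixel statistics


def _p_and_lambda(ratemap: RateMap, occupancy: OccupancyMap):
    v = occupancy.valid & ~np.isnan(ratemap.rate)
    if not v.any():
        raise SpatialError("no valid pixels")
    z = occupancy.z[v]
    p = z / z.sum()
    lam = ratemap.rate[v]
    return p, lam


def skaggs_information(p: np.ndarray, lam: np.ndarray) -> float:
    """Skaggs spatial information in bits/spike from occupancy probabilities
    p_n and pixel rates lambda_n (0*log 0 taken as 0)."""
    p = np.asarray(p, dtype=float)
    lam = np.asarray(lam, dtype=float)
    lbar = float(np.dot(p, lam))
    if lbar <= 0:
        raise SpatialError("spatial information undefined without spikes")
    pos = lam > 0
    ratio = lam[pos] / lbar
    return float(np.sum(p[pos] * ratio * np.log2(ratio)))


def sparsity_index(p: np.ndarray, lam: np.ndarray) -> float:
    """Sparsity (sum p lambda)^2 / sum p lambda^2 in (0, 1]; 1 = uniform
    firing, 1/N = firing confined to one of N equally occupied pixels."""
    p = np.asarray(p, dtype=float)
    lam = np.asarray(lam, dtype=float)
    lbar = float(np.dot(p, lam))
    if lbar <= 0:
        raise SpatialError("sparsity undefined without spikes")
    return float(lbar ** 2 / np.dot(p, lam ** 2))


def spatial_information(ratemap: RateMap, occupancy: OccupancyMap) -> float:
    p, lam = _p_and_lambda(ratemap, occupancy)
    return skaggs_information(p, lam)


def sparsity(ratemap: RateMap, occupancy: OccupancyMap) -> float:
    p, lam = _p_and_lambda(ratemap, occupancy)
    return sparsity_index(p, lam)


def peak_firing_rate(ratemap: RateMap) -> float:
    """Maximum rate over valid pixels of the 2D map."""
    v = ratemap.valid & ~np.isnan(ratemap.rate)
    if not v.any():
        raise SpatialError("peak rate undefined: no valid pixels")
    return float(np.nanmax(ratemap.rate[v]))


# ---------------------------------------------------------------------------
# linearized (1D) maps


def _circular_gaussian_smooth(values: np.ndarray, sigma_bins: float) -> np.ndarray:
    n = values.size
    if sigma_bins <= 0 or n < 2:
        return values.copy()
    half = min(n // 2, int(np.ceil(4 * sigma_bins)))
    offs = np.arange(-half, half + 1)
    kern = np.exp(-offs ** 2 / (2 * sigma_bins ** 2))
    kern /= kern.sum()
    out = np.zeros(n)
    for o, k in zip(offs, kern):
        out += k * np.roll(values, o)
    return out


def linearized_ratemap(spike_s: np.ndarray, occupancy_s: np.ndarray, dt: float,
                       perimeter: float, config: Optional[AnalysisConfig] = None,
                       normalize: bool = False) -> LinearizedMap:
    """Circular 1D rate map over arc-length bins.

    Occupancy and spike histograms are accumulated on the bins, both smoothed
    with a circular Gaussian (sigma = 1 bin), and divided; bins whose
    smoothed occupancy falls below the occupancy mask are invalid.
    """
    config = config or AnalysisConfig()
    n_bins = max(2, int(round(perimeter / config.linear_bin_cm)))
    edges = np.linspace(0.0, perimeter, n_bins + 1)
    occ, _ = np.histogram(np.mod(occupancy_s, perimeter), bins=edges)
    spk, _ = np.histogram(np.mod(spike_s, perimeter), bins=edges)
    occ_t = _circular_gaussian_smooth(occ.astype(float) * dt, config.linear_sigma_bins)
    spk_s = _circular_gaussian_smooth(spk.astype(float), config.linear_sigma_bins)
    valid = occ_t >= config.occupancy_mask_s
    rate = np.full(n_bins, np.nan)
    rate[valid] = spk_s[valid] / occ_t[valid]
    if normalize:
        peak = np.nanmax(rate) if valid.any() else np.nan
        if peak and peak > 0:
            rate = rate / peak
    return LinearizedMap(bin_edges_cm=edges, rate=rate, occupancy_s=occ_t,
                         valid=valid, normalized=normalize)


def split_half_stability(track_t: np.ndarray, track_s: np.ndarray,
                         moving: np.ndarray, spike_t: np.ndarray,
                         spike_s: np.ndarray, dt: float, perimeter: float,
                         config: Optional[AnalysisConfig] = None) -> float:
    """Pearson correlation between linearized rate maps of the two temporal
    halves of a session (bins valid in both halves only)."""
    config = config or AnalysisConfig()
    mid = 0.5 * (track_t[0] + track_t[-1])
    maps = []
    for half in (track_t <= mid, track_t > mid):
        sel = half & moving
        sp = spike_s[(spike_t <= mid) if half[0] else (spike_t > mid)]
        # spikes already movement-filtered by the caller
        maps.append(linearized_ratemap(sp, track_s[sel], dt, perimeter, config))
    joint = maps[0].valid & maps[1].valid
    if joint.sum() < 2:
        raise SpatialError("fewer than two jointly valid bins for stability")
    a = maps[0].rate[joint]
    b = maps[1].rate[joint]
    if np.std(a) == 0 or np.std(b) == 0:
        raise SpatialError("constant half-map; stability undefined")
    return float(pearsonr(a, b)[0])


# ---------------------------------------------------------------------------
# session-level summary


def spatial_summary(session: SessionRecord,
                    config: Optional[AnalysisConfig] = None,
                    ellipse: Optional[EllipseModel] = None) -> SpatialMetrics:
    """Full spatial chain for one session.

    Midpoint positions -> speed filter -> best-fit ellipse -> linearization
    -> lap count -> 2D occupancy/rate maps -> information, sparsity, peak
    rate -> split-half stability on linearized maps.
    """
    config = config or AnalysisConfig()
    if session.tracking is None:
        raise SpatialError("session has no tracking")
    if session.arena is None:
        raise SpatialError("session has no arena geometry")
    t, xy = midpoint_position(session.tracking)
    dt = session.tracking.dt
    speed = compute_speed(xy, dt, config.speed_smooth_s)
    moving = speed > config.speed_threshold_cm_s

    if ellipse is None:
        ellipse = fit_ellipse(xy)
    s = linearize(xy, ellipse)
    laps = count_laps(s, ellipse.perimeter)

    # spikes during the tracked span, mapped to the nearest tracking frame
    spikes = session.spikes.times
    in_track = (spikes >= t[0]) & (spikes <= t[-1])
    sp_t = spikes[in_track]
    idx = np.clip(np.searchsorted(t, sp_t), 0, t.size - 1)
    left = np.clip(idx - 1, 0, t.size - 1)
    idx = np.where(np.abs(t[left] - sp_t) < np.abs(t[idx] - sp_t), left, idx)
    sp_moving = moving[idx]
    sp_xy = xy[idx[sp_moving]]
    sp_s = s[idx[sp_moving]]
    sp_t_mov = sp_t[sp_moving]

    occ = compute_occupancy(xy[moving], dt, session.arena, config)
    rmap = compute_ratemap(sp_xy, occ, config)

    movement_time = moving.sum() * dt
    mean_mov = sp_xy.shape[0] / movement_time if movement_time > 0 else float("nan")
    mean_all = session.spikes.n_spikes / session.spikes.duration_s

    if sp_xy.shape[0] > 0:
        info = spatial_information(rmap, occ)
        spars = sparsity(rmap, occ)
        peak = peak_firing_rate(rmap)
    else:
        info = spars = peak = float("nan")
    try:
        stab = split_half_stability(t, s, moving, sp_t_mov, sp_s, dt,
                                    ellipse.perimeter, config)
    except SpatialError:
        stab = float("nan")

    return SpatialMetrics(
        information_bits_per_spike=info, sparsity_index=spars,
        peak_rate_hz=peak, stability_r=stab,
        n_spikes_included=int(sp_xy.shape[0]), n_laps=laps,
        mean_rate_movement_hz=float(mean_mov),
        mean_rate_overall_hz=float(mean_all),
    )
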