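"""Shared acoustic primitives: pulses, ray sampling, travel-time tables.

Straight-ray kinematics are used throughout: travel time is the line
integral of slowness along the (possibly piecewise-linear) path.  This is
the same path model the tomographic inversions assume, which keeps the
synthetic data and the reconstruction operators mutually consistent and
makes analytic time-of-flight oracles exact.

Internal unit conventions: coordinates and pixel sizes in mm, slowness in
s/m, path lengths in m, times in s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.interpolate import CubicSpline
from scipy.signal import butter

from .containers import Grid
from .geometry import AcquisitionConfig, RingGeometry

__all__ = [
    "Pulse",
    "transmit_pulse",
    "band_impulse",
    "line_integral_tof",
    "build_path_matrix",
    "fan_waypoints",
    "dual_sos_travel_times",
    "element_pixel_distances",
    "add_pulses",
]

MM = 1e-3  # mm -> m


@dataclass(frozen=True)
class Pulse:
    """Band-limited wavelet with analytic spline evaluation.

    ``__call__`` evaluates the wavelet at arbitrary times (s, relative to
    the pulse centre) and ``derivative`` its exact time derivative — the
    pair is consistent to machine precision, which the waveform-inversion
    gradient relies on.
    """

    spline: CubicSpline
    dspline: CubicSpline
    t_min: float
    t_max: float

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        inside = (t >= self.t_min) & (t <= self.t_max)
        out[inside] = self.spline(t[inside])
        return out

    def derivative(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        inside = (t >= self.t_min) & (t <= self.t_max)
        out[inside] = self.dspline(t[inside])
        return out

    def sampled(self, dt: float) -> tuple[np.ndarray, int]:
        """Wavelet sampled on a ``dt`` grid; returns (samples, centre index)."""
        n_left = int(np.ceil(-self.t_min / dt))
        n_right = int(np.ceil(self.t_max / dt))
        t = (np.arange(n_left + n_right + 1) - n_left) * dt
        return self(t), n_left

    @property
    def envelope_fwhm(self) -> float:
        """Full width at half maximum of the wavelet envelope (s)."""
        from scipy.signal import hilbert

        t = np.linspace(self.t_min, self.t_max, 4001)
        env = np.abs(hilbert(self(t)))
        above = env >= 0.5 * env.max()
        return float(t[above][-1] - t[above][0])


def _make_pulse(fine_t: np.ndarray, raw: np.ndarray, config: AcquisitionConfig) -> Pulse:
    """Bandpass a raw waveform with the transducer band and wrap as Pulse."""
    fs_fine = 1.0 / (fine_t[1] - fine_t[0])
    fc = config.center_frequency
    bw = config.fractional_bandwidth
    sos_band = butter(
        2, [fc * (1 - bw), fc * (1 + bw)], btype="bandpass", fs=fs_fine, output="sos"
    )
    from scipy.signal import sosfiltfilt

    filtered = sosfiltfilt(sos_band, raw)
    filtered = filtered / np.abs(filtered).max()
    # Truncate negligible tails to keep evaluation windows small.
    keep = np.abs(filtered) > 1e-4
    i0, i1 = np.nonzero(keep)[0][[0, -1]]
    spline = CubicSpline(fine_t[i0 : i1 + 1], filtered[i0 : i1 + 1], bc_type="clamped")
    return Pulse(
        spline=spline,
        dspline=spline.derivative(),
        t_min=float(fine_t[i0]),
        t_max=float(fine_t[i1]),
    )


def transmit_pulse(
    config: AcquisitionConfig, duration: float = 0.16e-6, oversample: int = 16
) -> Pulse:
    """Single-cycle bipolar square transmit pulse filtered to the array band.

    The electrical excitation is a 0.16 us bipolar square wave; the emitted
    wavelet is that excitation seen through the transducer's fractional
    bandwidth (zero-phase model, centred at t = 0).
    """
    dt = 1.0 / (config.sampling_rate * oversample)
    half = 2.0e-6
    t = np.arange(-half, half + dt / 2, dt)
    raw = np.zeros_like(t)
    raw[(t >= -duration / 2) & (t < 0)] = 1.0
    raw[(t >= 0) & (t < duration / 2)] = -1.0
    return _make_pulse(t, raw, config)


def band_impulse(config: AcquisitionConfig, oversample: int = 16) -> Pulse:
    """Zero-phase impulse response of the transducer band (receive model)."""
    dt = 1.0 / (config.sampling_rate * oversample)
    half = 2.0e-6
    t = np.arange(-half, half + dt / 2, dt)
    raw = np.zeros_like(t)
    raw[np.argmin(np.abs(t))] = 1.0
    return _make_pulse(t, raw, config)


def _segment_samples(starts: np.ndarray, ends: np.ndarray, step_mm: float):
    """Midpoint samples along segments; yields (points, ds_m, row lengths)."""
    starts = np.atleast_2d(starts)
    ends = np.atleast_2d(ends)
    d = np.linalg.norm(ends - starts, axis=1)
    n = np.maximum(np.ceil(d / step_mm).astype(int), 1)
    return d, n


def line_integral_tof(
    starts,
    ends,
    slowness: np.ndarray,
    grid: Grid,
    water_slowness: float,
    step_mm: float = 0.5,
) -> np.ndarray:
    """Straight-ray travel times through a slowness map (s).

    Midpoint-rule integral of slowness along each segment; sample points
    falling outside the grid contribute the water slowness.
    """
    starts = np.atleast_2d(np.asarray(starts, dtype=float))
    ends = np.atleast_2d(np.asarray(ends, dtype=float))
    d_mm, n_steps = _segment_samples(starts, ends, step_mm)
    n_max = int(n_steps.max())
    tof = np.zeros(len(starts))
    # Uniform sample count per ray keeps the computation fully vectorised;
    # each ray uses its own effective step d/n <= step_mm.
    frac = (np.arange(n_max) + 0.5) / n_max
    for k in range(n_max):
        pts = starts + frac[k] * (ends - starts)
        ix = np.round((pts[:, 0] - grid.origin[0]) / grid.pixel_size).astype(int)
        iy = np.round((pts[:, 1] - grid.origin[1]) / grid.pixel_size).astype(int)
        inside = (ix >= 0) & (ix < grid.nx) & (iy >= 0) & (iy < grid.ny)
        s_here = np.where(
            inside, slowness[np.clip(iy, 0, grid.ny - 1), np.clip(ix, 0, grid.nx - 1)], water_slowness
        )
        tof += s_here
    return tof * (d_mm * MM / n_max)


def build_path_matrix(
    waypoints: np.ndarray, grid: Grid, step_mm: float = 0.5
) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Sparse path-length matrix for piecewise-linear rays.

    Parameters
    ----------
    waypoints:
        ``(n_rays, n_pts, 2)`` polyline vertices in mm.
    step_mm:
        Sampling step along each segment.

    Returns
    -------
    L, outside
        ``L`` is ``(n_rays, ny*nx)`` CSR with path length per pixel in m
        (midpoint-rule attribution); ``outside`` is the per-ray path length
        (m) falling outside the grid, to be multiplied by the known water
        slowness.  Travel time = ``L @ slowness.ravel() + outside * s_water``.
    """
    waypoints = np.asarray(waypoints, dtype=float)
    n_rays, n_pts, _ = waypoints.shape
    npix = grid.ny * grid.nx
    rows_all, cols_all, vals_all = [], [], []
    outside = np.zeros(n_rays)
    for seg in range(n_pts - 1):
        starts = waypoints[:, seg]
        ends = waypoints[:, seg + 1]
        d_mm, _ = _segment_samples(starts, ends, step_mm)
        n_max = max(int(np.ceil(d_mm.max() / step_mm)), 1)
        ds_m = d_mm * MM / n_max
        frac = (np.arange(n_max) + 0.5) / n_max
        for k in range(n_max):
            pts = starts + frac[k] * (ends - starts)
            ix = np.round((pts[:, 0] - grid.origin[0]) / grid.pixel_size).astype(int)
            iy = np.round((pts[:, 1] - grid.origin[1]) / grid.pixel_size).astype(int)
            inside = (ix >= 0) & (ix < grid.nx) & (iy >= 0) & (iy < grid.ny)
            rows = np.nonzero(inside)[0]
            if rows.size:
                rows_all.append(rows)
                cols_all.append(iy[rows] * grid.nx + ix[rows])
                vals_all.append(ds_m[rows])
            outside += np.where(inside, 0.0, ds_m)
    if rows_all:
        rows = np.concatenate(rows_all)
        cols = np.concatenate(cols_all)
        vals = np.concatenate(vals_all)
    else:  # pragma: no cover - degenerate geometry
        rows = cols = np.zeros(0, dtype=int)
        vals = np.zeros(0)
    L = sparse.coo_matrix((vals, (rows, cols)), shape=(n_rays, npix)).tocsr()
    return L, outside


def fan_waypoints(
    tx_xy: np.ndarray,
    rx_xy: np.ndarray,
    n_paths: int,
    wavelength_mm: float,
) -> np.ndarray:
    """Fan of paths per pair: straight ray plus laterally offset bent rays.

    Control points sit at the segment midpoint, offset perpendicular to the
    ray within the first-Fresnel-zone half width ``0.5*sqrt(lambda*d)``.
    Returns ``(n_pairs*n_paths, 3, 2)`` polylines grouped pair-major.
    """
    tx_xy = np.atleast_2d(tx_xy)
    rx_xy = np.atleast_2d(rx_xy)
    n_pairs = len(tx_xy)
    delta = rx_xy - tx_xy
    d = np.linalg.norm(delta, axis=1, keepdims=True)
    perp = np.column_stack([-delta[:, 1], delta[:, 0]]) / np.maximum(d, 1e-12)
    mid = 0.5 * (tx_xy + rx_xy)
    half_width = 0.5 * np.sqrt(wavelength_mm * d)
    if n_paths == 1:
        offsets = np.zeros(1)
    else:
        offsets = np.linspace(-1.0, 1.0, n_paths)
    way = np.empty((n_pairs, n_paths, 3, 2))
    way[:, :, 0] = tx_xy[:, None]
    way[:, :, 2] = rx_xy[:, None]
    way[:, :, 1] = mid[:, None] + offsets[None, :, None] * half_width[:, None] * perp[:, None]
    return way.reshape(n_pairs * n_paths, 3, 2)


def element_pixel_distances(geometry: RingGeometry, grid: Grid) -> np.ndarray:
    """``(n_elements, ny*nx)`` element-to-pixel distances in mm."""
    pix = grid.pixel_coords()
    diff = pix[None, :, :] - geometry.element_positions[:, None, :]
    return np.linalg.norm(diff, axis=2)


def dual_sos_travel_times(
    geometry: RingGeometry,
    body_mask: np.ndarray,
    grid: Grid,
    c_water: float,
    c_tissue: float,
    step_mm: float = 0.5,
) -> np.ndarray:
    """Two-segment travel times pixel -> element (s), shape (n_el, ny, nx).

    The straight segment from each pixel to each element is split into its
    in-body and in-water portions: ``t = len_water/c_water +
    len_tissue/c_tissue``.  The in-body length is measured by sampling the
    segment against ``body_mask``.
    """
    if body_mask.shape != grid.shape:
        raise ValueError("body_mask shape must match grid")
    pix = grid.pixel_coords()
    dist = element_pixel_distances(geometry, grid)  # mm
    n_el = geometry.n_elements
    npix = pix.shape[0]
    mask = body_mask.astype(bool)
    t = np.empty((n_el, npix))
    n_steps = max(int(np.ceil(dist.max() / step_mm)), 1)
    frac = (np.arange(n_steps) + 0.5) / n_steps
    for e in range(n_el):
        src = geometry.element_positions[e]
        inside_count = np.zeros(npix)
        for f in frac:
            pts = src + f * (pix - src)
            ix = np.round((pts[:, 0] - grid.origin[0]) / grid.pixel_size).astype(int)
            iy = np.round((pts[:, 1] - grid.origin[1]) / grid.pixel_size).astype(int)
            ok = (ix >= 0) & (ix < grid.nx) & (iy >= 0) & (iy < grid.ny)
            hit = np.zeros(npix, dtype=bool)
            hit[ok] = mask[iy[ok], ix[ok]]
            inside_count += hit
        len_tissue = dist[e] * MM * inside_count / n_steps
        len_water = dist[e] * MM - len_tissue
        t[e] = len_water / c_water + len_tissue / c_tissue
    return t.reshape(n_el, grid.ny, grid.nx)


def add_pulses(
    traces: np.ndarray,
    tofs: np.ndarray,
    amps: np.ndarray,
    pulse: Pulse,
    config: AcquisitionConfig,
) -> None:
    """Accumulate ``amp * pulse(t - tof)`` into trace rows, in place.

    ``traces`` is ``(n_events, n_samples)``; the wavelet is evaluated with
    its spline at exact (sub-sample) delays within its support window.
    """
    dt = config.dt
    t0 = config.acquisition_delay
    n_samples = config.n_samples
    win = int(np.ceil((pulse.t_max - pulse.t_min) / dt)) + 2
    first = np.ceil((tofs + pulse.t_min - t0) / dt).astype(int)
    offs = np.arange(win)
    idx = first[:, None] + offs[None, :]
    tt = t0 + idx * dt - tofs[:, None]
    vals = amps[:, None] * pulse(tt)
    valid = (idx >= 0) & (idx < n_samples)
    rows = np.broadcast_to(np.arange(len(tofs))[:, None], idx.shape)
    np.add.at(traces, (rows[valid], idx[valid]), vals[valid])
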