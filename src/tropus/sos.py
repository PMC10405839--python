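"""Quantitative speed-of-sound imaging from transmitted waves.

Pipeline: (1) reference waveforms and travel times for every
emitter/opposite-arc-receiver pair are obtained from a water-only
acquisition; (2) per-pair time of flight is picked by matching-pursuit
decomposition of the measured trace into scaled, time-shifted copies of
the reference wavelet (the earliest retained shift is the TOF — robust to
overlapping multipath arrivals); (3) straight-ray travel-time tomography
(damped SIRT sweeps) converts the TOF differences into an initial slowness
map; (4) a gradient-descent waveform inversion refines the map by
minimising the mean-squared error between modelled and measured windows,
with each pair's wavefield modelled as the average of the reference
wavelet time-shifted along a fan of rays spanning the first Fresnel zone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve

from ._rays import MM, Pulse, build_path_matrix, fan_waypoints, transmit_pulse
from .containers import Grid, ReconImage, SignalSet, SOS_BOUNDS
from .geometry import AcquisitionConfig, RingGeometry, opposite_arc_receivers

__all__ = [
    "ReferenceSet",
    "TOFMatrix",
    "SlownessGrid",
    "FWIState",
    "acquire_reference",
    "estimate_tof",
    "initial_sos_from_tof",
    "WaveformModel",
    "forward_waveforms",
    "fwi_reconstruct",
    "sos_image",
]


def transmission_pairs(geometry: RingGeometry, half_angle: float = np.pi / 3) -> np.ndarray:
    """All (emitter, receiver) pairs with receivers on the opposite arc."""
    pairs = []
    for tx in range(geometry.n_elements):
        for rx in opposite_arc_receivers(geometry, tx, half_angle):
            pairs.append((tx, rx))
    return np.asarray(pairs, dtype=int)


@dataclass
class ReferenceSet:
    """Water-path reference waveforms per emitter-receiver pair.

    The coupling water is homogeneous, so the reference trace of a pair at
    distance ``d`` is the transmit wavelet delayed by ``d/c_water`` and
    scaled by geometric spreading; ``tof`` holds those analytic water
    travel times.
    """

    geometry: RingGeometry
    config: AcquisitionConfig
    pairs: np.ndarray
    tof: np.ndarray
    amplitude: np.ndarray
    pulse: Pulse

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def traces(self) -> np.ndarray:
        """Synthesised reference traces, ``(n_pairs, n_samples)``."""
        t = self.config.times[None, :] - self.tof[:, None]
        return self.amplitude[:, None] * self.pulse(t)


@dataclass
class TOFMatrix:
    """Per-pair first-arrival times (s) with validity flags."""

    pairs: np.ndarray
    tof: np.ndarray
    validity: np.ndarray
    reference_tof: np.ndarray

    def __post_init__(self) -> None:
        v = self.validity
        if np.any(self.tof[v] <= 0):
            raise ValueError("valid TOFs must be positive")
        if np.any(self.tof[v] < 0.8 * self.reference_tof[v]):
            raise ValueError("valid TOF below 0.8x the water reference is unphysical")


@dataclass
class SlownessGrid:
    """Per-pixel slowness (s/m) on a reconstruction grid."""

    slowness: np.ndarray
    grid: Grid
    water_slowness: float

    def __post_init__(self) -> None:
        if self.slowness.shape != self.grid.shape:
            raise ValueError("slowness shape must match grid")
        if np.any(self.slowness <= 0):
            raise ValueError("slowness must be positive")

    @property
    def sos(self) -> np.ndarray:
        return 1.0 / self.slowness


@dataclass
class FWIState:
    """Progress of the waveform inversion."""

    iteration: int = 0
    loss: float = np.inf
    step_size: float = 0.0
    loss_history: list[float] = field(default_factory=list)
    n_clipped_paths: int = 0


def acquire_reference(
    geometry: RingGeometry,
    config: AcquisitionConfig,
    half_angle: float = np.pi / 3,
    min_amp_distance_mm: float = 2.0,
) -> ReferenceSet:
    """Reference waveforms/TOFs for all opposite-arc pairs in water."""
    pairs = transmission_pairs(geometry, half_angle)
    pos = geometry.element_positions
    d_mm = np.linalg.norm(pos[pairs[:, 0]] - pos[pairs[:, 1]], axis=1)
    tof = d_mm * MM / config.water_sos
    amp = 1.0 / np.sqrt(np.maximum(d_mm, min_amp_distance_mm) * MM)
    return ReferenceSet(
        geometry=geometry, config=config, pairs=pairs, tof=tof, amplitude=amp,
        pulse=transmit_pulse(config),
    )


def _measured_windows(
    measured: SignalSet, reference: ReferenceSet, before: float, after: float
) -> tuple[np.ndarray, np.ndarray, int]:
    """Extract per-pair windows around the water reference TOF."""
    cfg = reference.config
    n_win = int(round((before + after) / cfg.dt))
    start = np.floor((reference.tof - before - cfg.acquisition_delay) / cfg.dt).astype(int)
    if start.min() < 0 or (start + n_win).max() > cfg.n_samples:
        raise ValueError("TOF window extends beyond the record; adjust window or n_samples")
    rows = np.asarray(measured.data, dtype=float)[reference.pairs[:, 0], reference.pairs[:, 1]]
    idx = start[:, None] + np.arange(n_win)[None, :]
    return np.take_along_axis(rows, idx, axis=1), start, n_win


def estimate_tof(
    measured: SignalSet,
    reference: ReferenceSet,
    search_before: float = 2.0e-6,
    search_after: float = 4.0e-6,
    max_components: int = 5,
    residual_energy_frac: float = 0.05,
    min_component_frac: float = 0.20,
) -> TOFMatrix:
    """Pick per-pair first-arrival times by matching pursuit.

    Each measured trace (windowed around the water arrival) is greedily
    decomposed as ``sum_k a_k * w(t - tau_k)`` with ``w`` the reference
    wavelet, via iterative cross-correlation peak extraction with parabolic
    sub-sample refinement.  Components stop at ``max_components``, when the
    residual energy drops below ``residual_energy_frac`` of the original,
    or when a component amplitude falls below ``min_component_frac`` of the
    first.  The TOF is the smallest retained shift — the first arrival,
    not an energy-weighted mean — which keeps overlapping multipath
    arrivals from biasing the pick late.
    """
    cfg = reference.config
    dt = cfg.dt
    M, start, n_win = _measured_windows(measured, reference, search_before, search_after)
    n_pairs = M.shape[0]
    kernel, k_center = reference.pulse.sampled(dt)
    k_energy = float(kernel @ kernel)
    t_win = cfg.acquisition_delay + (start[:, None] + np.arange(n_win)[None, :]) * dt

    residual = M.copy()
    energy0 = np.sum(M * M, axis=1)
    first_amp = np.zeros(n_pairs)
    best_tau = np.full(n_pairs, np.inf)
    n_comps = np.zeros(n_pairs, dtype=int)
    active = energy0 > 0

    for _ in range(max_components):
        if not active.any():
            break
        corr = fftconvolve(residual[active], kernel[::-1][None, :], mode="full", axes=1)
        peak = np.argmax(corr, axis=1)
        rows = np.arange(corr.shape[0])
        c0 = corr[rows, peak]
        # parabolic sub-sample refinement of the correlation peak
        ok_in = (peak > 0) & (peak < corr.shape[1] - 1)
        cm = np.where(ok_in, corr[rows, np.maximum(peak - 1, 0)], 0.0)
        cp = np.where(ok_in, corr[rows, np.minimum(peak + 1, corr.shape[1] - 1)], 0.0)
        denom = cm - 2 * c0 + cp
        delta = np.where(np.abs(denom) > 1e-30, 0.5 * (cm - cp) / denom, 0.0)
        delta = np.clip(delta, -0.5, 0.5)
        act_idx = np.nonzero(active)[0]
        # lag -> absolute shift: kernel index 0 aligned at window sample
        # (peak - (len(kernel)-1)); wavelet centre at k_center later.
        lag = peak - (len(kernel) - 1) + delta
        tau = cfg.acquisition_delay + (start[act_idx] + lag + k_center) * dt
        # quarter-sample refinement: the correlation oscillates at the
        # carrier (few samples per period), so re-evaluate it on a fine
        # offset grid with the wavelet spline and re-fit the parabola
        R_act = residual[act_idx]
        tw = t_win[act_idx]
        fine = 0.25 * dt
        c_fine = np.empty((3, len(act_idx)))
        for j, off in enumerate((-fine, 0.0, fine)):
            c_fine[j] = np.sum(R_act * reference.pulse(tw - (tau + off)[:, None]), axis=1)
        denom_f = c_fine[0] - 2 * c_fine[1] + c_fine[2]
        delta_f = np.where(np.abs(denom_f) > 1e-30, 0.5 * (c_fine[0] - c_fine[2]) / denom_f, 0.0)
        delta_f = np.clip(delta_f, -1.0, 1.0)
        tau = tau + delta_f * fine
        c0 = np.max(c_fine, axis=0)
        amps = c0 / k_energy

        keep = amps > 0
        newly_first = keep & (n_comps[act_idx] == 0)
        first_amp[act_idx[newly_first]] = amps[newly_first]
        strong = keep & (amps >= min_component_frac * np.where(first_amp[act_idx] > 0, first_amp[act_idx], np.inf))
        retained = newly_first | strong
        best_tau[act_idx[retained]] = np.minimum(best_tau[act_idx[retained]], tau[retained])
        n_comps[act_idx[retained]] += 1

        # subtract retained components and update the active set
        comp = amps[:, None] * reference.pulse(t_win[act_idx] - tau[:, None])
        residual[act_idx[retained]] -= comp[retained]
        res_energy = np.sum(residual[act_idx] ** 2, axis=1)
        still = retained & (res_energy > residual_energy_frac * energy0[act_idx])
        active = np.zeros_like(active)
        active[act_idx[still]] = True

    tof = np.where(np.isfinite(best_tau), best_tau, 0.0)
    validity = (
        np.isfinite(best_tau)
        & (first_amp > 0)
        & (tof >= 0.8 * reference.tof)
        & (tof < cfg.acquisition_delay + cfg.n_samples * dt)
    )
    return TOFMatrix(
        pairs=reference.pairs, tof=tof, validity=validity, reference_tof=reference.tof
    )


def initial_sos_from_tof(
    tofm: TOFMatrix,
    geometry: RingGeometry,
    grid: Grid,
    water_sos: float,
    support: np.ndarray | None = None,
    n_sweeps: int = 20,
    relaxation: float = 0.7,
    damping: float = 0.05,
    smooth_sigma_px: float = 1.0,
    path_step_mm: float = 0.5,
) -> SlownessGrid:
    """Straight-ray travel-time tomography for the slowness starting model.

    Solves ``L @ dslowness = dtof`` (path-length matrix against TOF
    differences to water) with damped SIRT sweeps; a light Gaussian
    smoothing per sweep regularises the under-determined arc coverage.
    Outside the optional ``support`` mask the medium is fixed to water.
    Resulting speed of sound is clamped to the plausible tissue range.
    """
    valid = tofm.validity
    if valid.mean() < 0.20:
        raise ValueError(
            f"only {valid.mean():.0%} of pairs have valid TOFs; need at least 20%"
        )
    pairs = tofm.pairs[valid]
    pos = geometry.element_positions
    waypoints = np.stack([pos[pairs[:, 0]], pos[pairs[:, 1]]], axis=1)
    L, _ = build_path_matrix(waypoints, grid, step_mm=path_step_mm)
    b = tofm.tof[valid] - tofm.reference_tof[valid]

    if support is not None:
        keep = sparse.diags(support.ravel().astype(float))
        L = (L @ keep).tocsr()

    row_sum = np.asarray(L.sum(axis=1)).ravel()
    col_sum = np.asarray(L.sum(axis=0)).ravel()
    inv_row = np.where(row_sum > 1e-12, 1.0 / np.maximum(row_sum, 1e-12), 0.0)
    inv_col = np.where(col_sum > 1e-12, 1.0 / np.maximum(col_sum, 1e-12), 0.0)

    x = np.zeros(grid.ny * grid.nx)
    for _ in range(n_sweeps):
        r = b - L @ x
        x = (1.0 - relaxation * damping) * x + relaxation * inv_col * (L.T @ (inv_row * r))
        if smooth_sigma_px > 0:
            x2 = gaussian_filter(x.reshape(grid.shape), smooth_sigma_px)
            if support is not None:
                x2[~support] = 0.0
            x = x2.ravel()
    slowness = 1.0 / water_sos + x
    sos = np.clip(1.0 / slowness, SOS_BOUNDS[0], SOS_BOUNDS[1])
    return SlownessGrid(slowness=1.0 / sos.reshape(grid.shape), grid=grid, water_slowness=1.0 / water_sos)


class WaveformModel:
    """Ray-fan waveform forward model and its exact gradient.

    Per pair the modelled window is ``amp/n_paths * sum_p w(t - tau_p)``
    with ``tau_p`` the slowness line integral along each of ``n_paths``
    paths (the straight ray plus bent rays through control points offset
    laterally within the first Fresnel-zone half width).  The model is
    linear in the path travel times, so the loss gradient with respect to
    per-pixel slowness is the path matrix transpose applied to the per-path
    wavelet-derivative correlations.
    """

    def __init__(
        self,
        reference: ReferenceSet,
        grid: Grid,
        n_paths: int = 7,
        window_before: float = 1.5e-6,
        window_after: float = 2.5e-6,
        path_step_mm: float = 0.5,
        support: np.ndarray | None = None,
    ) -> None:
        self.reference = reference
        self.grid = grid
        self.n_paths = int(n_paths)
        if self.n_paths < 1:
            raise ValueError("n_paths must be >= 1")
        self.window_before = window_before
        self.window_after = window_after
        cfg = reference.config
        pos = reference.geometry.element_positions
        pairs = reference.pairs
        lam_mm = cfg.water_sos / cfg.center_frequency * 1e3
        way = fan_waypoints(pos[pairs[:, 0]], pos[pairs[:, 1]], self.n_paths, lam_mm)
        self.n_clipped_paths = int(
            np.sum(
                (way[:, 1, 0] < grid.x[0]) | (way[:, 1, 0] > grid.x[-1])
                | (way[:, 1, 1] < grid.y[0]) | (way[:, 1, 1] > grid.y[-1])
            )
        )
        if self.n_clipped_paths:
            warnings.warn(
                f"{self.n_clipped_paths} fan-path control points clipped to the grid",
                stacklevel=2,
            )
        self.L, self.outside_m = build_path_matrix(way, grid, step_mm=path_step_mm)
        # static correction: bent fan paths are geometrically longer than the
        # straight ray even in pure water; subtracting each path's water-path
        # excess makes the fan reduce exactly to the reference in water and
        # removes the resulting slow bias from the inversion
        water_slowness = 1.0 / reference.config.water_sos
        path_len_tof = (
            np.asarray(self.L.sum(axis=1)).ravel() + self.outside_m
        ) * water_slowness
        self.static_correction = path_len_tof.reshape(
            reference.n_pairs, self.n_paths
        ) - reference.tof[:, None]
        self.support = None
        if support is not None:
            self.support = support.ravel().astype(bool)
            keep = sparse.diags(self.support.astype(float))
            self.L_free = (self.L @ keep).tocsr()
        else:
            self.L_free = self.L
        dt = cfg.dt
        self.n_win = int(round((window_before + window_after) / dt))
        self.start = np.floor(
            (reference.tof - window_before - cfg.acquisition_delay) / dt
        ).astype(int)
        self.t_win = (
            cfg.acquisition_delay
            + (self.start[:, None] + np.arange(self.n_win)[None, :]) * dt
        )

    def path_tofs(self, slowness: np.ndarray) -> np.ndarray:
        """Per-(pair, path) travel times (s).

        Pixels outside the support mask are expected to hold the water
        slowness (the inversion keeps them projected there).
        """
        water_slowness = 1.0 / self.reference.config.water_sos
        tof = self.L @ slowness.ravel() + self.outside_m * water_slowness
        return tof.reshape(self.reference.n_pairs, self.n_paths) - self.static_correction

    def traces(self, slowness: np.ndarray) -> np.ndarray:
        """Modelled windowed traces ``(n_pairs, n_win)``."""
        tau = self.path_tofs(slowness)
        ref = self.reference
        E = np.zeros((ref.n_pairs, self.n_win))
        for p in range(self.n_paths):
            E += ref.pulse(self.t_win - tau[:, p][:, None])
        return (ref.amplitude / self.n_paths)[:, None] * E

    def measured_windows(self, measured: SignalSet) -> np.ndarray:
        M, start, _ = _measured_windows(
            measured, self.reference, self.window_before, self.window_after
        )
        if not np.array_equal(start, self.start):  # pragma: no cover - same formula
            raise AssertionError("window bookkeeping mismatch")
        return M

    def loss_and_grad(
        self, slowness: np.ndarray, M: np.ndarray, valid: np.ndarray
    ) -> tuple[float, np.ndarray]:
        """Mean-squared waveform error over valid pairs and its gradient."""
        ref = self.reference
        tau = self.path_tofs(slowness)
        scale = ref.amplitude / self.n_paths
        E = np.zeros_like(M)
        W = [None] * self.n_paths
        for p in range(self.n_paths):
            W[p] = ref.pulse(self.t_win - tau[:, p][:, None])
            E += W[p]
        E *= scale[:, None]
        D = (E - M) * valid[:, None]
        n_tot = max(int(valid.sum()), 1) * self.n_win
        loss = float(np.sum(D * D)) / n_tot
        g_tau = np.empty((ref.n_pairs, self.n_paths))
        for p in range(self.n_paths):
            dW = ref.pulse.derivative(self.t_win - tau[:, p][:, None])
            g_tau[:, p] = -(2.0 / n_tot) * scale * np.sum(D * dW, axis=1)
        grad = self.L_free.T @ g_tau.ravel()
        return loss, grad

    def loss(self, slowness: np.ndarray, M: np.ndarray, valid: np.ndarray) -> float:
        E = self.traces(slowness)
        D = (E - M) * valid[:, None]
        n_tot = max(int(valid.sum()), 1) * self.n_win
        return float(np.sum(D * D)) / n_tot


def forward_waveforms(
    slowness: SlownessGrid,
    reference: ReferenceSet,
    n_paths: int = 7,
    **model_kwargs,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimated windowed transmission traces for a slowness map.

    Returns ``(traces, window_start_indices)``: per opposite-arc pair, the
    reference wavelet averaged over the fan-path time shifts, in the
    per-pair analysis window around the water arrival.
    """
    model = WaveformModel(reference, slowness.grid, n_paths=n_paths, **model_kwargs)
    return model.traces(slowness.slowness), model.start


def fwi_reconstruct(
    measured: SignalSet,
    init: SlownessGrid,
    reference: ReferenceSet,
    n_iterations: int = 40,
    step: float | None = None,
    n_paths: int = 7,
    support: np.ndarray | None = None,
    tof_matrix: TOFMatrix | None = None,
    fixed_step: bool = False,
    max_halvings: int = 8,
    **model_kwargs,
) -> tuple[SlownessGrid, FWIState]:
    """Gradient-descent waveform inversion of the slowness map.

    Starting from the travel-time initialisation, iteratively updates the
    per-pixel slowness to reduce the mean-squared error between modelled
    and measured transmission windows.  The step size is Barzilai-Borwein
    after the first iteration (unless ``fixed_step``), safeguarded by a
    backtracking line search that halves the step up to ``max_halvings``
    times; only loss-decreasing steps are accepted, so the recorded loss
    history is non-increasing.  Slowness stays within the plausible
    speed-of-sound bounds (projected updates); pixels outside ``support``
    stay at water.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    model = WaveformModel(reference, init.grid, n_paths=n_paths, support=support, **model_kwargs)
    M = model.measured_windows(measured)
    valid = (
        tof_matrix.validity.astype(float)
        if tof_matrix is not None
        else np.ones(reference.n_pairs)
    )
    s_min, s_max = 1.0 / SOS_BOUNDS[1], 1.0 / SOS_BOUNDS[0]

    def project(x):
        x = np.clip(x, s_min, s_max)
        if support is not None:
            x = np.where(support.ravel(), x, init.water_slowness)
        return x

    x = project(init.slowness.ravel().copy())
    state = FWIState(n_clipped_paths=model.n_clipped_paths)
    loss, grad = model.loss_and_grad(x, M, valid)
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite initial waveform loss")
    state.loss = loss
    state.loss_history.append(loss)
    prev_x = None
    prev_grad = None
    # first trial step: slowness perturbation of ~1e-6 s/m at the gradient peak
    current_step = step if step is not None else 1e-6 / max(np.abs(grad).max(), 1e-30)

    for it in range(1, n_iterations + 1):
        if prev_x is not None and not fixed_step and step is None:
            s_vec = x - prev_x
            y_vec = grad - prev_grad
            sy = float(s_vec @ y_vec)
            yy = float(y_vec @ y_vec)
            if sy > 0 and yy > 0:
                current_step = sy / yy
        trial = current_step
        accepted = False
        for _ in range(max_halvings + 1):
            x_new = project(x - trial * grad)
            loss_new = model.loss(x_new, M, valid)
            if not np.isfinite(loss_new):
                raise FloatingPointError(f"non-finite loss at iteration {it}")
            if loss_new < loss:
                accepted = True
                break
            trial *= 0.5
        if not accepted:
            break
        prev_x, prev_grad = x, grad
        x = x_new
        loss = loss_new
        state.iteration = it
        state.step_size = trial
        state.loss_history.append(loss)
        state.loss = loss
        if it < n_iterations:
            _, grad = model.loss_and_grad(x, M, valid)
        current_step = trial
    out = SlownessGrid(
        slowness=x.reshape(init.grid.shape), grid=init.grid, water_slowness=init.water_slowness
    )
    return out, state


def sos_image(slowness: SlownessGrid) -> ReconImage:
    """Speed-of-sound map (m/s) as a :class:`ReconImage`."""
    sos = np.clip(slowness.sos, SOS_BOUNDS[0], SOS_BOUNDS[1])
    return ReconImage(
        pixels=sos,
        pixel_size=slowness.grid.pixel_size,
        origin=slowness.grid.origin,
        mode="sos",
        units="m/s",
    )
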