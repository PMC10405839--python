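"""Forward simulation of the three acquisition modes on digital phantoms.

Optoacoustic (MSOT) records are spherical-mean projections of the initial
pressure seen through the transducer band; pulse-echo/transmission (STA)
records are built from straight-ray travel times through the phantom's
speed-of-sound map.  Both share the exact kinematic model used by the
reconstruction stages.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

from ._rays import (
    MM,
    add_pulses,
    band_impulse,
    dual_sos_travel_times,
    line_integral_tof,
    transmit_pulse,
)
from .containers import SignalSet
from .geometry import AcquisitionConfig, RingGeometry
from .msot import bessel_fluence
from .phantoms import Phantom
from .spectra import ChromophoreSpectraLibrary, default_spectra

__all__ = ["simulate_optoacoustic", "simulate_sta", "RecordTooShortError"]


class RecordTooShortError(ValueError):
    """The configured record cannot contain the required arrivals."""


def _bin_projection(p0_flat, floor_idx, frac, n_samples):
    """Histogram pixel amplitudes into time bins with linear splitting."""
    g = np.bincount(floor_idx, weights=p0_flat * (1.0 - frac), minlength=n_samples + 2)
    g += np.bincount(floor_idx + 1, weights=p0_flat * frac, minlength=n_samples + 2)
    return g[:n_samples]


def simulate_optoacoustic(
    phantom: Phantom,
    geometry: RingGeometry,
    config: AcquisitionConfig,
    fluence_mu_eff: float = 0.15,
    n_repeats: int = 200,
    noise_sd: float | None = None,
    motion_fraction: float = 0.0,
    spectra: ChromophoreSpectraLibrary | None = None,
    c_tissue: float | None = None,
    seed: int = 0,
    travel_times: np.ndarray | None = None,
) -> tuple[dict[float, SignalSet], np.ndarray]:
    """Simulate multispectral optoacoustic sinograms.

    The initial pressure at wavelength ``lam`` is ``p0 = mu_a(x, lam) *
    Phi(x)`` with ``mu_a`` assembled from the phantom concentration maps and
    the chromophore spectra and ``Phi`` the modified-Bessel disc fluence
    model (the Grueneisen constant and laser energy are absorbed into the
    arbitrary units).  Each element records the circular-arc projection of
    ``p0`` (dual-speed straight-segment kinematics), differentiated in time
    and filtered by the transducer band.

    Parameters
    ----------
    n_repeats:
        Laser shots per wavelength (the full acquisition averages 200).
    noise_sd:
        Additive white-noise sd in a.u.; ``None`` uses 1% of the clean peak.
    motion_fraction:
        Fraction of frames corrupted by a rigid phantom shift of at least
        2 pixels, exercising the motion-rejection stage.

    Returns
    -------
    signals, corrupted
        Mapping wavelength -> :class:`SignalSet` (frames = repeats) and a
        boolean array flagging the motion-corrupted frame indices (shared
        across wavelengths — breathing displaces whole frames).
    """
    if spectra is None:
        spectra = default_spectra()
    grid = phantom.grid
    wavelengths = np.asarray(config.wavelengths, dtype=float)
    if wavelengths.min() < spectra.wavelengths[0] or wavelengths.max() > spectra.wavelengths[-1]:
        raise ValueError("requested wavelength outside spectra support")
    A = spectra.resample(wavelengths)  # (n_wl, 4)
    if c_tissue is None:
        c_tissue = float(phantom.sos_map[phantom.body_mask].mean()) if phantom.body_mask.any() else phantom.water_sos
    if travel_times is None:
        travel_times = dual_sos_travel_times(
            geometry, phantom.body_mask, grid, phantom.water_sos, c_tissue
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 271]))

    fluence = bessel_fluence(phantom.body_mask, grid, fluence_mu_eff) if phantom.body_mask.any() else np.ones(grid.shape)
    mu_a = np.tensordot(A, phantom.concentration_maps, axes=(1, 0))  # (n_wl, ny, nx)
    p0 = mu_a * fluence[None]

    n_el = geometry.n_elements
    n_samples = config.n_samples
    dt = config.dt
    s_pos = (travel_times.reshape(n_el, -1) - config.acquisition_delay) / dt
    if s_pos.max() >= n_samples - 1:
        raise RecordTooShortError(
            "record too short for the farthest pixel arrival; increase n_samples"
        )
    floor_idx = np.floor(s_pos).astype(np.int64)
    frac = s_pos - floor_idx

    impulse = band_impulse(config)
    kernel, k_center = impulse.sampled(dt)

    n_corrupt = int(round(motion_fraction * n_repeats))
    corrupted = np.zeros(n_repeats, dtype=bool)
    if n_corrupt:
        corrupted[rng.choice(n_repeats, size=n_corrupt, replace=False)] = True

    def clean_signal(p0_map):
        flat = p0_map.ravel()
        g = np.empty((n_el, n_samples))
        for e in range(n_el):
            g[e] = _bin_projection(flat, floor_idx[e], frac[e], n_samples)
        dg = np.gradient(g, dt, axis=1)
        full = fftconvolve(dg, kernel[None, :], mode="full", axes=1)
        return full[:, k_center : k_center + n_samples]

    out: dict[float, SignalSet] = {}
    shift_cache: dict[int, tuple[int, int]] = {}
    for w, lam in enumerate(wavelengths):
        clean = clean_signal(p0[w])
        peak = np.abs(clean).max()
        sd = 0.01 * peak if noise_sd is None else noise_sd
        frames = np.empty((n_repeats, n_el, n_samples), dtype=np.float32)
        for r in range(n_repeats):
            if corrupted[r]:
                if r not in shift_cache:
                    mag = rng.integers(2, 5, size=2)
                    sign = rng.choice([-1, 1], size=2)
                    shift_cache[r] = (int(mag[0] * sign[0]), int(mag[1] * sign[1]))
                dy, dx = shift_cache[r]
                shifted = np.roll(p0[w], (dy, dx), axis=(0, 1))
                sig = clean_signal(shifted)
            else:
                sig = clean
            frames[r] = sig + sd * rng.standard_normal((n_el, n_samples))
        out[float(lam)] = SignalSet(
            mode="msot", data=frames, config=config, geometry=geometry, wavelength_nm=float(lam)
        )
    return out, corrupted


def simulate_sta(
    phantom: Phantom,
    geometry: RingGeometry,
    config: AcquisitionConfig,
    noise_sd: float | None = None,
    seed: int = 0,
    min_amp_distance_mm: float = 2.0,
) -> SignalSet:
    """Simulate the full synthetic-transmit-aperture block.

    One element transmits a band-limited single-cycle bipolar pulse at a
    time while all elements receive:

    * transmission component — the pulse delayed by the straight-ray travel
      time through the speed-of-sound map and scaled by ``1/sqrt(path)``;
    * reflection component — for every phantom scatterer, the pulse delayed
      by ``t(tx->s) + t(s->rx)`` (straight rays through the map), scaled by
      reflectivity over the two-leg geometric spreading.

    Additive white Gaussian noise is applied to the whole block (default
    sd: 1% of the transmission amplitude of a median-distance pair).
    """
    grid = phantom.grid
    slowness = 1.0 / phantom.sos_map  # s/m
    water_slowness = 1.0 / phantom.water_sos
    pos = geometry.element_positions
    n_el = geometry.n_elements
    n_samples = config.n_samples
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 577]))
    pulse = transmit_pulse(config)

    # --- transmission (traversing) waves, exact sub-sample synthesis ---
    tx_idx, rx_idx = np.meshgrid(np.arange(n_el), np.arange(n_el), indexing="ij")
    tx_idx = tx_idx.ravel()
    rx_idx = rx_idx.ravel()
    off_diag = tx_idx != rx_idx
    starts = pos[tx_idx[off_diag]]
    ends = pos[rx_idx[off_diag]]
    d_mm = np.linalg.norm(ends - starts, axis=1)
    tof = line_integral_tof(starts, ends, slowness, grid, water_slowness)
    t_end = config.acquisition_delay + (n_samples - 1) * config.dt
    if tof.max() + pulse.t_max > t_end:
        raise RecordTooShortError(
            f"record ends at {t_end * 1e6:.1f} us but the slowest transmission "
            f"arrives at {tof.max() * 1e6:.1f} us; increase n_samples"
        )
    amp = 1.0 / np.sqrt(np.maximum(d_mm, min_amp_distance_mm) * MM)
    typical_amp = float(np.median(amp))
    block = np.zeros((n_el * n_el, n_samples))
    tmp = np.zeros((off_diag.sum(), n_samples))
    add_pulses(tmp, tof, amp, pulse, config)
    block[off_diag] = tmp

    # --- reflections from discrete scatterers via impulse trains ---
    scat = phantom.scatterers
    if len(scat):
        s_xy = scat[:, :2]
        refl = scat[:, 2]
        n_s = len(scat)
        el_rep = np.repeat(pos, n_s, axis=0)
        sc_rep = np.tile(s_xy, (n_el, 1))
        d_es = np.linalg.norm(el_rep - sc_rep, axis=1).reshape(n_el, n_s)  # mm
        tof_es = line_integral_tof(el_rep, sc_rep, slowness, grid, water_slowness).reshape(n_el, n_s)
        kernel, k_center = pulse.sampled(config.dt)
        spread = np.sqrt(np.maximum(d_es, min_amp_distance_mm) * MM)
        block3 = block.reshape(n_el, n_el, n_samples)
        for tx in range(n_el):
            ev_tof = tof_es[tx][None, :] + tof_es  # (rx, n_s)
            ev_amp = refl[None, :] / (spread[tx][None, :] * spread)
            s_pos = (ev_tof - config.acquisition_delay) / config.dt
            ok = (s_pos > 0) & (s_pos < n_samples - 1)
            fl = np.floor(s_pos).astype(np.int64)
            fr = s_pos - fl
            imp = np.zeros((n_el, n_samples + 1))
            rows = np.broadcast_to(np.arange(n_el)[:, None], fl.shape)
            np.add.at(imp, (rows[ok], fl[ok]), (ev_amp * (1 - fr))[ok])
            np.add.at(imp, (rows[ok], fl[ok] + 1), (ev_amp * fr)[ok])
            echo = fftconvolve(imp[:, :n_samples], kernel[None, :], mode="full", axes=1)
            block3[tx] += echo[:, k_center : k_center + n_samples]
        block = block3.reshape(n_el * n_el, n_samples)

    # default noise: 1% of the typical (median-distance) transmission amplitude
    sd = 0.01 * typical_amp if noise_sd is None else noise_sd
    data = block.reshape(n_el, n_el, n_samples).astype(np.float32)
    if sd > 0:
        data = data + sd * rng.standard_normal(data.shape).astype(np.float32)
    return SignalSet(mode="sta", data=data, config=config, geometry=geometry)
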