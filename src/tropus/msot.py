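"""Optoacoustic image formation: filtering, motion rejection, dual-speed
back-projection, fluence correction, and display enhancement.

The quantitative product of this module is a multispectral stack of
back-projected, fluence-corrected images — the input to linear spectral
unmixing.  Contrast enhancement (adaptive histogram equalization plus
Frangi vesselness compositing) is a separate display product: equalization
is non-linear and would destroy the spectral proportionality that unmixing
relies on, so it is never applied to the stack that feeds quantification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt
from scipy.special import i0

from ._rays import dual_sos_travel_times
from .containers import Grid, ReconImage, SignalSet

__all__ = [
    "MultispectralStack",
    "bandpass",
    "reject_motion_frames",
    "backproject_dual_sos",
    "bessel_fluence",
    "correct_fluence",
    "enhance_and_composite",
    "reconstruct_stack",
    "MotionRejectionError",
]


class MotionRejectionError(RuntimeError):
    """Every frame fell below the motion-correlation threshold."""


@dataclass
class MultispectralStack:
    """Per-wavelength reconstructed images ``(n_wavelengths, ny, nx)``."""

    images: np.ndarray
    wavelengths: np.ndarray
    pixel_size: float
    body_mask: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.images.shape[0] != self.wavelengths.size:
            raise ValueError("first axis must match the wavelength grid")
        if self.images.shape[1:] != self.body_mask.shape:
            raise ValueError("image and mask grids differ")
        if not np.all(np.isfinite(self.images[:, self.body_mask])):
            raise ValueError("stack must be finite inside the body mask")


def bandpass(signals: SignalSet, low: float = 0.1e6, high: float = 6.0e6) -> SignalSet:
    """Zero-phase Butterworth band-pass per trace (default 0.1-6 MHz).

    Removes DC/low-frequency drift and out-of-band noise before
    back-projection.
    """
    nyquist = signals.config.sampling_rate / 2.0
    if not 0.0 < low < high < nyquist:
        raise ValueError(f"band ({low:g}, {high:g}) Hz must lie inside (0, {nyquist:g})")
    sos = butter(4, [low, high], btype="bandpass", fs=signals.config.sampling_rate, output="sos")
    data = sosfiltfilt(sos, np.asarray(signals.data, dtype=float), axis=-1)
    return SignalSet(
        mode=signals.mode,
        data=data,
        config=signals.config,
        geometry=signals.geometry,
        wavelength_nm=signals.wavelength_nm,
    )


def reject_motion_frames(
    frames: SignalSet, threshold: float = 0.90
) -> tuple[np.ndarray, np.ndarray]:
    """Split frames into kept/rejected by correlation with the median sinogram.

    Breathing shifts the whole cross-section between laser shots; affected
    sinograms decorrelate from the per-pixel median over the repeat axis.
    Frames whose normalized cross-correlation with the median falls below
    ``threshold`` are rejected.
    """
    data = np.asarray(frames.data, dtype=float)
    if data.shape[0] < 3:
        raise ValueError("motion rejection needs at least 3 frames")
    median = np.median(data, axis=0).ravel()
    median = median - median.mean()
    m_norm = np.linalg.norm(median)
    corrs = np.empty(data.shape[0])
    for i in range(data.shape[0]):
        f = data[i].ravel()
        f = f - f.mean()
        denom = np.linalg.norm(f) * m_norm
        corrs[i] = (f @ median) / denom if denom > 0 else 1.0
    kept = np.nonzero(corrs >= threshold)[0]
    rejected = np.nonzero(corrs < threshold)[0]
    if kept.size == 0:
        raise MotionRejectionError(
            "all frames rejected; lower the correlation threshold "
            f"(max frame correlation was {corrs.max():.3f})"
        )
    return kept, rejected


def backproject_dual_sos(
    signals: SignalSet | np.ndarray,
    body_mask: np.ndarray,
    c_water: float,
    c_tissue: float,
    grid: Grid,
    config=None,
    geometry=None,
    travel_times: np.ndarray | None = None,
) -> ReconImage:
    """Universal back-projection with water/tissue dual-speed delays.

    The delay from pixel ``x`` to element ``e`` splits the straight segment
    into its in-water and in-body portions, ``len_w/c_water +
    len_t/c_tissue``.  Each element contributes the universal-BP term
    ``2 s(t) - 2 t s'(t)`` interpolated linearly at the pixel delay.

    ``signals`` may be a :class:`SignalSet` (frames are averaged) or an
    already-averaged ``(n_elements, n_samples)`` array, in which case
    ``config`` and ``geometry`` must be given.
    """
    if isinstance(signals, SignalSet):
        sino = np.asarray(signals.data, dtype=float).mean(axis=0)
        config = signals.config
        geometry = signals.geometry
    else:
        sino = np.asarray(signals, dtype=float)
        if config is None or geometry is None:
            raise ValueError("config and geometry required for raw-array input")
    if body_mask.shape != grid.shape:
        raise ValueError("body_mask shape must match the target grid")
    for c, name in ((c_water, "c_water"), (c_tissue, "c_tissue")):
        if not 1300.0 <= c <= 1700.0:
            raise ValueError(f"{name}={c:g} m/s outside the plausible range")
    if travel_times is None:
        travel_times = dual_sos_travel_times(geometry, body_mask, grid, c_water, c_tissue)
    n_el, n_samples = sino.shape
    dt = config.dt
    times = config.times
    dsino = np.gradient(sino, dt, axis=1)
    term = 2.0 * sino - 2.0 * times[None, :] * dsino
    img = np.zeros(grid.ny * grid.nx)
    for e in range(n_el):
        s_pos = (travel_times[e].ravel() - config.acquisition_delay) / dt
        s_pos = np.clip(s_pos, 0, n_samples - 1 - 1e-9)
        fl = np.floor(s_pos).astype(np.int64)
        fr = s_pos - fl
        img += term[e, fl] * (1 - fr) + term[e, fl + 1] * fr
    return ReconImage(
        pixels=img.reshape(grid.shape),
        pixel_size=grid.pixel_size,
        origin=grid.origin,
        mode="msot",
        units="a.u.",
    )


def bessel_fluence(body_mask: np.ndarray, grid: Grid, mu_eff: float) -> np.ndarray:
    """Modified-Bessel disc model of light fluence inside the body.

    The body is approximated by a disc of equal area centred on the mask
    centroid; the relative fluence at distance ``rho`` from the centroid is
    ``I0(mu_eff*rho) / I0(mu_eff*R)`` — 1 at the surface, attenuated toward
    the centre.  Outside the mask the fluence is 1 (clear water).
    """
    if mu_eff <= 0:
        raise ValueError("mu_eff must be positive")
    if body_mask.sum() < 10:
        raise ValueError("degenerate body mask (< 10 pixels)")
    yy, xx = np.nonzero(body_mask)
    cx = grid.origin[0] + xx.mean() * grid.pixel_size
    cy = grid.origin[1] + yy.mean() * grid.pixel_size
    R = np.sqrt(body_mask.sum() * grid.pixel_size**2 / np.pi)
    gx, gy = grid.meshgrid()
    rho = np.hypot(gx - cx, gy - cy)
    phi = np.ones(grid.shape)
    phi[body_mask] = i0(mu_eff * rho[body_mask]) / i0(mu_eff * R)
    return phi


def correct_fluence(
    image: ReconImage, body_mask: np.ndarray, mu_eff: float, eps: float = 0.01
) -> ReconImage:
    """Divide out the modified-Bessel disc fluence inside the body mask.

    Pixels outside the mask are left unchanged; the fluence is floored at
    ``eps`` to avoid amplifying noise at extreme attenuation.
    """
    grid = image.grid
    phi = bessel_fluence(body_mask, grid, mu_eff)
    out = image.pixels.copy()
    out[body_mask] = image.pixels[body_mask] / np.maximum(phi[body_mask], eps)
    return ReconImage(
        pixels=out,
        pixel_size=image.pixel_size,
        origin=image.origin,
        mode=image.mode,
        units=image.units,
    )


def enhance_and_composite(
    image: ReconImage,
    body_mask: np.ndarray,
    alpha: float = 1.0,
    clip_limit: float = 0.01,
    tiles: int = 8,
    vessel_scales_mm: tuple[float, float] = (0.1, 0.5),
) -> ReconImage:
    """Display product: CLAHE plus Frangi vesselness, masked composite.

    Contrast-limited adaptive histogram equalization is applied to the
    masked image, a Frangi filter extracts tubular (vessel) structures at
    0.1-0.5 mm scales, and the composite is ``norm(equalized) + alpha *
    norm(vesselness)`` multiplied by the body mask (exact background
    suppression).
    """
    from skimage import exposure, filters

    px = np.nan_to_num(image.pixels, nan=0.0)
    lo, hi = px.min(), px.max()
    norm = (px - lo) / (hi - lo) if hi > lo else np.zeros_like(px)
    eq = exposure.equalize_adapthist(norm, kernel_size=max(px.shape[0] // tiles, 2), clip_limit=clip_limit)
    sigmas_px = np.linspace(
        vessel_scales_mm[0] / image.pixel_size, vessel_scales_mm[1] / image.pixel_size, 4
    )
    sigmas_px = np.maximum(sigmas_px, 0.5)
    vessel = filters.frangi(norm, sigmas=sigmas_px, black_ridges=False)
    vmax = vessel.max()
    vessel = vessel / vmax if vmax > 0 else vessel
    emax = eq.max()
    eqn = eq / emax if emax > 0 else eq
    comp = (eqn + alpha * vessel) * body_mask
    return ReconImage(
        pixels=comp,
        pixel_size=image.pixel_size,
        origin=image.origin,
        mode="msot",
        units="a.u.",
    )


def reconstruct_stack(
    frames_per_wavelength: dict[float, SignalSet],
    body_mask: np.ndarray,
    grid: Grid,
    c_water: float | None = None,
    c_tissue: float = 1540.0,
    mu_eff: float = 0.15,
    band: tuple[float, float] = (0.1e6, 6.0e6),
    motion_threshold: float = 0.90,
) -> MultispectralStack:
    """Quantitative per-wavelength pipeline.

    Per wavelength: band-pass -> motion-frame rejection -> average of kept
    frames -> dual-speed universal back-projection -> Bessel fluence
    correction.  The resulting stack keeps spectral linearity and is the
    input to unmixing; display enhancement is deliberately not applied here.
    """
    if not frames_per_wavelength:
        raise ValueError("no wavelengths supplied")
    any_set = next(iter(frames_per_wavelength.values()))
    config = any_set.config
    expected = [float(w) for w in config.wavelengths]
    missing = [w for w in expected if w not in {float(k) for k in frames_per_wavelength}]
    if missing:
        raise ValueError(f"missing wavelengths: {missing}")
    if c_water is None:
        c_water = config.water_sos
    travel = dual_sos_travel_times(any_set.geometry, body_mask, grid, c_water, c_tissue)
    images = []
    for lam in expected:
        s = frames_per_wavelength[lam]
        s = bandpass(s, *band)
        if s.n_frames >= 3:
            kept, _ = reject_motion_frames(s, motion_threshold)
        else:
            kept = np.arange(s.n_frames)
        sino = s.data[kept].mean(axis=0)
        img = backproject_dual_sos(
            sino,
            body_mask,
            c_water,
            c_tissue,
            grid,
            config=config,
            geometry=s.geometry,
            travel_times=travel,
        )
        img = correct_fluence(img, body_mask, mu_eff)
        images.append(img.pixels)
    return MultispectralStack(
        images=np.stack(images),
        wavelengths=np.asarray(expected),
        pixel_size=grid.pixel_size,
        body_mask=body_mask.astype(bool),
        origin=grid.origin,
    )
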