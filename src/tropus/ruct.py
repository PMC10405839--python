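"""Reflection ultrasound computed tomography (pulse-echo on the ring).

Each transmission event is beamformed individually by delay-and-sum over
the contiguous receive aperture centred on the transmitter; the low-
contrast single-view images are compounded by summation over all views,
envelope-detected and log-compressed.  The compounded image delineates the
skin surface, from which the body mask and cross-sectional area follow.
"""

from __future__ import annotations

import numpy as np

from ._rays import MM, element_pixel_distances, transmit_pulse
from .containers import Grid, ReconImage, SignalSet
from .geometry import das_aperture_receivers

__all__ = [
    "das_single",
    "compound",
    "compound_all",
    "auto_body_mask",
    "area_mm2",
    "SegmentationError",
]


class SegmentationError(RuntimeError):
    """Automatic body segmentation found no foreground."""


def _das_view(
    data: np.ndarray,
    dist_mm: np.ndarray,
    elem_dist_mm: np.ndarray,
    tx_index: int,
    receivers: np.ndarray,
    sos: float,
    config,
    mute_guard_mm: float,
) -> np.ndarray:
    """Delay-and-sum one transmission event onto the grid (flat envelope).

    The receive aperture is beamformed coherently on the analytic (Hilbert)
    signal — the echo wavelet is bipolar, so sampling raw RF at the exact
    round-trip delay would hit its zero crossing — and the view's envelope
    is the magnitude of the complex sum.  Pixels whose round-trip path is
    within ``mute_guard_mm`` of the direct tx->rx chord are muted for that
    channel: the direct transmitted wave is not an echo and would otherwise
    paint the chord onto the image.
    """
    from scipy.signal import hilbert

    n_samples = data.shape[-1]
    dt = config.dt
    apod = np.hanning(len(receivers) + 2)[1:-1]
    acc = np.zeros(dist_mm.shape[1], dtype=complex)
    d_tx = dist_mm[tx_index]
    analytic = hilbert(data[tx_index][receivers], axis=-1)
    for w, rx, tr in zip(apod, receivers, analytic):
        path = d_tx + dist_mm[rx]
        keep = path >= elem_dist_mm[tx_index, rx] + mute_guard_mm
        t = path * MM / sos
        s_pos = (t - config.acquisition_delay) / dt
        keep &= (s_pos >= 0) & (s_pos <= n_samples - 2)
        s_pos = np.clip(s_pos, 0, n_samples - 2)
        fl = np.floor(s_pos).astype(np.int64)
        fr = s_pos - fl
        acc += (w * keep) * (tr[fl] * (1 - fr) + tr[fl + 1] * fr)
    return np.abs(acc)


def _default_mute_guard_mm(config, sos: float) -> float:
    """Spatial extent of the transmit wavelet (mm) used for direct-wave muting."""
    return 2.0 * transmit_pulse(config).envelope_fwhm * sos * 1e3


def das_single(
    signals: SignalSet,
    tx_index: int,
    grid: Grid,
    sos: float,
    aperture_deg: float = 90.0,
    dist_mm: np.ndarray | None = None,
    mute_guard_mm: float | None = None,
) -> ReconImage:
    """Low-contrast image from a single transmission event.

    Receive channels are the contiguous aperture centred on the transmitter
    (128 channels on a 512-element ring at the default 90 degrees); pixel
    values sum the receiver traces at the two-way delay
    ``(|x_tx - x| + |x - x_rx|)/sos`` with linear trace interpolation and
    Hann receive apodization, and the view is envelope-detected (magnitude
    of the analytic beamformed signal).
    """
    if signals.mode != "sta":
        raise ValueError("das_single requires an STA SignalSet")
    receivers = das_aperture_receivers(signals.geometry, tx_index, aperture_deg)
    if dist_mm is None:
        dist_mm = element_pixel_distances(signals.geometry, grid)
    if mute_guard_mm is None:
        mute_guard_mm = _default_mute_guard_mm(signals.config, sos)
    pos = signals.geometry.element_positions
    elem_dist = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
    img = _das_view(
        np.asarray(signals.data, dtype=float),
        dist_mm,
        elem_dist,
        tx_index,
        receivers,
        sos,
        signals.config,
        mute_guard_mm,
    )
    return ReconImage(
        pixels=img.reshape(grid.shape),
        pixel_size=grid.pixel_size,
        origin=grid.origin,
        mode="ruct",
        units="a.u.",
    )


def compound(
    low_contrast_images: list[ReconImage],
    dynamic_range_db: float = 40.0,
    log_compress: bool = True,
) -> ReconImage:
    """Sum single-view envelope images, optionally log-compress.

    The linear stage is the plain pixel-wise sum of all views (the views
    are already envelope-detected, so summation compounds them
    incoherently); the absolute value of the sum is then mapped to dB
    relative to its maximum and floored at ``-dynamic_range_db``.
    ``log_compress=False`` returns the linear envelope instead.
    """
    if not low_contrast_images:
        raise ValueError("no images to compound")
    ref = low_contrast_images[0]
    acc = np.zeros_like(ref.pixels)
    for im in low_contrast_images:
        if im.pixels.shape != ref.pixels.shape or im.pixel_size != ref.pixel_size:
            raise ValueError("all images must share the same grid")
        acc = acc + im.pixels
    env = np.abs(acc)
    if not log_compress:
        return ReconImage(
            pixels=env, pixel_size=ref.pixel_size, origin=ref.origin, mode="ruct", units="a.u."
        )
    peak = env.max()
    if peak <= 0:
        db = np.full_like(env, -dynamic_range_db)
    else:
        with np.errstate(divide="ignore"):
            db = 20.0 * np.log10(env / peak)
        db = np.maximum(db, -dynamic_range_db)
    return ReconImage(
        pixels=db, pixel_size=ref.pixel_size, origin=ref.origin, mode="ruct", units="a.u."
    )


def compound_all(
    signals: SignalSet,
    grid: Grid,
    sos: float | None = None,
    aperture_deg: float = 90.0,
    dynamic_range_db: float = 40.0,
) -> ReconImage:
    """Full multi-view compounded RUCT image (all transmission events).

    Equivalent to compounding :func:`das_single` over every transmitter but
    with the element-pixel distance table computed once.
    """
    if signals.mode != "sta":
        raise ValueError("compound_all requires an STA SignalSet")
    if sos is None:
        sos = signals.config.water_sos
    dist_mm = element_pixel_distances(signals.geometry, grid)
    pos = signals.geometry.element_positions
    elem_dist = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
    guard = _default_mute_guard_mm(signals.config, sos)
    data = np.asarray(signals.data, dtype=float)
    acc = np.zeros(grid.ny * grid.nx)
    for tx in range(signals.geometry.n_elements):
        receivers = das_aperture_receivers(signals.geometry, tx, aperture_deg)
        acc += _das_view(
            data, dist_mm, elem_dist, tx, receivers, sos, signals.config, guard
        )
    env = np.abs(acc)
    peak = env.max()
    if peak <= 0:
        db = np.full_like(env, -dynamic_range_db)
    else:
        with np.errstate(divide="ignore"):
            db = 20.0 * np.log10(env / peak)
        db = np.maximum(db, -dynamic_range_db)
    return ReconImage(
        pixels=db.reshape(grid.shape),
        pixel_size=grid.pixel_size,
        origin=grid.origin,
        mode="ruct",
        units="a.u.",
    )


def auto_body_mask(
    ruct: ReconImage, edge_erosion_mm: float = 0.0, closing_radius_mm: float = 0.5
) -> np.ndarray:
    """Segment the body from a log-compressed RUCT image.

    Otsu threshold -> morphological closing (0.5 mm disk) -> largest
    connected component -> hole filling.  The threshold is computed on the
    linear envelope (the dB image mapped back through ``10**(dB/20)``):
    log compression flattens the histogram separation between the bright
    skin rim/tissue speckle and the water sidelobe halo, which makes Otsu
    on the dB values unreliable.  ``edge_erosion_mm`` optionally shrinks
    the filled mask to compensate the systematic outward bias of
    threshold segmentation (half the lateral point-spread width; see the
    calibration helper in the pipeline module).
    """
    from scipy import ndimage
    from skimage import filters, morphology

    px = ruct.pixels
    finite = px[np.isfinite(px)]
    if finite.size == 0 or finite.max() - finite.min() < 1e-9:
        raise SegmentationError("RUCT image has no contrast to segment")
    lin = 10.0 ** (np.nan_to_num(px, nan=px[np.isfinite(px)].min()) / 20.0)
    # clip isolated hot spots so a single bright reflector cannot dominate
    # the histogram normalisation
    lin = np.minimum(lin, np.percentile(lin, 99.5))
    thr = filters.threshold_otsu(lin[np.isfinite(px)])
    fg = lin > thr
    if not fg.any():
        raise SegmentationError("no foreground above the Otsu threshold")
    r_close = max(int(round(closing_radius_mm / ruct.pixel_size)), 1)
    fg = morphology.closing(fg, morphology.disk(r_close))
    labels, n = ndimage.label(fg)
    if n == 0:
        raise SegmentationError("no connected foreground component")
    sizes = ndimage.sum(fg, labels, index=np.arange(1, n + 1))
    fg = labels == (1 + np.argmax(sizes))
    fg = ndimage.binary_fill_holes(fg)
    if edge_erosion_mm > 0:
        # distance-transform erosion supports sub-pixel radii on average
        fg = ndimage.distance_transform_edt(fg) * ruct.pixel_size > edge_erosion_mm
    if not fg.any():
        raise SegmentationError("segmentation produced an empty mask")
    return fg


def area_mm2(mask: np.ndarray, pixel_size: float) -> float:
    """Cross-sectional area of a binary mask: pixel count times pixel area."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return float(mask.sum()) * pixel_size**2
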