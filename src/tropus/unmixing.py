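"""Linear spectral unmixing and liver lipid quantification.

Each in-mask pixel spectrum ``s`` (one value per excitation wavelength) is
decomposed as ``s = A c`` with ``A`` the wavelengths-by-4 matrix of
chromophore absorption spectra (Hb, HbO2, melanin, lipid) and ``c`` the
non-negative per-pixel concentrations, solved per pixel by (non-negative)
least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .msot import MultispectralStack
from .spectra import CHROMOPHORES, ChromophoreSpectraLibrary

__all__ = [
    "ChromophoreMaps",
    "unmix_linear",
    "roi_spectrum",
    "lipid_metric",
    "melanin_saturated",
    "IdentifiabilityError",
]


class IdentifiabilityError(ValueError):
    """The spectra matrix is (numerically) rank deficient."""


@dataclass
class ChromophoreMaps:
    """Unmixed concentration maps ``(4, ny, nx)`` in (Hb, HbO2, melanin,
    lipid) order plus the per-pixel residual norm of the fit."""

    maps: np.ndarray
    residual: np.ndarray
    body_mask: np.ndarray
    pixel_size: float

    def map_for(self, name: str) -> np.ndarray:
        return self.maps[CHROMOPHORES.index(name)]


def _check_rank(A: np.ndarray) -> None:
    svals = np.linalg.svd(A, compute_uv=False)
    if svals[-1] < 1e-10 * svals[0]:
        # Name the most collinear chromophore pair in the error.
        An = A / np.linalg.norm(A, axis=0, keepdims=True)
        gram = np.abs(An.T @ An)
        np.fill_diagonal(gram, 0.0)
        i, j = np.unravel_index(np.argmax(gram), gram.shape)
        raise IdentifiabilityError(
            f"spectra matrix is rank deficient; chromophores "
            f"'{CHROMOPHORES[i]}' and '{CHROMOPHORES[j]}' are collinear "
            f"on this wavelength grid"
        )


def unmix_linear(
    stack: MultispectralStack,
    spectra: ChromophoreSpectraLibrary,
    nonneg: bool = True,
) -> ChromophoreMaps:
    """Per-pixel least-squares chromophore separation.

    Solves ``min ||A c - s||^2`` over the concentrations of every pixel in
    the stack's body mask; ``nonneg=True`` (default — concentrations are
    physical) constrains ``c >= 0``.  Pixels outside the mask are zero.
    """
    n_wl = stack.wavelengths.size
    if n_wl < len(CHROMOPHORES):
        raise ValueError("need at least 4 wavelengths to separate 4 chromophores")
    A = spectra.resample(stack.wavelengths)
    _check_rank(A)
    ny, nx = stack.images.shape[1:]
    S = stack.images.reshape(n_wl, -1)
    mask = stack.body_mask.ravel()
    maps = np.zeros((len(CHROMOPHORES), ny * nx))
    residual = np.zeros(ny * nx)
    cols = np.nonzero(mask)[0]
    if nonneg:
        for j in cols:
            c, rnorm = nnls(A, S[:, j])
            maps[:, j] = c
            residual[j] = rnorm
    else:
        sol, *_ = np.linalg.lstsq(A, S[:, cols], rcond=None)
        maps[:, cols] = sol
        residual[cols] = np.linalg.norm(S[:, cols] - A @ sol, axis=0)
    return ChromophoreMaps(
        maps=maps.reshape(len(CHROMOPHORES), ny, nx),
        residual=residual.reshape(ny, nx),
        body_mask=stack.body_mask,
        pixel_size=stack.pixel_size,
    )


def roi_spectrum(stack: MultispectralStack, roi_mask: np.ndarray) -> np.ndarray:
    """Mean stack value over an ROI per wavelength."""
    roi = np.asarray(roi_mask, dtype=bool)
    if roi.shape != stack.body_mask.shape:
        raise ValueError("roi_mask grid mismatch")
    if not roi.any():
        raise ValueError("empty ROI")
    return stack.images[:, roi].mean(axis=1)


def lipid_metric(maps: ChromophoreMaps, liver_mask: np.ndarray) -> float:
    """Background-removed mean liver lipid signal (a.u.).

    The non-distinct absorption background is estimated as the median lipid
    value over the body outside the liver; the metric is the liver-mean
    lipid minus that background, floored at zero.
    """
    liver = np.asarray(liver_mask, dtype=bool)
    if not liver.any():
        raise ValueError("empty liver mask")
    bg_region = maps.body_mask & ~liver
    if not bg_region.any():
        raise ValueError("liver mask covers the whole body; background undefined")
    lipid = maps.map_for("lipid")
    background = float(np.median(lipid[bg_region]))
    return max(float(lipid[liver].mean()) - background, 0.0)


def melanin_saturated(
    maps: ChromophoreMaps, level: float, quantile: float = 0.99
) -> bool:
    """Quality-control flag: skin-pigmentation saturation of the melanin map.

    A section is flagged (and excluded from group statistics) when the
    in-body melanin map's ``quantile`` value exceeds ``level`` — mirroring
    the exclusion of heavily pigmented animals whose melanin channel
    saturates.
    """
    mel = maps.map_for("melanin")[maps.body_mask]
    if mel.size == 0:
        return False
    return bool(np.quantile(mel, quantile) > level)
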