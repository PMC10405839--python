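"""In-memory containers shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import AcquisitionConfig, RingGeometry

__all__ = ["Grid", "SignalSet", "ReconImage", "SOS_BOUNDS"]

#: Physiologically plausible speed-of-sound range for soft tissue/water (m/s).
SOS_BOUNDS = (1300.0, 1700.0)


@dataclass(frozen=True)
class Grid:
    """Square-pixel 2D reconstruction lattice.

    ``pixels[iy, ix]`` sits at physical position
    ``(origin[0] + ix * pixel_size, origin[1] + iy * pixel_size)`` in mm.
    """

    nx: int
    ny: int
    pixel_size: float
    origin: tuple[float, float]

    def __post_init__(self) -> None:
        if self.nx <= 0 or self.ny <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @classmethod
    def centered(cls, n: int, pixel_size: float) -> "Grid":
        """n-by-n grid centred on the ring origin."""
        half = (n - 1) / 2.0 * pixel_size
        return cls(nx=n, ny=n, pixel_size=pixel_size, origin=(-half, -half))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def x(self) -> np.ndarray:
        """Pixel-centre x coordinates (mm)."""
        return self.origin[0] + np.arange(self.nx) * self.pixel_size

    @property
    def y(self) -> np.ndarray:
        """Pixel-centre y coordinates (mm)."""
        return self.origin[1] + np.arange(self.ny) * self.pixel_size

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x, self.y)

    def pixel_coords(self) -> np.ndarray:
        """``(ny*nx, 2)`` array of pixel-centre (x, y) coordinates in mm."""
        xx, yy = self.meshgrid()
        return np.column_stack([xx.ravel(), yy.ravel()])


@dataclass
class SignalSet:
    """Time-resolved per-element records of one acquisition.

    ``data`` is ``(n_frames_or_tx, n_elements, n_samples)``.  For ``mode="sta"``
    the first axis enumerates transmission events and must have length
    ``n_elements`` (the full synthetic-transmit-aperture block); for
    ``mode="msot"`` it enumerates repeated laser shots at one wavelength.
    """

    mode: str
    data: np.ndarray
    config: AcquisitionConfig
    geometry: RingGeometry
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("msot", "sta"):
            raise ValueError(f"unknown mode {self.mode!r}")
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError("data must be (frame_or_tx, element, sample)")
        if data.shape[1] != self.geometry.n_elements:
            raise ValueError("element axis must match geometry.n_elements")
        if data.shape[2] != self.config.n_samples:
            raise ValueError("sample axis must match config.n_samples")
        if self.mode == "sta" and data.shape[0] != self.geometry.n_elements:
            raise ValueError("sta blocks need one frame per transmitting element")
        self.data = data

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass
class ReconImage:
    """2D reconstructed image with physical pixel geometry.

    ``mode`` tags the product ("msot", "ruct", "sos" or "chromophore");
    ``units`` is "m/s" for speed-of-sound maps and "a.u." otherwise.
    Speed-of-sound maps must stay within the soft-tissue range.
    """

    pixels: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    mode: str = "msot"
    units: str = "a.u."

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.mode not in ("msot", "ruct", "sos", "chromophore"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "sos":
            finite = px[np.isfinite(px)]
            if finite.size and (finite.min() < SOS_BOUNDS[0] or finite.max() > SOS_BOUNDS[1]):
                raise ValueError(
                    f"speed-of-sound pixels must lie within {SOS_BOUNDS} m/s"
                )
        self.pixels = px

    @property
    def grid(self) -> Grid:
        ny, nx = self.pixels.shape
        return Grid(nx=nx, ny=ny, pixel_size=self.pixel_size, origin=self.origin)
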