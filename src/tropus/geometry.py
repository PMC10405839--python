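"""Ring-array geometry and acquisition configuration.

The imaging system is a circular transducer ring surrounding the sample:
every element can transmit and receive, so the same array serves
optoacoustic (MSOT), pulse-echo (RUCT) and transmission (SoS) imaging.
All physical coordinates are expressed in millimetres, times in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RingGeometry",
    "AcquisitionConfig",
    "make_ring_geometry",
    "opposite_arc_receivers",
    "das_aperture_receivers",
    "full_scale_config",
    "scaled_config",
    "MSOT_WAVELENGTHS_NM",
]

#: Optical excitation grid: 740 to 940 nm in 20 nm steps (11 wavelengths).
MSOT_WAVELENGTHS_NM: tuple[float, ...] = tuple(float(w) for w in range(740, 941, 20))


@dataclass(frozen=True)
class RingGeometry:
    """Positions of the elements of a circular transducer array.

    Element 0 sits on the +x axis and indices increase counter-clockwise.

    Attributes
    ----------
    n_elements:
        Number of transducer elements on the ring.
    radius:
        Ring radius in mm.
    element_angles:
        Angular position of each element in radians, uniformly spaced by
        ``2*pi/n_elements``, strictly increasing from 0.
    element_positions:
        ``(n_elements, 2)`` array of (x, y) coordinates in mm.
    """

    n_elements: int
    radius: float
    element_angles: np.ndarray = field(repr=False)
    element_positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        angles = np.asarray(self.element_angles, dtype=float)
        pos = np.asarray(self.element_positions, dtype=float)
        if angles.shape != (self.n_elements,):
            raise ValueError("element_angles length must equal n_elements")
        step = 2.0 * np.pi / self.n_elements
        if not np.allclose(np.diff(angles), step, rtol=0, atol=1e-12):
            raise ValueError("element angles must be uniformly spaced")
        radii = np.hypot(pos[:, 0], pos[:, 1])
        if not np.allclose(radii, self.radius, rtol=1e-9, atol=0):
            raise ValueError("all element positions must lie on the ring")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Sampling and transducer-band parameters of one acquisition.

    Attributes
    ----------
    sampling_rate:
        DAQ sampling rate in samples/s.
    n_samples:
        Samples per record per element.
    center_frequency:
        Transducer centre frequency in Hz.
    fractional_bandwidth:
        Fractional -6 dB transmit/receive bandwidth (dimensionless).
    wavelengths:
        Optical excitation wavelengths in nm, ascending.
    water_sos:
        Speed of sound of the coupling water in m/s.
    acquisition_delay:
        Time of sample 0 relative to the excitation event, in s.
    """

    sampling_rate: float
    n_samples: int
    center_frequency: float = 5.0e6
    fractional_bandwidth: float = 0.6
    wavelengths: tuple[float, ...] = MSOT_WAVELENGTHS_NM
    water_sos: float = 1523.0
    acquisition_delay: float = 0.0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        wl = tuple(float(w) for w in self.wavelengths)
        if any(b <= a for a, b in zip(wl, wl[1:])):
            raise ValueError("wavelengths must be sorted ascending")
        object.__setattr__(self, "wavelengths", wl)
        upper_edge = self.center_frequency * (1.0 + self.fractional_bandwidth)
        if self.sampling_rate <= 2.0 * upper_edge:
            raise ValueError(
                "sampling_rate must exceed twice the upper band edge "
                f"({2.0 * upper_edge:.3g} Hz)"
            )

    @property
    def dt(self) -> float:
        """Sampling interval in s."""
        return 1.0 / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in s, including the acquisition delay."""
        return self.acquisition_delay + np.arange(self.n_samples) / self.sampling_rate


def make_ring_geometry(n_elements: int, radius: float) -> RingGeometry:
    """Build an ideal uniformly spaced circular array.

    Element ``k`` is placed at angle ``2*pi*k/n_elements`` (counter-clockwise,
    element 0 on the +x axis).

    Parameters
    ----------
    n_elements:
        Number of elements; at least 4.
    radius:
        Ring radius in mm; strictly positive.
    """
    if n_elements < 4:
        raise ValueError("n_elements must be at least 4")
    if radius <= 0:
        raise ValueError("radius must be positive")
    angles = 2.0 * np.pi * np.arange(n_elements) / n_elements
    positions = radius * np.column_stack([np.cos(angles), np.sin(angles)])
    return RingGeometry(
        n_elements=int(n_elements),
        radius=float(radius),
        element_angles=angles,
        element_positions=positions,
    )


def opposite_arc_receivers(
    geometry: RingGeometry, emitter_index: int, half_angle: float = np.pi / 3
) -> np.ndarray:
    """Receivers on the arc diametrically opposite a transmitting element.

    Transmission (speed-of-sound) imaging only uses waves that traverse the
    object, i.e. signals received on the far side of the ring.  The selected
    set contains every element whose angular distance to the point opposite
    the emitter is at most ``half_angle``; by uniform spacing this is
    ``2*floor(n*half_angle/(2*pi)) + 1`` elements.  With the default 60
    degree half-angle a 512-element ring yields 171 receivers per emitter.

    Returns
    -------
    numpy.ndarray
        Sorted receiver indices.
    """
    n = geometry.n_elements
    if not 0 <= emitter_index < n:
        raise ValueError(f"emitter_index {emitter_index} out of range [0, {n})")
    if not 0.0 < half_angle < np.pi / 2:
        raise ValueError("half_angle must lie in (0, pi/2)")
    k = int(np.floor(n * half_angle / (2.0 * np.pi)))
    center = (emitter_index + n // 2) % n
    offsets = np.arange(-k, k + 1)
    return np.sort((center + offsets) % n)


def das_aperture_receivers(
    geometry: RingGeometry, tx_index: int, aperture_deg: float = 90.0
) -> np.ndarray:
    """Contiguous receive aperture centred on the transmitting element.

    Pulse-echo delay-and-sum uses the ``round(n * aperture_deg / 360)``
    neighbouring channels around the transmitter (128 channels for a
    512-element ring at the default 90 degrees).  Even counts are split with
    the extra element on the counter-clockwise side.
    """
    n = geometry.n_elements
    if not 0 <= tx_index < n:
        raise ValueError(f"tx_index {tx_index} out of range [0, {n})")
    if not 0 < aperture_deg <= 360:
        raise ValueError("aperture_deg must lie in (0, 360]")
    count = int(round(n * aperture_deg / 360.0))
    count = max(count, 1)
    left = (count - 1) // 2
    right = count - 1 - left
    offsets = np.arange(-left, right + 1)
    return np.sort((tx_index + offsets) % n)


def full_scale_config(
    n_samples: int = 2030, wavelengths: tuple[float, ...] = MSOT_WAVELENGTHS_NM
) -> AcquisitionConfig:
    """Acquisition parameters of the physical system (40 MS/s, 5 MHz, 60% BW)."""
    return AcquisitionConfig(
        sampling_rate=40.0e6,
        n_samples=n_samples,
        center_frequency=5.0e6,
        fractional_bandwidth=0.6,
        wavelengths=wavelengths,
    )


def scaled_config(
    n_samples: int = 1280, wavelengths: tuple[float, ...] = MSOT_WAVELENGTHS_NM
) -> AcquisitionConfig:
    """Desk-scale acquisition: 20 MS/s sampling, longer 64 us records.

    The reduced rate still oversamples the 8 MHz upper band edge, and the
    longer window guarantees that diametric transmissions across the 80 mm
    ring (~53 us in water) fall inside the record.
    """
    return AcquisitionConfig(
        sampling_rate=20.0e6,
        n_samples=n_samples,
        center_frequency=5.0e6,
        fractional_bandwidth=0.6,
        wavelengths=wavelengths,
    )
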