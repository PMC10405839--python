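"""Near-infrared absorption spectra of the four unmixed chromophores.

Multispectral optoacoustic imaging separates deoxyhemoglobin (Hb),
oxyhemoglobin (HbO2), melanin and lipid by their distinct optical
absorption in the 700-1000 nm window: Hb shows its 757 nm band and exceeds
HbO2 below the ~800 nm isosbestic point, HbO2 dominates beyond it, melanin
decays monotonically with wavelength, and lipid has a distinct absorption
peak at 920 nm — the spectral fingerprint that makes hepatic fat visible.

The packaged library is a synthetic tabulation: smooth parametric curves
shaped after the standard literature compilations of these absorbers
(relative units), not digitized measurement data.  They reproduce the
qualitative features the unmixing relies on and are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["CHROMOPHORES", "ChromophoreSpectraLibrary", "default_spectra"]

#: Canonical chromophore order used throughout the package.
CHROMOPHORES: tuple[str, ...] = ("hb", "hbo2", "melanin", "lipid")


@dataclass(frozen=True)
class ChromophoreSpectraLibrary:
    """Tabulated relative absorption coefficients (a.u./mm) per chromophore.

    ``absorption`` has shape ``(n_wavelengths, 4)`` with columns in
    :data:`CHROMOPHORES` order.
    """

    wavelengths: np.ndarray
    absorption: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorption, dtype=float)
        if ab.shape != (wl.size, len(CHROMOPHORES)):
            raise ValueError("absorption must be (n_wavelengths, 4)")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(ab <= 0):
            raise ValueError("absorption values must be positive")

    def resample(self, wavelengths) -> np.ndarray:
        """Linear-interpolation spectra matrix on a target wavelength grid.

        Returns the ``(len(wavelengths), 4)`` design matrix used both by the
        forward simulator and by the linear unmixing stage.
        """
        wl = np.asarray(wavelengths, dtype=float)
        if wl.min() < self.wavelengths[0] or wl.max() > self.wavelengths[-1]:
            raise ValueError(
                f"wavelengths outside tabulated support "
                f"[{self.wavelengths[0]:g}, {self.wavelengths[-1]:g}] nm"
            )
        return np.column_stack(
            [np.interp(wl, self.wavelengths, self.absorption[:, j]) for j in range(len(CHROMOPHORES))]
        )

    def spectrum(self, name: str) -> np.ndarray:
        """Absorption column of one chromophore."""
        return self.absorption[:, CHROMOPHORES.index(name)]

    def to_csv(self, path) -> None:
        header = "wavelength_nm," + ",".join(CHROMOPHORES)
        np.savetxt(
            path,
            np.column_stack([self.wavelengths, self.absorption]),
            delimiter=",",
            header=header,
            comments="",
        )

    @classmethod
    def from_csv(cls, path) -> "ChromophoreSpectraLibrary":
        """Read a spectra table (columns: wavelength_nm, hb, hbo2, melanin, lipid)."""
        path = Path(path)
        with open(path) as fh:
            names = [c.strip() for c in fh.readline().split(",")]
        expected = ["wavelength_nm", *CHROMOPHORES]
        if names != expected:
            raise ValueError(f"spectra CSV must have columns {expected}, got {names}")
        table = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(wavelengths=table[:, 0], absorption=table[:, 1:])


def default_spectra() -> ChromophoreSpectraLibrary:
    """Packaged chromophore library on a 1 nm grid over 700-1000 nm.

    Parametric synthetic spectra (relative units):

    * Hb: decaying NIR tail with a gentle 757 nm shoulder; exceeds HbO2
      at 740 nm and decreases monotonically across the acquisition band.
    * HbO2: sigmoidal rise through the ~800 nm isosbestic crossing; exceeds
      Hb at 900 nm.
    * melanin: power-law decay, strictly decreasing with wavelength.
    * lipid: low plateau with a weak 760 nm shoulder and the dominant
      920 nm peak (global maximum of the band).
    """
    wl = np.arange(700.0, 1000.0 + 1e-9, 1.0)
    hb = 0.40 + 1.30 * np.exp(-(wl - 700.0) / 130.0) + 0.15 * np.exp(-(((wl - 757.0) / 35.0) ** 2))
    hbo2 = 0.27 + 0.95 / (1.0 + np.exp(-(wl - 800.0) / 45.0))
    melanin = 3.0 * (wl / 700.0) ** -3.5
    lipid = (
        0.06
        + 0.18 * np.exp(-(((wl - 760.0) / 40.0) ** 2))
        + 1.00 * np.exp(-(((wl - 920.0) / 25.0) ** 2))
    )
    absorption = np.column_stack([hb, hbo2, melanin, lipid])
    return ChromophoreSpectraLibrary(wavelengths=wl, absorption=absorption)
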