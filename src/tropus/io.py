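"""File I/O: HDF5 signal containers, TIFF image export, YAML configs.

One HDF5 file stores one acquisition: a ``/geometry`` and ``/config`` group
shared by all modes, MSOT frames per wavelength under ``/msot/<nm>``, and the
synthetic-transmit-aperture block under ``/sta``.  All writes are lossless:
a write followed by a read reproduces arrays bit-exactly.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import h5py
import numpy as np
import tifffile
import yaml

from .containers import ReconImage, SignalSet
from .geometry import AcquisitionConfig, RingGeometry, make_ring_geometry

__all__ = [
    "SignalFormatError",
    "write_signals",
    "read_signals",
    "read_acquisition",
    "write_phantom_truth",
    "read_phantom_truth",
    "export_image",
    "import_image",
    "export_stack",
    "import_stack",
    "save_config",
    "load_config",
]

_CONFIG_ATTRS = (
    "sampling_rate",
    "n_samples",
    "center_frequency",
    "fractional_bandwidth",
    "water_sos",
    "acquisition_delay",
)


class SignalFormatError(ValueError):
    """A signal container is missing a required group, dataset or attribute."""


def _write_header(f: h5py.File, config: AcquisitionConfig, geometry: RingGeometry) -> None:
    geo = f.require_group("geometry")
    geo.attrs["n_elements"] = geometry.n_elements
    geo.attrs["radius_mm"] = geometry.radius
    cfg = f.require_group("config")
    for name in _CONFIG_ATTRS:
        cfg.attrs[name] = getattr(config, name)
    if "wavelengths_nm" in cfg:
        del cfg["wavelengths_nm"]
    cfg.create_dataset("wavelengths_nm", data=np.asarray(config.wavelengths, dtype=float))
    cfg.attrs["time_units"] = "s"
    geo.attrs["length_units"] = "mm"


def _read_header(f: h5py.File) -> tuple[AcquisitionConfig, RingGeometry]:
    for group in ("geometry", "config"):
        if group not in f:
            raise SignalFormatError(f"missing group '{group}'")
    geo = f["geometry"]
    cfg = f["config"]
    for attr in ("n_elements", "radius_mm"):
        if attr not in geo.attrs:
            raise SignalFormatError(f"missing geometry attribute '{attr}'")
    kwargs = {}
    for name in _CONFIG_ATTRS:
        if name not in cfg.attrs:
            raise SignalFormatError(f"missing config attribute '{name}'")
        kwargs[name] = cfg.attrs[name]
    if "wavelengths_nm" not in cfg:
        raise SignalFormatError("missing config dataset 'wavelengths_nm'")
    kwargs["n_samples"] = int(kwargs["n_samples"])
    config = AcquisitionConfig(wavelengths=tuple(cfg["wavelengths_nm"][()]), **kwargs)
    geometry = make_ring_geometry(int(geo.attrs["n_elements"]), float(geo.attrs["radius_mm"]))
    return config, geometry


def write_signals(signals: SignalSet | Iterable[SignalSet], path) -> None:
    """Write one or several :class:`SignalSet` objects to one HDF5 container.

    All sets must share geometry and config.  MSOT sets are stored under
    ``/msot/<wavelength_nm>``, the STA block under ``/sta``.
    """
    sets = [signals] if isinstance(signals, SignalSet) else list(signals)
    if not sets:
        raise ValueError("nothing to write")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        _write_header(f, sets[0].config, sets[0].geometry)
        for s in sets:
            if s.mode == "sta":
                ds = f.create_dataset("sta", data=s.data)
            else:
                if s.wavelength_nm is None:
                    raise ValueError("msot SignalSet needs wavelength_nm for storage")
                grp = f.require_group("msot")
                ds = grp.create_dataset(f"{s.wavelength_nm:g}", data=s.data)
                ds.attrs["wavelength_nm"] = float(s.wavelength_nm)
            ds.attrs["mode"] = s.mode
            ds.attrs["units"] = "a.u."


def read_signals(path, mode: str = "sta", wavelength_nm: float | None = None) -> SignalSet:
    """Read one :class:`SignalSet` from an HDF5 container.

    Parameters
    ----------
    mode:
        "sta" for the transmit-aperture block, "msot" for one wavelength.
    wavelength_nm:
        Required for ``mode="msot"``.
    """
    with h5py.File(path, "r") as f:
        config, geometry = _read_header(f)
        if mode == "sta":
            if "sta" not in f:
                raise SignalFormatError("missing dataset 'sta'")
            data = f["sta"][()]
            return SignalSet(mode="sta", data=data, config=config, geometry=geometry)
        if mode == "msot":
            if wavelength_nm is None:
                raise ValueError("wavelength_nm required for msot reads")
            key = f"msot/{wavelength_nm:g}"
            if key not in f:
                raise SignalFormatError(f"missing dataset '{key}'")
            data = f[key][()]
            return SignalSet(
                mode="msot",
                data=data,
                config=config,
                geometry=geometry,
                wavelength_nm=float(wavelength_nm),
            )
    raise ValueError(f"unknown mode {mode!r}")


def read_acquisition(path) -> dict:
    """Read everything in a container.

    Returns a dict with keys ``config``, ``geometry``, optionally ``sta``
    (a SignalSet) and ``msot`` (mapping wavelength -> SignalSet).
    """
    out: dict = {}
    with h5py.File(path, "r") as f:
        config, geometry = _read_header(f)
        out["config"] = config
        out["geometry"] = geometry
        if "sta" in f:
            out["sta"] = SignalSet(
                mode="sta", data=f["sta"][()], config=config, geometry=geometry
            )
        if "msot" in f:
            msot = {}
            for key in sorted(f["msot"], key=float):
                msot[float(key)] = SignalSet(
                    mode="msot",
                    data=f[f"msot/{key}"][()],
                    config=config,
                    geometry=geometry,
                    wavelength_nm=float(key),
                )
            out["msot"] = msot
    return out


def write_phantom_truth(path, phantom) -> None:
    """Append the generating ground truth of a section to its container.

    Stores the speed-of-sound map, masks, chromophore concentrations,
    scatterers and grid geometry under ``/truth`` so reconstructions can be
    validated (or masks reused) without regenerating the phantom.
    """
    with h5py.File(path, "a") as f:
        if "truth" in f:
            del f["truth"]
        g = f.create_group("truth")
        g.create_dataset("sos_map", data=phantom.sos_map)
        g.create_dataset("body_mask", data=phantom.body_mask)
        g.create_dataset("liver_mask", data=phantom.liver_mask)
        g.create_dataset("concentration_maps", data=phantom.concentration_maps)
        g.create_dataset("scatterers", data=phantom.scatterers)
        g.create_dataset("vessels", data=phantom.vessels)
        g.attrs["pixel_size_mm"] = phantom.grid.pixel_size
        g.attrs["origin_mm"] = phantom.grid.origin
        g.attrs["water_sos"] = phantom.water_sos
        g.attrs["liver_sos"] = phantom.liver_sos


def read_phantom_truth(path):
    """Read the ``/truth`` group back into a :class:`~tropus.phantoms.Phantom`."""
    from .containers import Grid
    from .phantoms import Phantom

    with h5py.File(path, "r") as f:
        if "truth" not in f:
            raise SignalFormatError("missing group 'truth'")
        g = f["truth"]
        sos = g["sos_map"][()]
        grid = Grid(
            nx=sos.shape[1],
            ny=sos.shape[0],
            pixel_size=float(g.attrs["pixel_size_mm"]),
            origin=tuple(g.attrs["origin_mm"]),
        )
        return Phantom(
            grid=grid,
            sos_map=sos,
            concentration_maps=g["concentration_maps"][()],
            scatterers=g["scatterers"][()],
            body_mask=g["body_mask"][()].astype(bool),
            liver_mask=g["liver_mask"][()].astype(bool),
            water_sos=float(g.attrs["water_sos"]),
            vessels=g["vessels"][()],
            liver_sos=float(g.attrs["liver_sos"]),
        )


def export_image(image: ReconImage, path) -> Path:
    """Export a reconstruction as 32-bit float TIFF plus a CSV sidecar.

    The TIFF resolution tag records the pixel size; the sidecar
    (``<stem>.csv``) carries mode, units, pixel size and origin so the image
    can be re-imported without loss of provenance.  NaN background pixels
    survive the round trip.
    """
    px = np.asarray(image.pixels)
    if px.ndim != 2:
        raise ValueError("export_image requires a 2D image")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # TIFF resolution is pixels per unit; record pixels per cm.
    ppcm = 10.0 / image.pixel_size
    tifffile.imwrite(
        path,
        px.astype(np.float32),
        resolution=(ppcm, ppcm),
        resolutionunit="CENTIMETER",
    )
    sidecar = path.with_suffix(".csv")
    with open(sidecar, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["key", "value"])
        w.writerow(["mode", image.mode])
        w.writerow(["units", image.units])
        w.writerow(["pixel_size_mm", repr(float(image.pixel_size))])
        w.writerow(["origin_x_mm", repr(float(image.origin[0]))])
        w.writerow(["origin_y_mm", repr(float(image.origin[1]))])
    return sidecar


def import_image(path) -> ReconImage:
    """Re-import a TIFF + CSV sidecar written by :func:`export_image`."""
    path = Path(path)
    pixels = tifffile.imread(path)
    sidecar = path.with_suffix(".csv")
    meta = {}
    with open(sidecar, newline="") as fh:
        for row in csv.DictReader(fh):
            meta[row["key"]] = row["value"]
    return ReconImage(
        pixels=np.asarray(pixels, dtype=float),
        pixel_size=float(meta["pixel_size_mm"]),
        origin=(float(meta["origin_x_mm"]), float(meta["origin_y_mm"])),
        mode=meta["mode"],
        units=meta["units"],
    )


def export_stack(stack, path) -> Path:
    """Export a multispectral stack as a multi-page float32 TIFF + sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path, np.asarray(stack.images, dtype=np.float32), photometric="minisblack"
    )
    sidecar = path.with_suffix(".csv")
    with open(sidecar, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["key", "value"])
        w.writerow(["pixel_size_mm", repr(float(stack.pixel_size))])
        w.writerow(["origin_x_mm", repr(float(stack.origin[0]))])
        w.writerow(["origin_y_mm", repr(float(stack.origin[1]))])
        w.writerow(["wavelengths_nm", ";".join(f"{x:g}" for x in stack.wavelengths)])
    mask_path = path.with_name(path.stem + "_mask.tif")
    tifffile.imwrite(mask_path, stack.body_mask.astype(np.uint8))
    return sidecar


def import_stack(path):
    """Re-import a stack written by :func:`export_stack`."""
    from .msot import MultispectralStack

    path = Path(path)
    images = np.asarray(tifffile.imread(path), dtype=float)
    meta = {}
    with open(path.with_suffix(".csv"), newline="") as fh:
        for row in csv.DictReader(fh):
            meta[row["key"]] = row["value"]
    mask = tifffile.imread(path.with_name(path.stem + "_mask.tif")).astype(bool)
    return MultispectralStack(
        images=images,
        wavelengths=np.array([float(x) for x in meta["wavelengths_nm"].split(";")]),
        pixel_size=float(meta["pixel_size_mm"]),
        body_mask=mask,
        origin=(float(meta["origin_x_mm"]), float(meta["origin_y_mm"])),
    )


def save_config(config: AcquisitionConfig, path) -> None:
    """Write an acquisition config as YAML."""
    doc = {name: float(getattr(config, name)) for name in _CONFIG_ATTRS}
    doc["n_samples"] = int(config.n_samples)
    doc["wavelengths_nm"] = [float(w) for w in config.wavelengths]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> AcquisitionConfig:
    """Load an acquisition config from YAML."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    wl = tuple(doc.pop("wavelengths_nm"))
    return AcquisitionConfig(wavelengths=wl, **doc)
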