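"""HDF5 containers and NIfTI export for phantoms, fluence and sensor data."""

from __future__ import annotations

import hashlib
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .acoustics import SensorData, TransducerArray
from .grids import GridSpec
from .phantom import (AcousticMaps, FunctionalMaps, OpticalMaps, Phantom)

__all__ = [
    "save_phantom", "load_phantom", "save_sensor_data", "load_sensor_data",
    "export_nifti", "array_checksum",
]

_FORMAT_VERSION = 1


def array_checksum(*arrays: np.ndarray) -> str:
    """sha256 over the raw bytes of the given arrays (reproducibility log)."""
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


def _write_grid(group: h5py.Group, grid: GridSpec) -> None:
    group.attrs["grid_shape"] = grid.shape
    group.attrs["voxel_size_mm"] = grid.voxel_size
    group.attrs["origin_mm"] = grid.origin
    group.attrs["format_version"] = _FORMAT_VERSION


def _read_grid(group: h5py.Group, path) -> GridSpec:
    try:
        return GridSpec(
            tuple(int(s) for s in group.attrs["grid_shape"]),
            float(group.attrs["voxel_size_mm"]),
            tuple(float(o) for o in group.attrs["origin_mm"]),
        )
    except KeyError as exc:
        raise ValueError(f"{path}: missing grid metadata ({exc}); not a phantom file "
                         f"or written by an incompatible version") from exc


def save_phantom(phantom: Phantom, path, fluence: dict | None = None) -> None:
    """One group per map family; grid metadata as root attributes.

    ``fluence`` optionally maps wavelength -> FluenceVolume, stored under
    ``fluence/<wavelength>``.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        _write_grid(f, phantom.grid)
        f.create_dataset("labels", data=phantom.labels, compression="gzip")
        fg = f.create_group("functional")
        for name in ("so2", "blood_vf", "water_vf", "fat_vf", "melanosome_vf", "thb"):
            fg.create_dataset(name, data=getattr(phantom.functional, name),
                              compression="gzip")
        og = f.create_group("optical")
        for wl in sorted(phantom.optical.mua):
            og.create_dataset(f"mua/{wl:g}", data=phantom.optical.mua[wl],
                              compression="gzip")
            og.create_dataset(f"mus/{wl:g}", data=phantom.optical.mus[wl],
                              compression="gzip")
        og.create_dataset("g", data=phantom.optical.g, compression="gzip")
        og.create_dataset("n", data=phantom.optical.n, compression="gzip")
        ag = f.create_group("acoustic")
        for name in ("c", "rho", "alpha0", "y"):
            ag.create_dataset(name, data=getattr(phantom.acoustic, name),
                              compression="gzip")
        mg = f.create_group("metadata")
        for key in ("density_type", "tumor_location"):
            mg.attrs[key] = phantom.metadata[key]
        for key in ("skin_tone", "seed"):
            mg.attrs[key] = int(phantom.metadata[key])
        import json

        mg.attrs["tissue_draws_json"] = json.dumps(phantom.metadata["tissue_draws"])
        if fluence:
            flg = f.create_group("fluence")
            for wl, fv in sorted(fluence.items()):
                d = flg.create_dataset(f"{wl:g}", data=fv.phi, compression="gzip")
                d.attrs["n_photons"] = fv.n_photons
                d.attrs["seed"] = fv.seed


def load_phantom(path) -> Phantom:
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            grid = _read_grid(f, path)
            labels = f["labels"][()]
            func = FunctionalMaps(*(f[f"functional/{n}"][()] for n in
                                    ("so2", "blood_vf", "water_vf", "fat_vf",
                                     "melanosome_vf", "thb")))
            mua = {float(k): f[f"optical/mua/{k}"][()] for k in f["optical/mua"]}
            mus = {float(k): f[f"optical/mus/{k}"][()] for k in f["optical/mus"]}
            optical = OpticalMaps(mua, mus, f["optical/g"][()], f["optical/n"][()])
            acoustic = AcousticMaps(*(f[f"acoustic/{n}"][()] for n in
                                      ("c", "rho", "alpha0", "y")))
            import json

            md = f["metadata"]
            metadata = {
                "density_type": md.attrs["density_type"],
                "tumor_location": md.attrs["tumor_location"],
                "skin_tone": int(md.attrs["skin_tone"]),
                "seed": int(md.attrs["seed"]),
                "tissue_draws": json.loads(md.attrs["tissue_draws_json"]),
            }
    except OSError as exc:
        raise ValueError(f"{path}: cannot read as HDF5 ({exc})") from exc
    return Phantom(grid, labels, func, optical, acoustic, metadata)


def save_sensor_data(sensors: dict, path, grid: GridSpec | None = None) -> None:
    """Multiwavelength sensor records: ``traces_<wl>[view, element, sample]``."""
    with h5py.File(Path(path), "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        for wl, sd in sorted(sensors.items()):
            d = f.create_dataset(f"traces_{wl:g}", data=sd.records, compression="gzip")
            d.attrs["dt_s"] = sd.dt
            d.attrs["noise_sigma"] = sd.noise_sigma
            d.attrs["sampling_rate_hz"] = sd.array.sampling_rate
            d.attrs["n_samples"] = sd.array.n_samples
            f.create_dataset(f"positions_{wl:g}", data=sd.array.positions)
        if grid is not None:
            _write_grid(f, grid)


def load_sensor_data(path) -> dict:
    out = {}
    try:
        with h5py.File(Path(path), "r") as f:
            for key in f:
                if not key.startswith("traces_"):
                    continue
                wl = float(key.split("_", 1)[1])
                d = f[key]
                array = TransducerArray(
                    f[f"positions_{wl:g}"][()],
                    sampling_rate=float(d.attrs["sampling_rate_hz"]),
                    n_samples=int(d.attrs["n_samples"]),
                )
                out[wl] = SensorData(records=d[()], dt=float(d.attrs["dt_s"]),
                                     array=array,
                                     noise_sigma=float(d.attrs["noise_sigma"]))
    except OSError as exc:
        raise ValueError(f"{path}: cannot read as HDF5 ({exc})") from exc
    return out


def export_nifti(volume: np.ndarray, grid: GridSpec, path) -> None:
    """Single-volume NIfTI export; voxel spacing preserved in the header."""
    affine = np.diag([grid.voxel_size] * 3 + [1.0])
    affine[:3, 3] = grid.origin
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine)
    img.header.set_zooms((grid.voxel_size,) * 3)
    nib.save(img, str(path))
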