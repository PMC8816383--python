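"""Single-file HDF5 container for raw and derived data.

Layout (schema version 1):

    /holograms/data          (angle, y, x)   counts
    /holograms/background    (angle, y, x)   counts
    /holograms/tilts         (angle, 2)      rad/um
    /fluorescence/<channel>  (y, x)          relative
    /brillouin/spectra       (frame, pixel)  counts
    /brillouin/positions     (frame, 2)      um
    /brillouin/calibration/{spectra, shifts}
    /ri/{volume, voxel_size}                 derived
    /brillouin/{shift, linewidth, valid}     derived
    /labels/{image, table}                   derived
    /maps/{density, concentration, modulus, modulus_valid}  derived

Root attributes carry the schema version, acquisition geometry, the
simulation seed and the run configuration.  Every physical dataset carries
a ``units`` attribute; derived datasets carry provenance (source datasets
and parameters) as a JSON attribute.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .geometry import AcquisitionGeometry

__all__ = [
    "SCHEMA_VERSION",
    "MissingGroupError",
    "open_container",
    "create_container",
    "write_dataset",
    "read_geometry",
    "require",
    "units_audit",
]

SCHEMA_VERSION = 1


class MissingGroupError(KeyError):
    """A pipeline stage's prerequisite group is absent from the container."""


class SchemaError(ValueError):
    """The container lacks schema metadata or uses an unsupported version."""


def create_container(path, geometry: AcquisitionGeometry, seed: int | None = None) -> h5py.File:
    """Create a new container and stamp schema + geometry attributes."""
    f = h5py.File(path, "w")
    f.attrs["schema_version"] = SCHEMA_VERSION
    f.attrs["geometry"] = json.dumps(
        {
            "wavelength_nm": geometry.wavelength_nm,
            "n_medium": geometry.n_medium,
            "na_illumination": geometry.na_illumination,
            "na_detection": geometry.na_detection,
            "theta_deg": geometry.theta_deg,
            "pixel_pitch_um": geometry.pixel_pitch_um,
            "axial_pitch_um": geometry.axial_pitch_um,
        }
    )
    if seed is not None:
        f.attrs["seed"] = int(seed)
    return f


def open_container(path, mode: str = "r") -> h5py.File:
    """Open an existing container, validating its schema version."""
    f = h5py.File(path, mode)
    if "schema_version" not in f.attrs:
        f.close()
        raise SchemaError(
            f"{path}: no schema_version attribute; not a container written by "
            "this package (re-export the data through create_container)"
        )
    version = int(f.attrs["schema_version"])
    if version > SCHEMA_VERSION:
        f.close()
        raise SchemaError(f"{path}: schema version {version} is newer than supported ({SCHEMA_VERSION})")
    return f


def read_geometry(f: h5py.File) -> AcquisitionGeometry:
    return AcquisitionGeometry(**json.loads(f.attrs["geometry"]))


def write_dataset(
    f: h5py.File,
    name: str,
    data: np.ndarray,
    units: str,
    sources: list[str] | None = None,
    parameters: dict | None = None,
) -> h5py.Dataset:
    """Write (or overwrite) a dataset with units and optional provenance."""
    if name in f:
        del f[name]
    ds = f.create_dataset(name, data=data)
    ds.attrs["units"] = units
    if sources is not None or parameters is not None:
        ds.attrs["provenance"] = json.dumps(
            {"sources": sources or [], "parameters": parameters or {}}
        )
    return ds


def require(f: h5py.File, *names: str) -> None:
    """Raise :class:`MissingGroupError` unless all datasets/groups exist."""
    for name in names:
        if name not in f:
            raise MissingGroupError(
                f"required group {name!r} missing from {f.filename}; "
                "run the producing stage first"
            )


def units_audit(f: h5py.File) -> list[str]:
    """Return the paths of datasets lacking a ``units`` attribute."""
    offenders: list[str] = []

    def visit(name, obj):
        if isinstance(obj, h5py.Dataset) and "units" not in obj.attrs:
            offenders.append(name)

    f.visititems(visit)
    return offenders
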