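"""Readers and writers for image cubes.

Two container formats:

* **HDF5** (canonical): one dataset ``intensities`` with axes
  ``(t | lambda, y, x)`` and all acquisition metadata stored as attributes.
  Bit-exact, self-describing round trip.
* **Multi-page TIFF** (import/export for microscope stacks): pixel data in
  the TIFF pages, acquisition metadata in a YAML (or JSON) sidecar file.

Axis order is enforced: the leading axis length must equal the metadata
frame/wavelength count, so a permuted stack is rejected rather than
silently misread.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .cubes import (
    AcquisitionMeta,
    CubeFormatError,
    CubeMetadataError,
    ReferenceCube,
    SpectralCube,
    TemporalCube,
)

__all__ = ["read_cube", "write_cube"]

_KIND_TO_CLASS = {
    "temporal": TemporalCube,
    "spectral": SpectralCube,
    "reference": ReferenceCube,
}

_HDF5_SUFFIXES = {".h5", ".hdf5", ".hdf"}
_TIFF_SUFFIXES = {".tif", ".tiff"}


def _sidecar_path(path: Path, meta_path=None) -> Path:
    if meta_path is not None:
        return Path(meta_path)
    for suffix in (".yaml", ".yml", ".json"):
        cand = path.with_suffix(suffix)
        if cand.exists():
            return cand
    raise CubeMetadataError(
        f"no metadata sidecar (.yaml/.yml/.json) found next to {path}"
    )


def _load_sidecar(path: Path) -> dict:
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def read_cube(path, kind: str | None = None, meta_path=None):
    """Read a cube from HDF5 or multi-page TIFF (+ metadata sidecar).

    Parameters
    ----------
    path
        ``.h5``/``.hdf5`` container or ``.tif``/``.tiff`` stack.
    kind
        ``"temporal"``, ``"spectral"`` or ``"reference"``.  Optional for
        HDF5 (stored as an attribute); required for TIFF unless the sidecar
        carries a ``kind`` entry.
    meta_path
        Explicit sidecar path for TIFF input; defaults to ``path`` with a
        ``.yaml``/``.yml``/``.json`` suffix.
    """
    path = Path(path)
    if path.suffix.lower() in _HDF5_SUFFIXES:
        with h5py.File(path, "r") as f:
            if "intensities" not in f:
                raise CubeFormatError(f"{path} lacks an 'intensities' dataset")
            ds = f["intensities"]
            data = ds[()]
            attrs = dict(ds.attrs)
            stored_kind = attrs.pop("kind", None)
            if isinstance(stored_kind, bytes):
                stored_kind = stored_kind.decode()
            provenance = json.loads(attrs.pop("provenance", "{}"))
            meta = AcquisitionMeta.from_dict(
                {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in attrs.items()}
            )
        kind = kind or stored_kind
    elif path.suffix.lower() in _TIFF_SUFFIXES:
        data = tifffile.imread(path)
        sidecar = _load_sidecar(_sidecar_path(path, meta_path))
        if not isinstance(sidecar, dict):
            raise CubeMetadataError(f"sidecar for {path} is not a mapping")
        kind = kind or sidecar.pop("kind", None)
        provenance = sidecar.pop("provenance", {})
        meta = AcquisitionMeta.from_dict(sidecar)
    else:
        raise CubeFormatError(f"unsupported cube container: {path.suffix!r}")

    if kind is None:
        raise CubeMetadataError("cube kind not stored; pass kind= explicitly")
    if kind not in _KIND_TO_CLASS:
        raise CubeMetadataError(f"unknown cube kind {kind!r}")
    return _KIND_TO_CLASS[kind](intensities=data, meta=meta, provenance=provenance)


def write_cube(cube, path, meta_path=None):
    """Write a cube to HDF5 (canonical) or TIFF + metadata sidecar.

    ``read_cube(write_cube(c))`` reproduces intensities bit-exactly and
    metadata exactly for both containers.
    """
    path = Path(path)
    meta_dict = cube.meta.to_dict()
    if path.suffix.lower() in _HDF5_SUFFIXES:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("intensities", data=cube.intensities)
            for key, val in meta_dict.items():
                ds.attrs[key] = val
            ds.attrs["kind"] = cube.kind
            ds.attrs["axes"] = "t_or_lambda,y,x"
            ds.attrs["provenance"] = json.dumps(cube.provenance, default=str)
    elif path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(path, cube.intensities)
        sidecar = dict(meta_dict)
        sidecar["kind"] = cube.kind
        if cube.provenance:
            sidecar["provenance"] = _jsonable(cube.provenance)
        sc_path = Path(meta_path) if meta_path is not None else path.with_suffix(".yaml")
        sc_path.write_text(yaml.safe_dump(sidecar))
    else:
        raise CubeFormatError(f"unsupported cube container: {path.suffix!r}")
    return path


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=str))
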