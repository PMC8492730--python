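"""Reading and writing OCTA / structural volumes.

Two interchange formats are supported:

* multi-page grayscale TIFF, one z-slice per page (via :mod:`tifffile`);
* raw uncompressed 8-bit binary accompanied by a JSON *sidecar* declaring
  ``{shape, axis_order, dtype, lateral_extent_mm, depth_extent_mm}``.

Commercial OCTA exports do not document the raw file's axis order, so the
sidecar makes it explicit: ``shape`` is the on-disk shape and ``axis_order``
is a permutation of ``"zyx"`` naming what each on-disk axis means.  Volumes
are always returned in canonical (z, y, x) order.  16-bit inputs are reduced
to 8-bit by an integer right-shift (with a warning); other dtypes are
rejected.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional, Union

import numpy as np
import tifffile

from .errors import FormatError, GeometryError
from .geometry import ScanGeometry
from .volume import OCTAVolume

SIDECAR_SUFFIX = ".json"
_TIFF_SUFFIXES = {".tif", ".tiff"}


def sidecar_path(path: Union[str, Path]) -> Path:
    path = Path(path)
    return path.with_name(path.name + SIDECAR_SUFFIX)


def _geometry_from(shape_zyx, lateral_mm: float, depth_mm: float) -> ScanGeometry:
    nz, ny, nx = (int(s) for s in shape_zyx)
    return ScanGeometry(
        lateral_extent_mm=float(lateral_mm),
        depth_extent_mm=float(depth_mm),
        n_ascans_x=nx,
        n_ascans_y=ny,
        n_axial_px=nz,
    )


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        warnings.warn(
            "16-bit input rescaled to 8-bit by integer right-shift (>> 8)",
            stacklevel=3,
        )
        return (arr >> 8).astype(np.uint8)
    raise FormatError(f"unsupported dtype {arr.dtype}; expected uint8 or uint16")


def read_volume(
    path: Union[str, Path],
    sidecar: Optional[Union[str, Path, dict]] = None,
    kind: str = "angiographic",
) -> OCTAVolume:
    """Read a volume from TIFF or raw binary into canonical (z, y, x) order.

    A sidecar next to the file (``<name>.json``) is picked up automatically
    when the ``sidecar`` argument is omitted.  For raw input a sidecar is
    mandatory; for TIFF it is optional and only supplies physical extents
    (default 3 x 3 mm).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    meta: Optional[dict] = None
    if sidecar is not None:
        if isinstance(sidecar, dict):
            meta = dict(sidecar)
        else:
            meta = json.loads(Path(sidecar).read_text())
    elif sidecar_path(path).exists():
        meta = json.loads(sidecar_path(path).read_text())

    if path.suffix.lower() in _TIFF_SUFFIXES:
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        arr = _to_uint8(np.asarray(arr))
        lateral = meta.get("lateral_extent_mm", 3.0) if meta else 3.0
        depth = meta.get("depth_extent_mm", 3.0) if meta else 3.0
        geometry = _geometry_from(arr.shape, lateral, depth)
        return OCTAVolume(arr, geometry, kind=kind)

    # raw binary
    if meta is None:
        raise FormatError(
            f"raw input {path} requires a JSON sidecar declaring "
            "shape, axis_order and dtype"
        )
    for key in ("shape", "axis_order", "dtype"):
        if key not in meta:
            raise FormatError(f"sidecar missing required key '{key}'")
    shape = tuple(int(s) for s in meta["shape"])
    axis_order = str(meta["axis_order"]).lower()
    if sorted(axis_order) != ["x", "y", "z"] or len(shape) != 3:
        raise FormatError("axis_order must be a permutation of 'zyx'")
    try:
        dtype = np.dtype(meta["dtype"])
    except TypeError as exc:
        raise FormatError(f"bad dtype in sidecar: {meta['dtype']}") from exc
    if dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
        raise FormatError(f"unsupported dtype {dtype}; expected uint8 or uint16")

    expected = int(np.prod(shape)) * dtype.itemsize
    actual = path.stat().st_size
    if expected != actual:
        raise GeometryError(
            f"file size {actual} bytes inconsistent with declared shape "
            f"{shape} and dtype {dtype} ({expected} bytes)"
        )
    arr = np.fromfile(path, dtype=dtype).reshape(shape)
    # permute on-disk axes into canonical (z, y, x)
    arr = arr.transpose([axis_order.index(c) for c in "zyx"])
    arr = _to_uint8(np.ascontiguousarray(arr))
    geometry = _geometry_from(
        arr.shape,
        meta.get("lateral_extent_mm", 3.0),
        meta.get("depth_extent_mm", 3.0),
    )
    return OCTAVolume(arr, geometry, kind=kind)


def write_volume(
    vol: OCTAVolume, path: Union[str, Path], format: Optional[str] = None
) -> Path:
    """Write a volume as multi-page TIFF or raw binary (+ JSON sidecar).

    ``format`` is "tiff" or "raw"; if omitted it is inferred from the file
    suffix.  Returns the written path.  Raw output always gets a sidecar
    next to it so it can be re-read without ambiguity.
    """
    path = Path(path)
    if format is None:
        format = "tiff" if path.suffix.lower() in _TIFF_SUFFIXES else "raw"
    if format not in ("tiff", "raw"):
        raise FormatError(f"unknown format '{format}'")

    try:
        if format == "tiff":
            tifffile.imwrite(path, vol.voxels, photometric="minisblack")
        else:
            vol.voxels.tofile(path)
            meta = {
                "shape": list(vol.voxels.shape),
                "axis_order": "zyx",
                "dtype": "uint8",
                "lateral_extent_mm": vol.geometry.lateral_extent_mm,
                "depth_extent_mm": vol.geometry.depth_extent_mm,
            }
            sidecar_path(path).write_text(json.dumps(meta, indent=1))
    except OSError as exc:
        raise OSError(f"cannot write volume to {path}: {exc}") from exc
    return path
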