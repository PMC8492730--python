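"""En-face slab projection, 2D binarization, and 2D perfusion density.

The superficial capillary plexus (SCP) and deep vascular complex (DVC) are
taken as fixed-depth slabs below the ILM — SCP spans the first
``scp_depth_um`` micrometres of retina, the DVC the next ``dvc_depth_um`` —
each clipped at the outer retinal boundary.  A slab is collapsed to an
en-face image by a per-column projection (max by default), binarized with a
global threshold (Otsu by default), and the 2D perfusion density is the
percentage of white (vessel) pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

from .errors import ConfigError, DegenerateHistogramError
from .quantify3d import intermeans_level
from .segmentation import RetinaSurfaces
from .volume import OCTAVolume

__all__ = [
    "SlabBounds",
    "EnFaceImage",
    "slab_bounds",
    "enface_project",
    "enface_threshold_level",
    "binarize_enface",
    "perfusion_density_2d",
]

DEFAULT_SCP_DEPTH_UM = 110.0
DEFAULT_DVC_DEPTH_UM = 60.0


@dataclass
class SlabBounds:
    """Per-column half-open axial ranges [lower, upper) of a named slab."""

    name: str
    lower: np.ndarray
    upper: np.ndarray


@dataclass
class EnFaceImage:
    """A 2D 8-bit en-face image plus the slab and operator that made it."""

    image: np.ndarray
    slab: SlabBounds
    operator: str
    empty_columns: int = 0

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.uint8)
        if self.image.ndim != 2:
            raise ConfigError("en-face image must be 2D")


def slab_bounds(
    surfaces: RetinaSurfaces,
    plexus: str,
    scp_depth_um: float = DEFAULT_SCP_DEPTH_UM,
    dvc_depth_um: float = DEFAULT_DVC_DEPTH_UM,
    max_clipped_fraction: float = 0.2,
) -> SlabBounds:
    """Axial ranges of the SCP or DVC slab below the ILM.

    SCP = ``[ilm, ilm + scp_depth)``; DVC = ``[ilm + scp_depth,
    ilm + scp_depth + dvc_depth)``; both clipped at the outer boundary.
    If the requested offsets exceed the retinal thickness at more than
    ``max_clipped_fraction`` of columns, the configuration is rejected.
    """
    if plexus not in ("scp", "dvc"):
        raise ConfigError(f"unknown plexus '{plexus}'")
    if scp_depth_um <= 0 or dvc_depth_um <= 0:
        raise ConfigError("slab depths must be positive")
    pitch = surfaces.geometry.axial_pitch_um
    scp_px = max(1, int(round(scp_depth_um / pitch)))
    dvc_px = max(1, int(round(dvc_depth_um / pitch)))
    ilm, outer = surfaces.ilm_depth, surfaces.outer_depth
    if plexus == "scp":
        lower = ilm
        upper = np.minimum(ilm + scp_px, outer)
        nominal_upper = ilm + scp_px
    else:
        lower = np.minimum(ilm + scp_px, outer)
        upper = np.minimum(ilm + scp_px + dvc_px, outer)
        nominal_upper = ilm + scp_px + dvc_px
    clipped = (nominal_upper > outer).mean()
    if clipped > max_clipped_fraction:
        raise ConfigError(
            f"slab '{plexus}' exceeds retinal thickness at "
            f"{clipped:.0%} of columns"
        )
    return SlabBounds(plexus, lower.copy(), upper.copy())


def enface_project(
    octa: OCTAVolume,
    bounds: SlabBounds,
    operator: str = "max",
    max_empty_fraction: float = 0.2,
) -> EnFaceImage:
    """Collapse a slab to an en-face image by a per-column z projection.

    Bounds are absolute axial indices; the volume's z-offset is honoured.
    Columns whose slab is empty map to 0 and are counted; too many empty
    columns is an error.
    """
    if operator not in ("max", "mean"):
        raise ConfigError(f"unknown projection operator '{operator}'")
    nz = octa.n_z
    lo = np.clip(bounds.lower - octa.z_offset, 0, nz)
    hi = np.clip(bounds.upper - octa.z_offset, 0, nz)
    empty = hi <= lo
    n_empty = int(empty.sum())
    if n_empty > max_empty_fraction * empty.size:
        raise ConfigError(
            f"slab '{bounds.name}' empty at {n_empty} of {empty.size} columns"
        )
    zz = np.arange(nz)[:, None, None]
    inside = (zz >= lo[None]) & (zz < hi[None])
    vox = octa.voxels
    if operator == "max":
        img = np.where(inside, vox, 0).max(axis=0)
    else:
        counts = np.maximum(inside.sum(axis=0), 1)
        img = np.rint(
            np.where(inside, vox, 0).sum(axis=0, dtype=np.float64) / counts
        )
    img = img.astype(np.uint8)
    img[empty] = 0
    return EnFaceImage(img, bounds, operator, empty_columns=n_empty)


def enface_threshold_level(
    img: np.ndarray, method: str = "otsu", k: float = 1.0
) -> float:
    """Global threshold level for an en-face image (white = vessel, > level)."""
    img = np.asarray(img)
    if img.min() == img.max():
        raise DegenerateHistogramError("constant en-face image")
    if method == "otsu":
        return float(threshold_otsu(img))
    if method == "isodata":
        hist = np.bincount(img.ravel(), minlength=256)
        return float(intermeans_level(hist))
    if method == "mean_plus_k_sd":
        return float(img.mean() + k * img.std())
    raise ConfigError(f"unknown en-face binarization method '{method}'")


def binarize_enface(
    img: np.ndarray | EnFaceImage, method: str = "otsu", k: float = 1.0
) -> np.ndarray:
    """Binarize an en-face image; returns a boolean mask (True = vessel)."""
    if isinstance(img, EnFaceImage):
        img = img.image
    level = enface_threshold_level(img, method=method, k=k)
    return np.asarray(img) > level


def perfusion_density_2d(binary: np.ndarray) -> float:
    """Percentage of white (vessel) pixels in a binarized en-face image."""
    binary = np.asarray(binary)
    if binary.dtype != bool:
        raise ConfigError("expected a boolean en-face mask")
    return 100.0 * float(binary.mean())
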