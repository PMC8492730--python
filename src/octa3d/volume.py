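"""In-memory containers for OCTA / structural volumes and binary masks.

Axis convention: all volumes use (z, y, x) with z increasing from the inner
(vitreous) side toward the outer (choroid) side.  Voxel indices are 0-based
and all slab / substack ranges are half-open ``[z0, z1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import GeometryError
from .geometry import ScanGeometry

VOLUME_KINDS = ("angiographic", "structural")


@dataclass
class OCTAVolume:
    """An 8-bit grayscale volume with geometry and axis convention.

    ``z_offset`` records where a substack starts in the full axial grid.
    ``axial_pitch_mm`` overrides the geometry's pitch after axial
    resampling; ``valid_mask`` marks voxels inside the retina after
    per-column masking (None means all voxels are valid).
    """

    voxels: np.ndarray
    geometry: ScanGeometry
    kind: str = "angiographic"
    z_offset: int = 0
    axial_pitch_mm: Optional[float] = None
    valid_mask: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.dtype != np.uint8:
            raise GeometryError(
                f"voxels must be uint8, got {self.voxels.dtype}"
            )
        if self.voxels.ndim != 3:
            raise GeometryError("voxels must be a 3D (z, y, x) array")
        nz, ny, nx = self.voxels.shape
        if (ny, nx) != (self.geometry.n_ascans_y, self.geometry.n_ascans_x):
            raise GeometryError(
                f"lateral shape {(ny, nx)} does not match geometry grid "
                f"{(self.geometry.n_ascans_y, self.geometry.n_ascans_x)}"
            )
        if self.z_offset < 0:
            raise GeometryError("z_offset must be >= 0")
        if self.z_offset == 0 and self.axial_pitch_mm is None:
            if nz != self.geometry.n_axial_px and nz > self.geometry.n_axial_px:
                raise GeometryError(
                    f"axial size {nz} exceeds geometry n_axial_px "
                    f"{self.geometry.n_axial_px}"
                )
        if self.kind not in VOLUME_KINDS:
            raise GeometryError(f"kind must be one of {VOLUME_KINDS}")
        if self.valid_mask is not None:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.voxels.shape:
                raise GeometryError("valid_mask shape must match voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_z(self) -> int:
        return self.voxels.shape[0]

    @property
    def effective_axial_pitch_mm(self) -> float:
        return (
            self.axial_pitch_mm
            if self.axial_pitch_mm is not None
            else self.geometry.axial_pitch_mm
        )

    @property
    def voxel_volume_mm3(self) -> float:
        g = self.geometry
        return (
            g.lateral_pitch_x_mm
            * g.lateral_pitch_y_mm
            * self.effective_axial_pitch_mm
        )

    def with_voxels(self, voxels: np.ndarray) -> "OCTAVolume":
        """Copy of this volume with new voxel data, metadata preserved."""
        return replace(self, voxels=voxels)


@dataclass
class BinaryVolume:
    """A boolean voxel mask with the physical volume of one voxel attached."""

    mask: np.ndarray
    geometry: ScanGeometry
    z_offset: int = 0
    effective_voxel_volume_mm3: float = 0.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise GeometryError("mask must be a 3D (z, y, x) array")
        if self.effective_voxel_volume_mm3 <= 0:
            raise GeometryError("effective_voxel_volume_mm3 must be > 0")

    @property
    def n_true(self) -> int:
        return int(self.mask.sum())
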