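"""Physical scan geometry of a macular OCTA acquisition.

A 3 x 3-mm macular cube is sampled on a lateral grid of A-scans (default
300 x 300) and an axial grid of depth pixels (default 1536 over 3 mm), so the
axial pixel pitch (~1.95 um) is much finer than the lateral pitch (10 um).
Quantifying vascular volume in mm^3 requires carrying these pitches
explicitly; see :func:`octa3d.quantify3d.z_scale_factor` for the anisotropy
correction derived from them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import GeometryError


@dataclass(frozen=True)
class ScanGeometry:
    """Physical extents and grid sizes of a volumetric scan.

    Parameters
    ----------
    lateral_extent_mm : float
        Physical width of the (square) XY scan field, in mm.
    depth_extent_mm : float
        Physical depth covered by the axial (Z) axis, in mm.
    n_ascans_x, n_ascans_y : int
        Lateral grid sizes (A-scans per B-scan, B-scans per cube).
    n_axial_px : int
        Axial pixels per A-scan.
    """

    lateral_extent_mm: float = 3.0
    depth_extent_mm: float = 3.0
    n_ascans_x: int = 300
    n_ascans_y: int = 300
    n_axial_px: int = 1536

    def __post_init__(self) -> None:
        if self.lateral_extent_mm <= 0 or self.depth_extent_mm <= 0:
            raise GeometryError("physical extents must be positive")
        for name in ("n_ascans_x", "n_ascans_y", "n_axial_px"):
            if int(getattr(self, name)) < 2:
                raise GeometryError(f"{name} must be >= 2")

    @property
    def lateral_pitch_x_mm(self) -> float:
        return self.lateral_extent_mm / self.n_ascans_x

    @property
    def lateral_pitch_y_mm(self) -> float:
        return self.lateral_extent_mm / self.n_ascans_y

    @property
    def axial_pitch_mm(self) -> float:
        return self.depth_extent_mm / self.n_axial_px

    @property
    def axial_pitch_um(self) -> float:
        return self.axial_pitch_mm * 1000.0

    @property
    def scan_area_mm2(self) -> float:
        return self.lateral_extent_mm * self.lateral_extent_mm

    @property
    def shape(self) -> tuple[int, int, int]:
        """Canonical voxel array shape, axis order (z, y, x)."""
        return (self.n_axial_px, self.n_ascans_y, self.n_ascans_x)
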