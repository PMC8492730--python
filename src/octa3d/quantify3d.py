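"""The 3D metric core: axial rescaling, global stack thresholding, and the
3D vascular volume / 3D perfusion density metrics.

The quantification follows the volume-rendered OCTA recipe: the retina
substack is resampled along z by the axial-to-lateral pitch ratio so voxels
become (approximately) isotropic, a single global threshold is computed from
the stack histogram by iterative intermeans (the classic "default"/IsoData
threshold), and every voxel strictly brighter than that level counts toward
the 3D vascular volume

    vascular volume [mm^3] = (# suprathreshold voxels) x voxel volume,
    3D perfusion density [%] = 100 x vascular volume / neuroretinal volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .errors import ConfigError, DegenerateHistogramError
from .geometry import ScanGeometry
from .volume import BinaryVolume, OCTAVolume

__all__ = [
    "ThresholdResult",
    "EyeMetrics",
    "z_scale_factor",
    "rescale_z",
    "intermeans_level",
    "default_global_threshold",
    "binarize",
    "vascular_volume_3d",
    "perfusion_density_3d",
]


@dataclass(frozen=True)
class ThresholdResult:
    """A global gray-level threshold plus the histogram it came from.

    Binarization keeps voxels with intensity strictly greater than ``level``.
    """

    level: int
    method: str
    histogram: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not 0 <= self.level <= 254:
            raise ConfigError(f"threshold level {self.level} outside [0, 254]")


@dataclass
class EyeMetrics:
    """Per-eye outputs of the full 2D + 3D quantification."""

    vascular_volume_mm3: float
    perfusion_density_3d_pct: float
    scp_density_2d_pct: float
    dvc_density_2d_pct: float
    mean_thickness_um: float
    macular_volume_mm3: float

    def __post_init__(self) -> None:
        if self.vascular_volume_mm3 < 0:
            raise ConfigError("vascular volume must be >= 0")
        for name in (
            "perfusion_density_3d_pct",
            "scp_density_2d_pct",
            "dvc_density_2d_pct",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ConfigError(f"{name}={v} outside [0, 100]")


def z_scale_factor(geometry: ScanGeometry) -> float:
    """Axial-to-lateral pixel-pitch ratio.

    Resampling the z-axis by this factor makes voxels isotropic at the
    lateral pitch.  For the default 3 x 3-mm geometry (3 mm / 1536 axial
    pixels over 3 mm / 300 A-scans) this is 300/1536 = 0.1953..., i.e. the
    0.195 rescaling number used in practice for such cubes.
    """
    return geometry.axial_pitch_mm / geometry.lateral_pitch_x_mm


def rescale_z(
    vol: OCTAVolume, factor: float, interpolation: str = "linear"
) -> OCTAVolume:
    """Resample the z-dimension to ``round(nz * factor)`` slices.

    The lateral grid is untouched.  The physical depth represented by the
    stack is preserved, so the effective axial pitch becomes
    ``old_pitch * nz / new_nz`` (equal to the lateral pitch when ``factor``
    is :func:`z_scale_factor`).  The retina validity mask, if present, is
    resampled with nearest-neighbour interpolation.
    """
    if not 0 < factor <= 1:
        raise ConfigError(f"rescale factor {factor} outside (0, 1]")
    if interpolation not in ("nearest", "linear"):
        raise ConfigError(f"unknown interpolation '{interpolation}'")
    nz = vol.n_z
    m = int(round(nz * factor))
    if m < 1:
        raise ConfigError(f"rescale factor {factor} yields {m} slices")
    if m == nz:
        return vol.with_voxels(vol.voxels.copy())

    order = 1 if interpolation == "linear" else 0
    zoom = (m / nz, 1.0, 1.0)
    data = ndi.zoom(
        vol.voxels.astype(np.float32), zoom, order=order, mode="nearest",
        grid_mode=True,
    )
    assert data.shape[0] == m, "zoom produced unexpected axial size"
    out = np.clip(np.rint(data), 0, 255).astype(np.uint8)

    valid = None
    if vol.valid_mask is not None:
        valid = (
            ndi.zoom(
                vol.valid_mask.astype(np.uint8), zoom, order=0,
                mode="nearest", grid_mode=True,
            )
            > 0
        )
    new_pitch = vol.effective_axial_pitch_mm * nz / m
    return OCTAVolume(
        out,
        vol.geometry,
        kind=vol.kind,
        z_offset=vol.z_offset,
        axial_pitch_mm=new_pitch,
        valid_mask=valid,
    )


def intermeans_level(histogram: np.ndarray) -> int:
    """Iterative intermeans (IsoData-style) threshold on a 256-bin histogram.

    Starting from the midpoint of the occupied gray range, iterate
    ``t <- floor((mean(<= t) + mean(> t)) / 2)`` to a fixed point.  A cycle
    (possible with floor rounding) terminates at the first revisited level.
    """
    hist = np.asarray(histogram, dtype=np.int64)
    if hist.ndim != 1 or hist.size != 256:
        raise ConfigError("histogram must have 256 bins")
    occupied = np.nonzero(hist)[0]
    if occupied.size == 0:
        raise DegenerateHistogramError("empty histogram")
    lo, hi = int(occupied[0]), int(occupied[-1])
    if lo == hi:
        raise DegenerateHistogramError(
            f"constant data (single occupied gray level {lo})"
        )
    levels = np.arange(256, dtype=np.float64)
    csum = np.cumsum(hist)
    cmoment = np.cumsum(hist * levels)
    total_n, total_m = csum[-1], cmoment[-1]

    t = (lo + hi) // 2
    seen = set()
    while t not in seen:
        seen.add(t)
        n_low = csum[t]
        mean_low = cmoment[t] / n_low
        mean_high = (total_m - cmoment[t]) / (total_n - n_low)
        t_new = int((mean_low + mean_high) // 2)
        if t_new == t:
            break
        t = t_new
    return t


def default_global_threshold(
    vol: OCTAVolume, exclude_masked: bool = True
) -> ThresholdResult:
    """Global intermeans threshold from the stack's histogram.

    When the volume carries a retina validity mask and ``exclude_masked`` is
    true (the default), voxels zeroed by retina masking are dropped from the
    histogram — otherwise the large zero spike would drag the low-class mean
    toward 0 and bias the threshold.
    """
    if vol.valid_mask is not None and exclude_masked:
        values = vol.voxels[vol.valid_mask]
    else:
        values = vol.voxels.ravel()
    hist = np.bincount(values, minlength=256)
    level = intermeans_level(hist)
    return ThresholdResult(level=level, method="intermeans", histogram=hist)


def binarize(vol: OCTAVolume, threshold: ThresholdResult) -> BinaryVolume:
    """Keep voxels with intensity strictly greater than the threshold level.

    Voxels outside the retina validity mask (if any) never enter the mask.
    """
    mask = vol.voxels > threshold.level
    if vol.valid_mask is not None:
        mask &= vol.valid_mask
    return BinaryVolume(
        mask,
        vol.geometry,
        z_offset=vol.z_offset,
        effective_voxel_volume_mm3=vol.voxel_volume_mm3,
    )


def vascular_volume_3d(mask: BinaryVolume) -> float:
    """Physical volume (mm^3) of the suprathreshold voxel set."""
    return mask.n_true * mask.effective_voxel_volume_mm3


def perfusion_density_3d(
    vascular_volume_mm3: float, neuroretinal_volume_mm3: float
) -> float:
    """3D perfusion density (%): vascular volume over neuroretinal volume."""
    if neuroretinal_volume_mm3 <= 0:
        raise ConfigError("neuroretinal volume must be > 0")
    return 100.0 * vascular_volume_mm3 / neuroretinal_volume_mm3
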