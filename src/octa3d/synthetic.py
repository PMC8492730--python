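"""Synthetic structural OCT + OCTA volume pairs with known ground truth.

The study this pipeline targets was run on 3 x 3-mm macular cubes from 70
eyes that are not publicly available, so the generator stands in for the
scanner: it produces a structural volume (bright retina band between an
undulating ILM and outer boundary over dark vitreous/choroid, with
multiplicative gamma speckle), an angiographic volume (bright tube-like
vessels in two plexus slabs — SCP and DVC — over additive gamma background
noise, optionally with decorrelation projection tails), and the exact
ground truth (vessel mask, surfaces, realized per-slab vessel fractions).

Vessels are grown as random-walk centerlines dilated to a tube radius; this
realizes a target volume fraction with vessel-like morphology while keeping
every quantity exactly known.  The per-eye signal strength index (SSI, the
0-10 scan-quality score used clinically as an exclusion gate) maps linearly
to vessel-to-background contrast.

Cohort generation emulates the study design: two groups of 35 subjects, one
randomly selected eye each, with a perfusion deficit confined to the DVC in
the diabetic group and clinical covariates (age, HbA1c, diabetes duration)
drawn from the cohort's published summary statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np

from .errors import ConfigError, FractionError
from .geometry import ScanGeometry
from .segmentation import RetinaSurfaces
from .volume import BinaryVolume, OCTAVolume

__all__ = [
    "SimEyeConfig",
    "GroundTruth",
    "EyeRecord",
    "CohortConfig",
    "SimulatedEye",
    "reduced_geometry",
    "grow_plexus",
    "simulate_eye",
    "inject_projection_tails",
    "simulate_cohort",
    "iter_cohort",
    "planar_vessel_fraction",
]


def reduced_geometry(
    n_lateral: int = 80, n_axial: int = 192,
    lateral_pitch_um: float = 12.0, axial_pitch_um: float = 3.0,
) -> ScanGeometry:
    """A desk-scale scan geometry preserving the full-size pitch anisotropy.

    Useful for tests and simulation studies where processing hundreds of
    full 300 x 300 x 1536 cubes would be wasteful.
    """
    return ScanGeometry(
        lateral_extent_mm=n_lateral * lateral_pitch_um / 1000.0,
        depth_extent_mm=n_axial * axial_pitch_um / 1000.0,
        n_ascans_x=n_lateral,
        n_ascans_y=n_lateral,
        n_axial_px=n_axial,
    )


@dataclass(frozen=True)
class SimEyeConfig:
    """Parameters of one synthetic eye.

    Depth parameters are in micrometres below the ILM; vessel fractions are
    per-slab voxel volume fractions in [0, 0.5]; ``ssi`` is the 0-10 signal
    strength index; ``tail_strength`` in [0, 1] scales projection tails.
    """

    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    ilm_depth_um: float = 200.0
    ilm_undulation_um: float = 15.0
    retina_thickness_um: float = 320.0
    thickness_undulation_um: float = 10.0
    scp_slab_um: tuple[float, float] = (0.0, 110.0)
    dvc_slab_um: tuple[float, float] = (110.0, 170.0)
    target_fraction_scp: float = 0.06
    target_fraction_dvc: float = 0.10
    vessel_radius_um: tuple[float, float] = (10.0, 16.0)
    noise_level: float = 12.0
    tail_strength: float = 0.3
    tail_decay_um: float = 100.0
    ssi: float = 9.0
    seed: int = 0
    vessel_intensity_range: tuple[float, float] = (40.0, 235.0)
    vessel_intensity_sd: float = 30.0
    background_structural: float = 8.0
    retina_intensity: float = 160.0
    speckle_shape: float = 4.0

    def __post_init__(self) -> None:
        for name in ("target_fraction_scp", "target_fraction_dvc"):
            f = getattr(self, name)
            if not 0 <= f <= 0.5:
                raise ConfigError(f"{name}={f} outside [0, 0.5]")
        if not 0 <= self.ssi <= 10:
            raise ConfigError(f"ssi={self.ssi} outside [0, 10]")
        if not 0 <= self.tail_strength <= 1:
            raise ConfigError(f"tail_strength={self.tail_strength} outside [0, 1]")
        for slab in (self.scp_slab_um, self.dvc_slab_um):
            if slab[1] <= slab[0] or slab[0] < 0:
                raise ConfigError(f"bad slab bounds {slab}")
            if slab[1] > self.retina_thickness_um:
                raise ConfigError(
                    f"slab {slab} extends beyond the retina "
                    f"({self.retina_thickness_um} um thick)"
                )
        depth_um = self.geometry.depth_extent_mm * 1000.0
        if self.ilm_depth_um + self.retina_thickness_um >= depth_um:
            raise ConfigError("retina does not fit within the axial range")


@dataclass
class GroundTruth:
    """Exact truth behind a simulated eye (pre-noise, pre-artifact)."""

    vessel_mask: BinaryVolume
    surfaces: RetinaSurfaces
    true_fraction_scp: float
    true_fraction_dvc: float


@dataclass
class EyeRecord:
    """One subject's included eye with clinical covariates and metrics."""

    subject_id: str
    group: str  # "diabetic" | "control"
    age: float
    ssi: float
    laterality: str = "OD"
    hba1c: Optional[float] = None
    diabetes_duration: Optional[float] = None
    metrics: Optional[object] = None  # EyeMetrics, filled by the pipeline

    def __post_init__(self) -> None:
        if self.group not in ("diabetic", "control"):
            raise ConfigError(f"unknown group '{self.group}'")


@dataclass
class SimulatedEye:
    record: EyeRecord
    structural: OCTAVolume
    octa: OCTAVolume
    truth: GroundTruth


# --------------------------------------------------------------------------
# vessel growth

def _ball_offsets(radius_um: float, pitches_um: tuple[float, float, float]):
    """Integer (dz, dy, dx) offsets inside an anisotropic ellipsoid."""
    semi = [max(radius_um / p, 0.0) for p in pitches_um]
    ext = [int(math.floor(s)) for s in semi]
    dz, dy, dx = np.mgrid[
        -ext[0] : ext[0] + 1, -ext[1] : ext[1] + 1, -ext[2] : ext[2] + 1
    ]
    rr = (
        (dz / max(semi[0], 0.5)) ** 2
        + (dy / max(semi[1], 0.5)) ** 2
        + (dx / max(semi[2], 0.5)) ** 2
    )
    sel = rr <= 1.0
    return dz[sel], dy[sel], dx[sel]


def grow_plexus(
    shape: tuple[int, int, int],
    target_fraction: float,
    radius_um: tuple[float, float],
    pitches_um: tuple[float, float, float],
    rng: np.random.Generator,
    z_drift: float = 0.15,
    max_stall_walks: int = 200,
) -> np.ndarray:
    """Grow a tube-like vessel mask of a target volume fraction in a slab.

    Centerlines are persistent random walks (mostly lateral, slight axial
    drift) stamped with an anisotropic ellipsoid of the sampled radius, so
    every vessel voxel is 26-connected to its centerline.  Walks are added
    until the realized fraction reaches the target (within a few percent
    relative); an unreachable target raises :class:`FractionError`.
    """
    if not 0 <= target_fraction <= 0.5:
        raise ConfigError(f"target_fraction={target_fraction} outside [0, 0.5]")
    shape = tuple(int(s) for s in shape)
    if any(s < 1 for s in shape):
        raise ConfigError(f"empty slab shape {shape}")
    mask = np.zeros(shape, dtype=bool)
    if target_fraction == 0:
        return mask

    nzs, nys, nxs = shape
    total = mask.size
    target_vox = target_fraction * total
    box_um = (nzs * pitches_um[0], nys * pitches_um[1], nxs * pitches_um[2])
    step_um = 0.8 * min(pitches_um[1], pitches_um[2])

    gain_per_step = None  # EMA of voxels added per step
    count = 0
    stalled = 0
    while count < 0.98 * target_vox:
        r = rng.uniform(*radius_um)
        offs = _ball_offsets(r, pitches_um)
        est = gain_per_step if gain_per_step else max(1.0, 0.3 * len(offs[0]))
        n_steps = int(np.clip((target_vox - count) / est, 4, 120))

        pos = np.array([rng.uniform(0, b) for b in box_um])
        theta = rng.uniform(0, 2 * np.pi)
        direc = np.array(
            [rng.normal(0, z_drift), math.sin(theta), math.cos(theta)]
        )
        direc /= np.linalg.norm(direc)
        zs, ys, xs = [], [], []
        for _ in range(n_steps):
            pos = pos + step_um * direc
            # reflect at the slab box
            for ax in range(3):
                if pos[ax] < 0:
                    pos[ax] = -pos[ax]
                    direc[ax] = -direc[ax]
                elif pos[ax] >= box_um[ax]:
                    pos[ax] = 2 * box_um[ax] - pos[ax] - 1e-9
                    direc[ax] = -direc[ax]
            jitter = rng.normal(0, 0.15, size=3)
            jitter[0] *= z_drift
            direc = direc + jitter
            direc /= np.linalg.norm(direc)
            zs.append(pos[0] / pitches_um[0])
            ys.append(pos[1] / pitches_um[1])
            xs.append(pos[2] / pitches_um[2])
        cz = np.rint(zs).astype(np.int64)
        cy = np.rint(ys).astype(np.int64)
        cx = np.rint(xs).astype(np.int64)
        vz = (cz[:, None] + offs[0][None]).ravel()
        vy = (cy[:, None] + offs[1][None]).ravel()
        vx = (cx[:, None] + offs[2][None]).ravel()
        ok = (
            (vz >= 0) & (vz < nzs)
            & (vy >= 0) & (vy < nys)
            & (vx >= 0) & (vx < nxs)
        )
        mask[vz[ok], vy[ok], vx[ok]] = True
        new_count = int(mask.sum())
        gained = new_count - count
        if gained <= 0:
            stalled += 1
            if stalled > max_stall_walks:
                raise FractionError(
                    f"target fraction {target_fraction} unreachable: stuck at "
                    f"{count / total:.4f}"
                )
        else:
            stalled = 0
            gain = gained / n_steps
            gain_per_step = (
                gain if gain_per_step is None else 0.5 * gain_per_step + 0.5 * gain
            )
        count = new_count
    return mask


# --------------------------------------------------------------------------
# volume synthesis

def _smooth_field(ny: int, nx: int, rng: np.random.Generator) -> np.ndarray:
    """A smooth lateral field in [-1, 1] (two random low-frequency cosines)."""
    yy, xx = np.mgrid[0:ny, 0:nx]
    f = np.zeros((ny, nx))
    for _ in range(2):
        fy, fx = rng.uniform(0.5, 1.5, size=2)
        py, px = rng.uniform(0, 2 * np.pi, size=2)
        f += np.cos(2 * np.pi * fy * yy / ny + py) * np.cos(
            2 * np.pi * fx * xx / nx + px
        )
    m = np.abs(f).max()
    return f / m if m > 0 else f


def _slab_px(slab_um: tuple[float, float], pitch_um: float) -> tuple[int, int]:
    s0 = int(round(slab_um[0] / pitch_um))
    s1 = max(s0 + 1, int(round(slab_um[1] / pitch_um)))
    return s0, s1


def simulate_eye(
    config: SimEyeConfig,
) -> tuple[OCTAVolume, OCTAVolume, GroundTruth]:
    """Generate one (structural, OCTA, ground-truth) triple.

    Deterministic given ``config`` (including its seed).
    """
    g = config.geometry
    nz, ny, nx = g.shape
    pitch_um = g.axial_pitch_um
    pitches = (pitch_um, g.lateral_pitch_y_mm * 1000, g.lateral_pitch_x_mm * 1000)
    rng = np.random.default_rng(config.seed)

    # surfaces
    ilm_um = config.ilm_depth_um + config.ilm_undulation_um * _smooth_field(
        ny, nx, rng
    )
    thick_um = (
        config.retina_thickness_um
        + config.thickness_undulation_um * _smooth_field(ny, nx, rng)
    )
    ilm_px = np.clip(np.rint(ilm_um / pitch_um).astype(np.int64), 0, nz - 2)
    outer_px = np.clip(
        np.rint((ilm_um + thick_um) / pitch_um).astype(np.int64), ilm_px + 1, nz
    )
    surfaces = RetinaSurfaces(ilm_px, outer_px, g)

    # vessel mask: grow each plexus in a flat slab, then follow the ILM
    vessel = np.zeros((nz, ny, nx), dtype=bool)
    fractions = {}
    for name, slab_um, target in (
        ("scp", config.scp_slab_um, config.target_fraction_scp),
        ("dvc", config.dvc_slab_um, config.target_fraction_dvc),
    ):
        s0, s1 = _slab_px(slab_um, pitch_um)
        slab_nz = s1 - s0
        flat = grow_plexus(
            (slab_nz, ny, nx), target, config.vessel_radius_um, pitches, rng
        )
        zc, yc, xc = np.nonzero(flat)
        zg = zc + s0 + ilm_px[yc, xc]
        ok = zg < nz
        vessel[zg[ok], yc[ok], xc[ok]] = True
        fractions[name] = float(ok.sum()) / flat.size
    voxel_mm3 = g.lateral_pitch_x_mm * g.lateral_pitch_y_mm * g.axial_pitch_mm

    # structural volume: bright retina band with multiplicative speckle
    zz = np.arange(nz)[:, None, None]
    band = (zz >= ilm_px[None]) & (zz < outer_px[None])
    struct = np.where(
        band, config.retina_intensity, config.background_structural
    ).astype(np.float64)
    speckle = rng.gamma(config.speckle_shape, 1.0 / config.speckle_shape, struct.shape)
    struct = np.clip(np.rint(struct * speckle), 0, 255).astype(np.uint8)
    structural = OCTAVolume(struct, g, kind="structural")

    # OCTA volume: additive gamma background + SSI-scaled vessel signal
    lo, hi = config.vessel_intensity_range
    vessel_intensity = lo + (hi - lo) * config.ssi / 10.0
    octa_f = rng.gamma(2.0, config.noise_level / 2.0, (nz, ny, nx))
    nv = int(vessel.sum())
    if nv:
        # capillary decorrelation is heterogeneous: per-voxel spread around
        # the SSI-dependent mean
        octa_f[vessel] = np.maximum(
            octa_f[vessel],
            vessel_intensity + rng.normal(0, config.vessel_intensity_sd, nv),
        )
    octa = OCTAVolume(
        np.clip(np.rint(octa_f), 0, 255).astype(np.uint8), g, kind="angiographic"
    )
    if config.tail_strength > 0 and nv:
        octa = inject_projection_tails(
            octa, vessel, config.tail_strength, config.tail_decay_um
        )

    truth = GroundTruth(
        vessel_mask=BinaryVolume(vessel, g, 0, voxel_mm3),
        surfaces=surfaces,
        true_fraction_scp=fractions["scp"],
        true_fraction_dvc=fractions["dvc"],
    )
    return structural, octa, truth


def inject_projection_tails(
    octa: OCTAVolume,
    vessel_mask: np.ndarray | BinaryVolume,
    tail_strength: float,
    tail_decay_um: float,
) -> OCTAVolume:
    """Add exponential decorrelation tails below every vessel voxel.

    A voxel at axial distance d below a vessel voxel of intensity V gains
    ``tail_strength * V * exp(-d / tail_decay_um)``; where several vessel
    voxels overlie the same point the strongest decayed contribution
    applies (a decorrelation tail scales with the overlying flow signal
    but stays strictly below ``tail_strength`` times its source, it does
    not accumulate without bound).  Output is clipped to 255.
    Deterministic; never decreases any voxel; columns without vessels are
    unchanged.
    """
    if not 0 <= tail_strength <= 1:
        raise ConfigError(f"tail_strength={tail_strength} outside [0, 1]")
    if tail_decay_um <= 0:
        raise ConfigError("tail_decay_um must be > 0")
    mask = vessel_mask.mask if isinstance(vessel_mask, BinaryVolume) else vessel_mask
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != octa.shape:
        raise ConfigError("vessel mask and OCTA volume must share geometry")
    if tail_strength == 0:
        return octa.with_voxels(octa.voxels.copy())

    pitch_um = octa.effective_axial_pitch_mm * 1000.0
    decay = math.exp(-pitch_um / tail_decay_um)
    v = octa.voxels.astype(np.float64)
    source = np.where(mask, v, 0.0)
    out = v.copy()
    decayed_max = np.zeros(v.shape[1:], dtype=np.float64)
    for z in range(1, v.shape[0]):
        np.maximum(decayed_max, source[z - 1], out=decayed_max)
        decayed_max *= decay
        out[z] += tail_strength * decayed_max
    return octa.with_voxels(np.clip(np.rint(out), 0, 255).astype(np.uint8))


def planar_vessel_fraction(truth: GroundTruth, bounds) -> float:
    """Ground-truth en-face vessel coverage of a slab (fraction in [0, 1]).

    The fraction of columns whose slab range contains at least one true
    vessel voxel — the quantity a perfect max-projection binarization of
    the slab would report.
    """
    mask = truth.vessel_mask.mask
    nz = mask.shape[0]
    zz = np.arange(nz)[:, None, None]
    inside = (zz >= bounds.lower[None]) & (zz < bounds.upper[None])
    return float((mask & inside).any(axis=0).mean())


# --------------------------------------------------------------------------
# cohorts

@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a simulated two-group cohort.

    Vessel fractions are drawn per eye from normal distributions; the
    diabetic group's DVC fraction mean is shifted down by
    ``effect_dvc_fraction`` (SCP distributions are identical in both
    groups, mirroring the DVC-confined deficit reported clinically).
    Covariate distributions follow the study cohort's summary statistics:
    age 27.2 +/- 10.2 (diabetic) vs 31.0 +/- 11.4 (control) years, HbA1c
    7.5 +/- 0.7 % and diabetes duration 13.2 +/- 6.0 years (diabetics
    only).  SSI is drawn uniformly from [7, 10] — the post-exclusion range.
    """

    n_per_group: int = 35
    base: SimEyeConfig = field(default_factory=SimEyeConfig)
    scp_fraction: tuple[float, float] = (0.06, 0.003)
    dvc_fraction_control: tuple[float, float] = (0.10, 0.015)
    effect_dvc_fraction: float = 0.010
    thickness_um: tuple[float, float] = (320.5, 8.0)
    age_diabetic: tuple[float, float] = (27.2, 10.2)
    age_control: tuple[float, float] = (31.0, 11.4)
    hba1c: tuple[float, float] = (7.5, 0.7)
    duration: tuple[float, float] = (13.2, 6.0)
    ssi_range: tuple[float, float] = (7.0, 10.0)

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ConfigError("n_per_group must be >= 2")


def _draw(rng, mean_sd, lo, hi):
    return float(np.clip(rng.normal(*mean_sd), lo, hi))


def iter_cohort(
    config: CohortConfig, seed: int
) -> Iterator[SimulatedEye]:
    """Yield simulated eyes one at a time (memory-friendly for big runs).

    Per-subject seeds are derived deterministically from the master seed via
    :class:`numpy.random.SeedSequence` spawning, so any prefix of the cohort
    is reproducible independently of how far iteration proceeds.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * config.n_per_group)
    idx = 0
    for group in ("diabetic", "control"):
        frac_dvc_mean = (
            config.dvc_fraction_control[0] - config.effect_dvc_fraction
            if group == "diabetic"
            else config.dvc_fraction_control[0]
        )
        for i in range(config.n_per_group):
            child = children[idx]
            idx += 1
            eye_seed = int(child.generate_state(1)[0] % (2**31))
            rng = np.random.default_rng(child)
            f_scp = float(np.clip(rng.normal(*config.scp_fraction), 0.0, 0.5))
            f_dvc = float(
                np.clip(
                    rng.normal(frac_dvc_mean, config.dvc_fraction_control[1]),
                    0.0,
                    0.5,
                )
            )
            t_mean, t_sd = config.thickness_um
            thick = _draw(
                rng, config.thickness_um, t_mean - 4 * t_sd, t_mean + 4 * t_sd
            )
            ssi = float(rng.uniform(*config.ssi_range))
            age_dist = (
                config.age_diabetic if group == "diabetic" else config.age_control
            )
            record = EyeRecord(
                subject_id=f"{group[:3]}-{i:03d}",
                group=group,
                age=_draw(rng, age_dist, 18.0, 80.0),
                ssi=ssi,
                laterality="OD" if rng.random() < 0.5 else "OS",
                hba1c=_draw(rng, config.hba1c, 5.5, 10.0)
                if group == "diabetic"
                else None,
                diabetes_duration=_draw(rng, config.duration, 1.0, 40.0)
                if group == "diabetic"
                else None,
            )
            eye_cfg = replace(
                config.base,
                target_fraction_scp=f_scp,
                target_fraction_dvc=f_dvc,
                retina_thickness_um=thick,
                ssi=ssi,
                seed=eye_seed,
            )
            structural, octa, truth = simulate_eye(eye_cfg)
            yield SimulatedEye(record, structural, octa, truth)


def simulate_cohort(config: CohortConfig, seed: int) -> list[SimulatedEye]:
    """Materialize a full cohort (see :func:`iter_cohort`)."""
    return list(iter_cohort(config, seed))
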