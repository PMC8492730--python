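"""Suppression of decorrelation-tail (projection) artifacts.

Superficial vessels cast spurious decorrelation signal down the beam axis,
so deeper slabs inherit a "shadow" copy of the overlying vasculature.  Two
standard mechanisms are offered behind one interface:

``axial_peak`` (default)
    Projection-resolved style.  Per A-scan column, contiguous runs of
    voxels above a robust noise floor (median + 2 MAD by default) are
    treated as candidate vessel segments.  Within a run, vessel peaks are
    the run's global maximum plus every local maximum with sufficient
    topographic prominence (so noise wiggles riding a decorrelation tail
    do not qualify, but a genuine deep vessel under a tail does).  Each
    vessel peak retains the contiguous region in which intensity stays
    above a fixed fraction of the peak — a vessel cross-section is a
    compact bump, whereas a projection tail hangs below it at a strictly
    smaller fraction of the source intensity and decays away.  Run voxels
    outside every retained region are attenuated to the column's noise
    median.  Voxels below the floor, or in runs too short to be vessels,
    are left untouched.

``subtraction``
    Scaled-reflectance baseline: each voxel becomes
    ``max(0, v(z) - alpha * max(v(z' < z)))``.

Neither mode ever increases a voxel intensity.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .errors import ConfigError
from .volume import OCTAVolume

__all__ = ["remove_projection_artifacts"]


@njit(cache=True)
def _axial_peak_kernel(vox, floors, meds, proms, min_run, keep_fraction, out):  # pragma: no cover
    nz, ny, nx = vox.shape
    keep = np.zeros(nz, dtype=np.bool_)
    for y in range(ny):
        for x in range(nx):
            floor = floors[y, x]
            med = meds[y, x]
            prom = proms[y, x]
            i = 0
            while i < nz:
                if vox[i, y, x] <= floor:
                    i += 1
                    continue
                j = i
                while j < nz and vox[j, y, x] > floor:
                    j += 1
                # run is [i, j)
                if j - i >= min_run:
                    for t in range(i, j):
                        keep[t] = False
                    # run global max
                    gmax = i
                    for t in range(i + 1, j):
                        if vox[t, y, x] > vox[gmax, y, x]:
                            gmax = t
                    for t in range(i, j):
                        v = vox[t, y, x]
                        left_ok = t == i or vox[t - 1, y, x] <= v
                        right_ok = t == j - 1 or vox[t + 1, y, x] <= v
                        if not (left_ok and right_ok):
                            continue
                        if t != gmax:
                            # topographic prominence within the run:
                            # min down to the nearest higher sample on
                            # each side (or run edge), take the higher
                            lmin = v
                            q = t - 1
                            while q >= i and vox[q, y, x] <= v:
                                if vox[q, y, x] < lmin:
                                    lmin = vox[q, y, x]
                                q -= 1
                            rmin = v
                            q = t + 1
                            while q < j and vox[q, y, x] <= v:
                                if vox[q, y, x] < rmin:
                                    rmin = vox[q, y, x]
                                q += 1
                            base = lmin if lmin > rmin else rmin
                            if v - base < prom:
                                continue
                        # retain the compact bump around the peak
                        cut = keep_fraction * v
                        if cut < floor:
                            cut = floor
                        L = t
                        while L - 1 >= i and vox[L - 1, y, x] >= cut:
                            L -= 1
                        R = t
                        while R + 1 < j and vox[R + 1, y, x] >= cut:
                            R += 1
                        for q in range(L, R + 1):
                            keep[q] = True
                    for t in range(i, j):
                        if not keep[t]:
                            out[t, y, x] = med
                i = j
    return out


def remove_projection_artifacts(
    octa: OCTAVolume,
    mode: str = "axial_peak",
    alpha: float = 0.3,
    noise_floor: str | int = "auto",
    min_run: int = 3,
    prominence_mads: float = 4.0,
    keep_fraction: float = 0.6,
) -> OCTAVolume:
    """Suppress projection tails in an OCTA volume.

    Parameters
    ----------
    mode : {"axial_peak", "subtraction"}
        Removal mechanism (see module docstring).
    alpha : float
        Subtraction weight in [0, 1] (subtraction mode only).
    noise_floor : "auto" or int
        Per-column floor; "auto" uses median + 2 MAD of the column.
    min_run : int
        Minimum suprafloor run length treated as vessel (axial_peak mode).
    prominence_mads : float
        Topographic prominence, in column MAD units, required for a local
        maximum other than the run's global maximum to count as a distinct
        (deep) vessel.
    keep_fraction : float
        Fraction of a peak's intensity defining the retained bump around
        it; a decorrelation tail sits below its source vessel at a smaller
        fraction than this, so it is attenuated while vessel bodies are
        kept intact.
    """
    if not 0 <= alpha <= 1:
        raise ConfigError(f"alpha={alpha} outside [0, 1]")
    if mode not in ("axial_peak", "subtraction"):
        raise ConfigError(f"unknown projection-removal mode '{mode}'")

    vox = octa.voxels
    if mode == "subtraction":
        v = vox.astype(np.float32)
        prior = np.maximum.accumulate(v, axis=0)
        prior = np.vstack([np.zeros_like(prior[:1]), prior[:-1]])
        out = np.clip(np.rint(v - alpha * prior), 0, 255).astype(np.uint8)
        return octa.with_voxels(out)

    v = vox.astype(np.float32)
    meds = np.median(v, axis=0)
    mads = np.median(np.abs(v - meds[None]), axis=0)
    if noise_floor == "auto":
        floors = meds + 2.0 * mads
    else:
        floors = np.full_like(meds, float(noise_floor))
    proms = np.maximum(prominence_mads * mads, 1.0)

    out = v.copy()
    _axial_peak_kernel(
        v, floors.astype(np.float32), meds.astype(np.float32),
        proms.astype(np.float32), min_run, np.float32(keep_fraction), out,
    )
    out8 = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    # attenuation replaces values by the column median (<= floor < value),
    # so no voxel can increase; guard against rounding at the boundary
    np.minimum(out8, vox, out=out8)
    return octa.with_voxels(out8)
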