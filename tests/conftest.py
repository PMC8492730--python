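"""Shared fixtures: small scan geometries and cached synthetic eyes."""

import numpy as np
import pytest

import octa3d as o


def small_geometry(nx=40, ny=40, nz=120, lateral_um=12.0, axial_um=3.0):
    return o.ScanGeometry(
        lateral_extent_mm=nx * lateral_um / 1000.0,
        depth_extent_mm=nz * axial_um / 1000.0,
        n_ascans_x=nx,
        n_ascans_y=ny,
        n_axial_px=nz,
    )


@pytest.fixture(scope="session")
def reduced_eye():
    """One default reduced-scale synthetic eye (with projection tails)."""
    cfg = o.SimEyeConfig(geometry=o.reduced_geometry(), seed=7)
    structural, octa, truth = o.simulate_eye(cfg)
    return cfg, structural, octa, truth


@pytest.fixture(scope="session")
def clean_eye():
    """High-contrast, tail-free reduced eye (for recovery-style checks)."""
    cfg = o.SimEyeConfig(
        geometry=o.reduced_geometry(), tail_strength=0.0, ssi=10.0, seed=11
    )
    structural, octa, truth = o.simulate_eye(cfg)
    return cfg, structural, octa, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
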