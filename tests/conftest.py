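"""Shared fixtures: geometric phantoms, fast small-cell presets, and a
session-scoped synthetic panel reused across module tests."""

from __future__ import annotations

import numpy as np
import pytest

from organelle3d import synthetic as syn
from organelle3d.io import CHLOROPLAST, MITOCHONDRION, PEROXISOME


def digitized_ball(radius_vox: int, spacing_nm=(10.0, 10.0, 10.0)):
    """Boolean ball of given voxel radius; physical radius depends on
    spacing only if isotropic (used with isotropic spacing in oracles)."""
    n = radius_vox + 4
    zz, yy, xx = np.mgrid[-n:n + 1, -n:n + 1, -n:n + 1]
    return (zz * zz + yy * yy + xx * xx) <= radius_vox * radius_vox


def anisotropic_sphere(radius_nm: float, spacing_nm):
    dz, dy, dx = spacing_nm
    hz = int(radius_nm / dz) + 3
    hy = int(radius_nm / dy) + 3
    hx = int(radius_nm / dx) + 3
    zz, yy, xx = np.mgrid[-hz:hz + 1, -hy:hy + 1, -hx:hx + 1]
    return ((zz * dz) ** 2 + (yy * dy) ** 2 + (xx * dx) ** 2) <= radius_nm**2


#: reduced-size cell spec for fast unit tests (same code paths as the
#: full-size default preset)
SMALL_OVERRIDES = dict(
    grid_shape=(32, 96, 96),
    cell_semiaxes_um=(1.45, 2.25, 2.25),
    vacuole_semiaxes_um=(1.35, 2.15, 2.15),
    nucleus_semiaxes_um=(0.4, 0.55, 0.55),
    chl_radius_um=(0.55, 0.65),
    per_radius_um=(0.16, 0.24),
    mito_radius_um=(0.13, 0.15),
    mito_length_um=(0.6, 1.1),
    site_area_vox=16,
    count_ranges={CHLOROPLAST: (6, 8), PEROXISOME: (4, 6),
                  MITOCHONDRION: (8, 12)},
    cell_scale_range=(0.9, 1.02),
)


def small_spec(condition: str, seed: int = 0, **extra) -> syn.SynthSpec:
    over = dict(SMALL_OVERRIDES)
    if condition == "light":
        over["site_area_vox"] = 28
        over["per_radius_um"] = (0.20, 0.30)
        over["mito_length_um"] = (0.4, 0.7)
        over["count_ranges"] = {CHLOROPLAST: (6, 8), PEROXISOME: (5, 7),
                                MITOCHONDRION: (9, 13)}
    over.update(extra)
    return syn.spec_for(condition, seed=seed, **over)


@pytest.fixture(scope="session")
def small_cell_dark():
    return syn.generate_cell(small_spec("dark", seed=3))


@pytest.fixture(scope="session")
def small_cell_light():
    return syn.generate_cell(small_spec("light", seed=3))


@pytest.fixture(scope="session")
def small_panel(small_cell_dark, small_cell_light):
    """2 dark + 2 light small cells with ground truth."""
    return [
        small_cell_dark,
        syn.generate_cell(small_spec("dark", seed=11)),
        small_cell_light,
        syn.generate_cell(small_spec("light", seed=11)),
    ]


@pytest.fixture(scope="session")
def default_cell_dark():
    """One full-size default dark cell (the study conditions)."""
    return syn.generate_cell(syn.dark_spec(seed=5))
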