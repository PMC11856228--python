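"""Shared fixtures: compact phantom configurations for fast pipeline tests.

Test phantoms use a reduced field of view (the neck region only) but the
study's native voxel sizes (CT 1.1 x 1.1 x 4.4 mm, SPECT 4.4 mm cubes), HU
classes, activity concentrations, and PSF widths.
"""

from __future__ import annotations

import numpy as np
import pytest

from remnantvol import PhantomSpec, SphereSpec, sphere_radius_mm

# Typical diagnostic fill concentrations (MBq/mL) per volume size, matching
# single-acquisition administered activities (e.g. 0.5 mL at 0.555 MBq).
FILL_CONC = {0.5: 1.11, 1.0: 1.109, 1.5: 0.493, 3.0: 0.432, 10.0: 0.37}


def single_sphere_spec(
    volume_ml: float,
    *,
    ct_shape=(128, 128, 16),
    fwhm: float = 14.0,
    seed: int = 1,
    noise: bool = True,
    pct_bkg: float = 0.0,
    conc: float | None = None,
) -> PhantomSpec:
    """A sphere centered on a voxel center at the middle slice."""
    cz = (ct_shape[2] - 1) / 2 * 4.4
    cx = (ct_shape[0] - 1) / 2 * 1.1
    if conc is None:
        conc = FILL_CONC.get(volume_ml)
    return PhantomSpec(
        spheres=[SphereSpec((cx, cx, cz), volume_ml, conc)],
        ct_shape=ct_shape,
        neck_radius_mm=55.0,
        psf_fwhm_mm=fwhm,
        noise=noise,
        seed=seed,
        pct_bkg=pct_bkg,
    )


def two_sphere_spec(
    volumes=(1.5, 3.0),
    *,
    separation_mm: float = 10.0,
    ct_shape=(160, 160, 16),
    fwhm: float = 14.0,
    seed: int = 1,
    noise: bool = True,
    pct_bkg: float = 0.0,
) -> PhantomSpec:
    """Two spheres side by side along x with the given surface separation."""
    cz = (ct_shape[2] - 1) / 2 * 4.4
    cy = (ct_shape[1] - 1) / 2 * 1.1
    cx = (ct_shape[0] - 1) / 2 * 1.1
    r = [sphere_radius_mm(v) for v in volumes]
    d = r[0] + r[1] + separation_mm
    return PhantomSpec(
        spheres=[
            SphereSpec((cx - d / 2, cy, cz), volumes[0], FILL_CONC.get(volumes[0])),
            SphereSpec((cx + d / 2, cy, cz), volumes[1], FILL_CONC.get(volumes[1])),
        ],
        ct_shape=ct_shape,
        neck_radius_mm=62.0,
        psf_fwhm_mm=fwhm,
        noise=noise,
        seed=seed,
        pct_bkg=pct_bkg,
    )


@pytest.fixture(scope="session")
def pair_1p5_3():
    """Correlated pair with 1.5 + 3 mL spheres, 1 cm apart, I-131-like blur."""
    from remnantvol import generate_pair

    return generate_pair(two_sphere_spec(seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
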