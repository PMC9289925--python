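"""Shared fixtures: one phantom spec and a few simulated images reused widely.

Session-scoped simulations keep the suite fast; every image is generated
programmatically from the parametric phantom model at run time.
"""

import numpy as np
import pytest

import acrpet
from acrpet.pet_simulator import SimulationConfig, simulate_recon

# axial window spanning the faceplate-insert slab (sampling midplane 71 mm)
INSERT_SLAB = (51.0, 91.0)


@pytest.fixture(scope="session")
def spec():
    return acrpet.default_acr_spec()


@pytest.fixture(scope="session")
def insert_templates(spec):
    return acrpet.make_insert_templates(spec)


@pytest.fixture(scope="session")
def rod_templates(spec):
    return acrpet.make_rod_templates(spec)


@pytest.fixture(scope="session")
def bg_template(spec):
    return acrpet.make_background_template(spec)


@pytest.fixture(scope="session")
def noiseless_insert_image(spec):
    """Noise-free 4 mm-blur reconstruction of the faceplate slab, 1 mm grid."""
    cfg = SimulationConfig(psf_fwhm=4.0, total_counts=1e8, noise=False,
                           render_voxel_size=1.0, voxel_size_out=1.0,
                           axial_range=INSERT_SLAB)
    return simulate_recon(spec, cfg)


@pytest.fixture(scope="session")
def noisy_insert_image(spec):
    cfg = SimulationConfig(psf_fwhm=4.0, total_counts=5e7, seed=11,
                           render_voxel_size=1.0, voxel_size_out=2.0,
                           axial_range=INSERT_SLAB)
    return simulate_recon(spec, cfg)


@pytest.fixture(scope="session")
def uniform_image(spec):
    """Constant-valued image on the faceplate slab grid."""
    cfg = SimulationConfig(psf_fwhm=0.0, total_counts=1e8, noise=False,
                           render_voxel_size=1.0, voxel_size_out=1.0,
                           axial_range=INSERT_SLAB)
    img = simulate_recon(spec, cfg)
    vals = np.full_like(img.values, 1234.5)
    return acrpet.VoxelImage(vals, img.voxel_size, img.origin, "activity")
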