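import numpy as np
import pytest

from osteoquant import CallusSpec, ScanGeometry, make_tibia_scan
from osteoquant.calibration import DensityImage


@pytest.fixture(scope="session")
def small_geometry() -> ScanGeometry:
    """Desk-scale operated tibia: coarse voxels, short shaft, 10-mm gap."""
    return ScanGeometry(
        outer_radius=8.0,
        cortical_thickness=2.5,
        bone_length=40.0,
        gap_width=10.0,
        voxel_spacing=0.4,
        fov_margin=6.0,
    )


@pytest.fixture(scope="session")
def small_scan(small_geometry):
    """Noiseless operated-tibia scan with a 2 cm^3, 700 mg HA/cm^3 callus."""
    return make_tibia_scan(
        small_geometry, CallusSpec(2.0, 700.0), noise_sd=0.0, seed=11
    )


@pytest.fixture(scope="session")
def noisy_scan(small_geometry):
    """Same scan with 20 HU additive noise (scanner-like)."""
    return make_tibia_scan(
        small_geometry, CallusSpec(2.0, 700.0), noise_sd=20.0, seed=11
    )


def cylinder_density(
    r_outer: float,
    r_inner: float,
    length: float,
    spacing: float,
    rho: float = 1200.0,
    margin: float = 1.0,
) -> DensityImage:
    """Voxelized homogeneous hollow cylinder (long axis = z)."""
    n_xy = int(np.ceil(2 * (r_outer + margin) / spacing))
    n_z = int(round(length / spacing))
    centre = n_xy * spacing / 2.0
    x = (np.arange(n_xy) + 0.5) * spacing - centre
    r2 = x[:, None] ** 2 + x[None, :] ** 2
    annulus = (r2 >= r_inner**2) & (r2 <= r_outer**2)
    vol = np.zeros((n_xy, n_xy, n_z))
    vol[annulus] = rho
    return DensityImage(vol, spacing)
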