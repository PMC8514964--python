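"""Shared fixtures: phantoms are generated once per session at reduced
block sizes so the unit suite stays fast; the acceptance tests build
their own full-size phantoms."""

import pytest

import lungstereo as ls


@pytest.fixture(scope="session")
def normoxia_parenchyma() -> ls.Phantom3D:
    """Closed-cell parenchymal block, ~130 um lattice cells, seed 1."""
    return ls.build_parenchyma_phantom(ls.NORMOXIA, seed=1, target_extent_vox=160)


@pytest.fixture(scope="session")
def hyperoxia_parenchyma() -> ls.Phantom3D:
    return ls.build_parenchyma_phantom(ls.HYPEROXIA, seed=1, target_extent_vox=160)


@pytest.fixture(scope="session")
def sphere_phantom() -> ls.Phantom3D:
    """Single 20 um cavity at 1 um voxels with analytic V and S."""
    return ls.build_sphere_phantom(radius_um=20.0, voxel_um=1.0)


@pytest.fixture(scope="session")
def vessel_phantom() -> ls.Phantom3D:
    """One axial vessel, lumen d=60 um with 6 um wall and 10 um sheath."""
    return ls.build_cylinder_phantom(
        lumen_diameter_um=60.0,
        wall_thickness_um=6.0,
        perivascular_thickness_um=10.0,
        length_um=200.0,
        voxel_um=1.0,
    )
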