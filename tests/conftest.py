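import numpy as np
import pytest

from fobtools import AcquisitionGeometry
from fobtools.brillouin import SpectrometerModel
from fobtools.forward import circle_tilts, simulate_hologram_set
from fobtools.holography import retrieve_fields
from fobtools.phantoms import PhantomSpec, Primitive, build_phantom

SPHERE_N = 1.357          # dn = 0.02 over medium 1.337
SPHERE_RADIUS_UM = 0.8    # 8 voxels at 0.1 um pitch


@pytest.fixture(scope="session")
def geometry():
    return AcquisitionGeometry(pixel_pitch_um=0.1, axial_pitch_um=0.1)


@pytest.fixture(scope="session")
def spectrometer():
    return SpectrometerModel()


@pytest.fixture(scope="session")
def sphere_truth():
    spec = PhantomSpec(
        grid_shape=(64, 64, 64),
        voxel_size_um=(0.1, 0.1, 0.1),
        n_medium=1.337,
        primitives=(
            Primitive(
                center_um=(3.2, 3.2, 3.2),
                radii_um=(SPHERE_RADIUS_UM,) * 3,
                n=SPHERE_N,
                shift_ghz=7.8,
                linewidth_ghz=0.8,
                label=1,
            ),
        ),
    )
    return build_phantom(spec)


@pytest.fixture(scope="session")
def sphere_tilts(geometry):
    return circle_tilts(geometry, n_angles=60, shape=(64, 64))


@pytest.fixture(scope="session")
def sphere_holograms(sphere_truth, geometry, sphere_tilts):
    return simulate_hologram_set(sphere_truth, geometry, tilts=sphere_tilts, mode="multislice")


@pytest.fixture(scope="session")
def sphere_fields(sphere_holograms):
    return retrieve_fields(sphere_holograms)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
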