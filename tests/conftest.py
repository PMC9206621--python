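import numpy as np
import pytest

from hybridreg.geometry import CameraModel, Volume3D
from hybridreg.phantom import FluoroSimSpec, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def camera():
    """Study geometry: 1000/600 mm, 160x160 detector at 0.5 mm pitch."""
    return CameraModel(1000.0, 600.0, 0.5, (160, 160))


@pytest.fixture(scope="session")
def small_camera():
    """Coarser detector for cheap registration tests."""
    return CameraModel(1000.0, 600.0, 1.0, (96, 96))


@pytest.fixture(scope="session")
def femur_volume():
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def small_volume():
    """Down-sampled femur phantom (32^3 at 2 mm) for fast tests."""
    return generate_phantom(
        PhantomSpec(shape=(32, 32, 32), spacing=2.0, shell_thickness=2.5)
    )


@pytest.fixture(scope="session")
def noiseless_sim():
    return FluoroSimSpec(noise_sigma=0.0)


@pytest.fixture(scope="session")
def uniform_cube():
    """20 mm uniform-attenuation cube inside a 40 mm grid."""
    n = 40
    vox = np.zeros((n, n, n))
    vox[10:30, 10:30, 10:30] = 0.7
    return Volume3D(vox, (1.0, 1.0, 1.0))
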