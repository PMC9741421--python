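import numpy as np
import pytest

from dotbench.mesh import (
    build_disk_mesh,
    Phantom,
    Inclusion,
    NodalCoefficients,
)
from dotbench.forward import ProbeGeometry


@pytest.fixture(scope="session")
def mesh32():
    return build_disk_mesh(32, 100.0)


@pytest.fixture(scope="session")
def mesh8():
    return build_disk_mesh(8, 80.0)


@pytest.fixture(scope="session")
def mesh16():
    return build_disk_mesh(16, 100.0)


@pytest.fixture
def homogeneous_coeffs(mesh32):
    n = mesh32.n_nodes
    return NodalCoefficients(np.full(n, 0.01), np.full(n, 1.0))


@pytest.fixture
def probe():
    return ProbeGeometry.for_background(1.0)


@pytest.fixture
def single_inclusion_phantom():
    return Phantom(
        diameter_mm=100.0,
        frequency_MHz=100.0,
        mu_a0=0.01,
        mu_s0=1.0,
        inclusions=(
            Inclusion(
                radius_mm=12.0,
                off_center_mm=20.0,
                angle_deg=45.0,
                contrast_a=2.0,
                contrast_s=3.0,
            ),
        ),
    )


@pytest.fixture
def homogeneous_phantom():
    return Phantom(diameter_mm=100.0, frequency_MHz=100.0, mu_a0=0.01, mu_s0=1.0)
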