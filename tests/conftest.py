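import numpy as np
import pytest
import trimesh

from pharyngoflow import (
    AreaProfile,
    SyntheticSpec,
    make_area_profile,
    make_surface_mesh,
)


def open_cylinder(radius=5.0, length=50.0, n_theta=64, spacing=0.5):
    """Open-ended tube of constant circular cross-section (analytic oracle)."""
    n = int(round(length / spacing)) + 1
    profile = AreaProfile(
        z_mm=length - spacing * np.arange(n),
        area_mm2=np.full(n, np.pi * radius**2),
    )
    return make_surface_mesh(profile, n_theta=n_theta), profile


@pytest.fixture(scope="session")
def cylinder():
    return open_cylinder()


@pytest.fixture(scope="session")
def ftp4_spec():
    return SyntheticSpec.from_template("FTP4_MO")


@pytest.fixture(scope="session")
def ftp4_profile(ftp4_spec):
    return make_area_profile(ftp4_spec)


@pytest.fixture(scope="session")
def ftp4_mesh(ftp4_spec, ftp4_profile):
    return make_surface_mesh(ftp4_profile, ftp4_spec)


@pytest.fixture(scope="session")
def two_lumen_mesh():
    """Two disjoint parallel tubes (areas 30 and 20 mm²) in one mesh."""
    meshes = []
    for area, x0 in ((30.0, -8.0), (20.0, 8.0)):
        m, _ = open_cylinder(radius=np.sqrt(area / np.pi), length=20.0, spacing=1.0)
        m = m.copy()
        m.vertices = m.vertices + np.array([x0, 0.0, 0.0])
        meshes.append(m)
    return trimesh.util.concatenate(meshes)
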