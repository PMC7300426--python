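import numpy as np
import pytest
import trimesh

from vesiclekit.synthetic import VesicleSurface


def mesh_surface(mesh: trimesh.Trimesh, vesicle_id: str = "mesh") -> VesicleSurface:
    return VesicleSurface(
        vesicle_id=vesicle_id,
        points=np.asarray(mesh.vertices, dtype=float),
        faces=np.asarray(mesh.faces, dtype=int),
        voxel_size=0.0,
    )


@pytest.fixture(scope="session")
def icosphere_r20() -> VesicleSurface:
    """Subdivision-4 icosphere of radius 20 nm (2562 vertices, 5120 faces)."""
    return mesh_surface(trimesh.creation.icosphere(subdivisions=4, radius=20.0), "ico20")


@pytest.fixture(scope="session")
def ellipsoid_mesh() -> VesicleSurface:
    """Icosphere stretched to semi-axes (30, 25, 20) nm."""
    mesh = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
    mesh.vertices = mesh.vertices * np.array([30.0, 25.0, 20.0])
    return mesh_surface(mesh, "ellipsoid")


@pytest.fixture(scope="session")
def unit_cube() -> VesicleSurface:
    """Unit cube mesh (8 vertices, 12 triangles), volume exactly 1."""
    return mesh_surface(trimesh.creation.box(extents=(1.0, 1.0, 1.0)), "cube")
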