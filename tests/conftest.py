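import numpy as np
import pytest

from aneuflow import PhantomSpec, StructuredVelocityField, TriSurface

CUBE_VERTICES = np.array(
    [
        [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
        [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
    ],
    dtype=float,
)

# consistent outward winding
CUBE_FACES = np.array(
    [
        [0, 2, 1], [0, 3, 2],  # z = 0
        [4, 5, 6], [4, 6, 7],  # z = 1
        [0, 1, 5], [0, 5, 4],  # y = 0
        [2, 3, 7], [2, 7, 6],  # y = 1
        [0, 4, 7], [0, 7, 3],  # x = 0
        [1, 2, 6], [1, 6, 5],  # x = 1
    ]
)


@pytest.fixture
def cube_surface() -> TriSurface:
    return TriSurface(vertices=CUBE_VERTICES.copy(), faces=CUBE_FACES.copy())


@pytest.fixture
def constant_field() -> StructuredVelocityField:
    u = np.zeros((2, 2, 2, 3))
    u[..., 0] = 1.0
    return StructuredVelocityField(
        origin=[0, 0, 0], spacing=[1, 1, 1], u=u, mask=np.ones((2, 2, 2), bool)
    )


def affine_field(G0, dims=(7, 7, 7), spacing=0.1, u0=(0.0, 0.0, 0.0)):
    """u(x) = u0 + G0 @ x sampled on an all-lumen grid."""
    G0 = np.asarray(G0, float)
    spacing = np.full(3, spacing, float) if np.isscalar(spacing) else np.asarray(spacing)
    origin = np.zeros(3)
    axes = [origin[a] + np.arange(dims[a]) * spacing[a] for a in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    u = np.asarray(u0, float) + np.einsum("ij,...j->...i", G0, pts)
    return StructuredVelocityField(
        origin=origin, spacing=spacing, u=u, mask=np.ones(dims, bool)
    )


@pytest.fixture(scope="session")
def sac_spec() -> PhantomSpec:
    return PhantomSpec(
        tube_radius=2e-3,
        tube_length=1.2e-2,
        sac_radius=3e-3,
        sac_center_offset=(3.8e-3, 0.0, 0.0),
        v_max=0.5,
    )
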