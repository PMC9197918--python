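"""Wall-shear-stress estimation on a lumen surface.

The near-wall velocity-gradient tensor is mapped from the structured
grid onto surface vertices by inverse-distance-weighted interpolation,
and the viscous traction vector is evaluated as

    tau = 2 * mu * symm(grad u) . n_inward

componentwise, with ``n`` the unit inward wall normal.  The full
traction is reported (no tangent-plane projection); an optional helper
returns the surface-parallel component for users who want it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io_formats import TriSurface
from .similarity_scaling import SimilaritySpec
from .tensor_calculus import GradientField

__all__ = [
    "SurfaceVectorField",
    "WssSummary",
    "compute_vertex_normals",
    "map_gradients_to_surface",
    "wss_vectors",
    "tangential_magnitude",
    "normalize_wss",
    "scale_wss",
    "summarize_wss",
]


@dataclass
class SurfaceVectorField:
    """Per-vertex WSS vectors (Pa) on a triangulated surface.

    ``mapped`` is False at vertices where no valid gradient voxel was
    found within the search radius; those carry NaN and are excluded
    from all summaries.
    """

    surface: TriSurface
    tau: np.ndarray          # (n_vertices, 3), Pa
    magnitude: np.ndarray    # (n_vertices,), Pa
    mapped: np.ndarray       # (n_vertices,) bool

    def __post_init__(self) -> None:
        m = self.mapped
        if not np.allclose(
            self.magnitude[m], np.linalg.norm(self.tau[m], axis=1), rtol=1e-12, atol=0
        ):
            raise ValueError("magnitude must equal ||tau||")


@dataclass(frozen=True)
class WssSummary:
    """Spatial summary of a WSS field: mean, peak and normalization reference (Pa)."""

    mean: float
    peak: float
    reference: float = float("nan")

    def __post_init__(self) -> None:
        if not (0 <= self.mean <= self.peak):
            raise ValueError(f"need 0 <= mean <= peak, got {self.mean}, {self.peak}")


# ---------------------------------------------------------------------------
# Normals
# ---------------------------------------------------------------------------

def _consistent_face_orientation(surface: TriSurface) -> np.ndarray:
    """Per-face +-1 signs that make winding consistent across shared edges.

    Breadth-first propagation over the edge-adjacency graph: two
    neighboring triangles are consistently wound when they traverse the
    shared edge in opposite directions.
    """
    faces = surface.faces
    nf = len(faces)
    edge_map: dict[tuple[int, int], list[tuple[int, bool]]] = {}
    for fi, (va, vb, vc) in enumerate(faces):
        for a, b in ((va, vb), (vb, vc), (vc, va)):
            key = (min(a, b), max(a, b))
            edge_map.setdefault(key, []).append((fi, a < b))
    for key, users in edge_map.items():
        if len(users) > 2:
            raise ValueError(f"edge {key} shared by {len(users)} faces: surface not manifold-like")

    sign = np.zeros(nf, dtype=np.int8)
    for seed in range(nf):
        if sign[seed]:
            continue
        sign[seed] = 1
        stack = [seed]
        while stack:
            fi = stack.pop()
            va, vb, vc = faces[fi]
            for a, b in ((va, vb), (vb, vc), (vc, va)):
                key = (min(a, b), max(a, b))
                for fj, fwd_j in edge_map[key]:
                    if fj == fi or sign[fj]:
                        continue
                    fwd_i = a < b
                    # consistent orientation traverses a shared edge in
                    # opposite directions
                    sign[fj] = sign[fi] if fwd_i != fwd_j else -sign[fi]
                    stack.append(fj)
    return sign.astype(float)


def compute_vertex_normals(surface: TriSurface, interior_point) -> TriSurface:
    """Return a copy of *surface* with unit inward per-vertex normals.

    Vertex normals are area-weighted averages of incident face normals.
    Face windings are first made mutually consistent by propagation over
    shared edges; the global orientation is then fixed so that the
    normal at the vertex nearest ``interior_point`` points toward it.
    """
    interior_point = np.asarray(interior_point, dtype=float).reshape(3)
    face_n, areas = surface.face_normals_areas()
    sign = _consistent_face_orientation(surface)
    weighted = face_n * (areas * sign)[:, None]

    vn = np.zeros_like(surface.vertices)
    np.add.at(vn, surface.faces[:, 0], weighted)
    np.add.at(vn, surface.faces[:, 1], weighted)
    np.add.at(vn, surface.faces[:, 2], weighted)

    norms = np.linalg.norm(vn, axis=1)
    degenerate = np.flatnonzero(norms == 0)
    if degenerate.size:
        raise ValueError(
            f"degenerate normals (zero-area vertex star) at vertex ids {degenerate.tolist()}"
        )
    vn /= norms[:, None]

    nearest = int(np.argmin(np.linalg.norm(surface.vertices - interior_point, axis=1)))
    to_interior = interior_point - surface.vertices[nearest]
    if np.dot(vn[nearest], to_interior) < 0:
        vn = -vn
    return TriSurface(
        vertices=surface.vertices.copy(), faces=surface.faces.copy(),
        normals=vn, inward=True,
    )


# ---------------------------------------------------------------------------
# Gradient mapping and traction
# ---------------------------------------------------------------------------

def map_gradients_to_surface(
    G: GradientField,
    surface: TriSurface,
    power: float = 2.0,
    n_neighbors: int = 8,
    search_radius: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-distance-weighted gradient tensors at surface vertices.

    For each vertex the ``n_neighbors`` nearest valid voxel centers
    within ``search_radius`` (default 3x the coarsest grid spacing)
    contribute with weights ``1/d**power``; a voxel center closer than
    1e-12 m short-circuits to that voxel's tensor.  Returns
    ``(tensors, mapped)`` where unmapped vertices hold NaN.
    """
    if power <= 0:
        raise ValueError("power must be > 0")
    if n_neighbors < 1:
        raise ValueError("n_neighbors must be >= 1")
    if search_radius is None:
        search_radius = 3.0 * float(np.max(G.spacing))

    valid_idx = np.argwhere(G.valid)
    if len(valid_idx) == 0:
        raise ValueError("gradient field has no valid voxels")
    centers = G.origin + valid_idx * G.spacing
    tensors_flat = G.g[G.valid]

    tree = cKDTree(centers)
    k = min(n_neighbors, len(centers))
    dist, idx = tree.query(surface.vertices, k=k)
    dist = np.atleast_2d(dist.reshape(len(surface.vertices), -1))
    idx = np.atleast_2d(idx.reshape(len(surface.vertices), -1))

    in_range = dist <= search_radius
    out = np.full((len(surface.vertices), 3, 3), np.nan)
    mapped = in_range.any(axis=1)

    exact = dist[:, 0] < 1e-12
    with np.errstate(divide="ignore"):
        w = np.where(in_range, 1.0 / dist**power, 0.0)
    wsum = w.sum(axis=1)
    ok = mapped & ~exact
    if np.any(ok):
        contrib = np.einsum("vk,vkij->vij", w[ok], tensors_flat[idx[ok]])
        out[ok] = contrib / wsum[ok, None, None]
    if np.any(exact):
        out[exact] = tensors_flat[idx[exact, 0]]
        mapped |= exact
    return out, mapped


def wss_vectors(
    surface_gradients: np.ndarray,
    surface: TriSurface,
    mu: float,
    mapped: np.ndarray | None = None,
) -> SurfaceVectorField:
    """Viscous traction tau = 2*mu*symm(g).n at every mapped vertex."""
    if surface.normals is None:
        raise ValueError("surface has no normals; call compute_vertex_normals first")
    if mu <= 0:
        raise ValueError("mu must be > 0")
    g = np.asarray(surface_gradients, dtype=float)
    if mapped is None:
        mapped = np.all(np.isfinite(g), axis=(-2, -1))
    S = (g + np.swapaxes(g, -1, -2)) / 2.0
    tau = 2.0 * mu * np.einsum("vij,vj->vi", S, surface.normals)
    tau[~mapped] = np.nan
    magnitude = np.linalg.norm(tau, axis=1)
    return SurfaceVectorField(surface=surface, tau=tau, magnitude=magnitude, mapped=mapped)


def tangential_magnitude(field: SurfaceVectorField) -> np.ndarray:
    """Surface-parallel component ||tau - (tau.n) n|| per vertex, Pa."""
    n = field.surface.normals
    tn = np.einsum("vi,vi->v", field.tau, n)
    return np.linalg.norm(field.tau - tn[:, None] * n, axis=1)


def normalize_wss(field: SurfaceVectorField, parent_patch) -> np.ndarray:
    """WSS magnitude divided by its mean over a parent-vessel vertex patch."""
    patch = np.asarray(list(parent_patch), dtype=np.int64)
    if patch.size == 0:
        raise ValueError("parent_patch must be nonempty")
    patch_mag = field.magnitude[patch]
    patch_mag = patch_mag[np.isfinite(patch_mag)]
    if patch_mag.size == 0:
        raise ValueError("parent_patch has no mapped vertices")
    reference = float(patch_mag.mean())
    if reference == 0:
        raise ValueError("degenerate parent-vessel reference (mean WSS is zero)")
    return field.magnitude / reference


def scale_wss(tau, sim: SimilaritySpec):
    """Rescale phantom-frame WSS to patient scale.

    Multiplies by (mu_vivo/mu_vitro)·(u_vivo/u_vitro)·(d_vitro/d_vivo);
    works elementwise on scalars or arrays.
    """
    return np.asarray(tau) * (sim.mu_ratio * sim.u_ratio * sim.d_ratio)


def summarize_wss(field: SurfaceVectorField, reference: float = float("nan")) -> WssSummary:
    """Unweighted vertex mean and max of the WSS magnitude (mapped vertices only)."""
    mags = field.magnitude[field.mapped]
    mags = mags[np.isfinite(mags)]
    if mags.size == 0:
        raise ValueError("no mapped vertices to summarize")
    return WssSummary(mean=float(mags.mean()), peak=float(mags.max()), reference=reference)
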