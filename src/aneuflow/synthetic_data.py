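"""Analytic ground-truth flows, aneurysm-like phantoms, and modality emulation.

Every downstream stage of the pipeline is testable against the fields
generated here: a parabolic pipe flow with a known wall-shear solution,
a tube-plus-spherical-sac phantom carrying a divergence-free
recirculating vortex, and box-average + noise degradation mimicking the
resolution of each measurement modality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from skimage import measure

from .io_formats import StructuredVelocityField, TriSurface

__all__ = [
    "ModalitySpec",
    "PhantomSpec",
    "MODALITY_PRESETS",
    "make_poiseuille",
    "analytic_wss_poiseuille",
    "make_sac_phantom",
    "emulate_modality",
]

_MODALITY_NAMES = {"mri", "stereo_piv", "tomo_piv", "cfd"}


@dataclass(frozen=True)
class ModalitySpec:
    """Resolution/noise description of one acquisition modality.

    ``spacing`` is the vector pitch (m); ``noise_sd`` the additive
    Gaussian noise per velocity component (m/s); ``depth_averaging`` a
    slab thickness (m) averaged along z, mimicking a laser-sheet or
    slice-profile thickness.
    """

    name: str
    spacing: tuple[float, float, float]
    noise_sd: float = 0.0
    depth_averaging: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in _MODALITY_NAMES:
            raise ValueError(f"modality name must be one of {sorted(_MODALITY_NAMES)}")
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be strictly positive")
        if self.noise_sd < 0 or self.depth_averaging < 0:
            raise ValueError("noise_sd and depth_averaging must be >= 0")


#: Default modality presets, in phantom-scale (scaled-up) units.
#:
#: The PIV vector pitches are estimates derived from the published
#: interrogation-window areas/volumes (0.144 mm^2 in-plane with 1 mm
#: plane spacing for the stereo system; 0.25 mm^3 for the tomographic
#: one); exact pitch per axis is a config value, not a physical constant.
#: The MRI noise default is 5% of a 1.5 m/s velocity-encoding scale.
MODALITY_PRESETS: dict[str, ModalitySpec] = {
    "mri": ModalitySpec("mri", (0.47e-3, 0.47e-3, 0.5e-3), noise_sd=0.075),
    "stereo_piv": ModalitySpec("stereo_piv", (0.38e-3, 0.38e-3, 1.0e-3),
                               depth_averaging=1.0e-3),
    "tomo_piv": ModalitySpec("tomo_piv", (0.63e-3, 0.63e-3, 0.63e-3)),
    "cfd": ModalitySpec("cfd", (0.2e-3, 0.2e-3, 0.2e-3)),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and flow scales of the tube-plus-sac phantom.

    ``sac_center_offset`` is relative to the tube-axis midpoint; all
    lengths are multiplied by ``scale_factor`` at build time (the
    phantom-manufacturing scale-up).
    """

    tube_radius: float
    tube_length: float
    sac_radius: float
    sac_center_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    v_max: float = 1.0
    scale_factor: float = 1.0
    # Sac vortex peak speed as a fraction of v_max.  Kept well below 1 so
    # the phantom mimics a slow recirculating sac under a fast parent-vessel
    # flow (neck shear markedly above sac-average shear).
    sac_strength: float = 0.15

    def __post_init__(self) -> None:
        if self.tube_radius <= 0 or self.tube_length <= 0:
            raise ValueError("tube radii/length must be > 0")
        if self.sac_radius < 0:
            raise ValueError("sac_radius must be >= 0")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be > 0")


def _as_spacing(spacing) -> np.ndarray:
    s = np.asarray(spacing, dtype=float)
    if s.ndim == 0:
        s = np.repeat(s, 3)
    s = s.reshape(3)
    if np.any(s <= 0):
        raise ValueError("spacing must be strictly positive")
    return s


def analytic_wss_poiseuille(mu: float, v_max: float, tube_radius: float) -> float:
    """Exact wall shear stress of parabolic pipe flow: 2·mu·v_max/R (Pa)."""
    if mu <= 0 or v_max <= 0 or tube_radius <= 0:
        raise ValueError("mu, v_max and tube_radius must all be > 0")
    return 2.0 * mu * v_max / tube_radius


def _cylinder_surface(radius: float, z0: float, z1: float,
                      n_theta: int, n_z: int) -> TriSurface:
    """Open-ended cylinder wall triangulation around the z axis."""
    theta = np.linspace(0.0, 2.0 * math.pi, n_theta, endpoint=False)
    zs = np.linspace(z0, z1, n_z)
    ring = np.stack([radius * np.cos(theta), radius * np.sin(theta)], axis=1)
    verts = np.empty((n_theta * n_z, 3))
    for iz, z in enumerate(zs):
        verts[iz * n_theta:(iz + 1) * n_theta, :2] = ring
        verts[iz * n_theta:(iz + 1) * n_theta, 2] = z
    faces = []
    for iz in range(n_z - 1):
        for it in range(n_theta):
            a = iz * n_theta + it
            b = iz * n_theta + (it + 1) % n_theta
            c = a + n_theta
            d = b + n_theta
            faces.append((a, b, d))
            faces.append((a, d, c))
    return TriSurface(vertices=verts, faces=np.array(faces))


def make_poiseuille(
    tube_radius: float, tube_length: float, v_max: float, spacing,
) -> tuple[StructuredVelocityField, TriSurface]:
    """Parabolic pipe flow along z with a triangulated cylinder wall.

    Axial velocity ``u_z(r) = v_max (1 - r^2/R^2)`` for ``r <= R``,
    zero outside; the mask marks voxel centers with ``r <= R``.
    """
    h = _as_spacing(spacing)
    if max(h[:2]) >= tube_radius:
        raise ValueError(
            f"in-plane spacing {h[:2]} must be finer than tube_radius {tube_radius}"
        )
    R = tube_radius
    half = R + 2 * max(h[:2])
    nx = 2 * int(math.ceil(half / h[0])) + 1
    ny = 2 * int(math.ceil(half / h[1])) + 1
    nz = int(math.floor(tube_length / h[2])) + 1
    origin = np.array([-(nx - 1) / 2 * h[0], -(ny - 1) / 2 * h[1], 0.0])
    x = origin[0] + np.arange(nx) * h[0]
    y = origin[1] + np.arange(ny) * h[1]
    r2 = x[:, None] ** 2 + y[None, :] ** 2
    uz_profile = v_max * np.clip(1.0 - r2 / R**2, 0.0, None)
    mask2d = r2 <= R**2
    u = np.zeros((nx, ny, nz, 3))
    u[..., 2] = uz_profile[:, :, None]
    mask = np.repeat(mask2d[:, :, None], nz, axis=2)
    field = StructuredVelocityField(origin=origin, spacing=h, u=u, mask=mask)

    n_theta = max(24, int(math.ceil(2 * math.pi * R / min(h[:2]))))
    n_z = max(2, nz)
    surface = _cylinder_surface(R, 0.0, (nz - 1) * h[2], n_theta, n_z)
    return field, surface


# ---------------------------------------------------------------------------
# Tube + spherical-sac phantom
# ---------------------------------------------------------------------------

def _smootherstep(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """C^2 step 6t^5-15t^4+10t^3 on [0,1] and its derivative."""
    t = np.clip(t, 0.0, 1.0)
    s = t**3 * (6 * t**2 - 15 * t + 10)
    ds = 30 * t**2 * (t - 1) ** 2
    return s, ds


#: Fraction of the sac radius over which the vortex stream function is
#: faded to zero at the wall.  Wide enough that modest grids resolve the
#: blend shell (a thinner shell stays exactly divergence-free
#: analytically but stalls the discrete-divergence convergence).
BLEND_FRACTION = 0.3


def _sac_vortex(dx, dy, dz, a: float, peak_speed: float):
    """Divergence-free recirculation confined to a sphere of radius *a*.

    A spherical-vortex interior flow (axis along z) whose Stokes stream
    function is faded to zero over the outer ``BLEND_FRACTION`` shell by
    a C^2 blend, so the velocity field stays exactly divergence-free and
    vanishes continuously at the sac wall.
    """
    s2 = dx**2 + dy**2
    s = np.sqrt(s2)
    r = np.sqrt(s2 + dz**2)
    A = peak_speed / (2.0 * a**2)

    q = r / a
    t = (q - (1.0 - BLEND_FRACTION)) / BLEND_FRACTION
    step, dstep = _smootherstep(t)
    w = 1.0 - step
    dw = -dstep / (BLEND_FRACTION * a)  # dw/dr
    f = w * (a**2 - r**2)
    fp = dw * (a**2 - r**2) - 2.0 * r * w

    with np.errstate(invalid="ignore", divide="ignore"):
        fp_over_r = np.where(r > 0, fp / np.where(r == 0, 1.0, r), -2.0 * w)
    us = -A * s * fp_over_r * dz      # radial (cylindrical) component
    uz = 2.0 * A * f + A * s2 * fp_over_r
    with np.errstate(invalid="ignore", divide="ignore"):
        inv_s = np.where(s > 0, 1.0 / np.where(s == 0, 1.0, s), 0.0)
    ux = us * dx * inv_s
    uy = us * dy * inv_s
    inside = r < a
    return np.where(inside, ux, 0.0), np.where(inside, uy, 0.0), np.where(inside, uz, 0.0)


def make_sac_phantom(
    spec: PhantomSpec, spacing,
) -> tuple[StructuredVelocityField, TriSurface]:
    """Aneurysm-like phantom: straight tube with a sidewall spherical sac.

    The velocity field superposes clipped parabolic tube flow and the
    confined spherical vortex of :func:`_sac_vortex` inside the sac;
    both parts are divergence-free, so the composite is too.  The wall
    is extracted as the zero level of the union signed distance by
    marching cubes.  ``sac_radius == 0`` degenerates to
    :func:`make_poiseuille`.
    """
    sf = spec.scale_factor
    R = spec.tube_radius * sf
    L = spec.tube_length * sf
    a = spec.sac_radius * sf
    if a == 0.0:
        return make_poiseuille(R, L, spec.v_max, spacing)
    h = _as_spacing(spacing)
    off = np.asarray(spec.sac_center_offset, dtype=float) * sf
    center = np.array([off[0], off[1], L / 2 + off[2]])
    if math.hypot(center[0], center[1]) >= R + a:
        raise ValueError(
            "sac does not intersect the tube: |offset_xy| "
            f"{math.hypot(center[0], center[1]):.4g} >= R + sac_radius {R + a:.4g}"
        )

    pad = 2 * h
    lo = np.minimum([-R, -R, 0.0], center - a) - pad
    hi = np.maximum([R, R, L], center + a) + pad
    dims = np.maximum(np.ceil((hi - lo) / h).astype(int) + 1, 2)
    origin = lo
    x = origin[0] + np.arange(dims[0]) * h[0]
    y = origin[1] + np.arange(dims[1]) * h[1]
    z = origin[2] + np.arange(dims[2]) * h[2]
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")

    rt = np.sqrt(X**2 + Y**2)
    uz_tube = spec.v_max * np.clip(1.0 - (X**2 + Y**2) / R**2, 0.0, None)
    ux, uy, uz_sac = _sac_vortex(X - center[0], Y - center[1], Z - center[2],
                                 a, spec.sac_strength * spec.v_max)
    u = np.stack([ux, uy, uz_tube + uz_sac], axis=-1)

    r_sac = np.sqrt((X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2)
    sdf = np.minimum(rt - R, r_sac - a)
    mask = sdf <= 0.0
    field = StructuredVelocityField(origin=origin, spacing=h, u=u, mask=mask)

    verts, faces, _, _ = measure.marching_cubes(sdf, level=0.0, spacing=tuple(h))
    verts, faces = _drop_degenerate_faces(verts, faces.astype(np.int64))
    surface = TriSurface(vertices=verts + origin, faces=faces)
    return field, surface


def _drop_degenerate_faces(verts: np.ndarray, faces: np.ndarray):
    """Remove zero-area triangles (grid nodes lying exactly on the level set)
    and any vertices left unreferenced."""
    e1 = verts[faces[:, 1]] - verts[faces[:, 0]]
    e2 = verts[faces[:, 2]] - verts[faces[:, 0]]
    area2 = np.linalg.norm(np.cross(e1, e2), axis=1)
    faces = faces[area2 > 1e-12 * area2.max()]
    used = np.unique(faces)
    remap = np.full(len(verts), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return verts[used], remap[faces]


# ---------------------------------------------------------------------------
# Modality degradation
# ---------------------------------------------------------------------------

def _box_ranges(src_coords: np.ndarray, centers: np.ndarray, width: float,
                n_src: int) -> tuple[np.ndarray, np.ndarray]:
    """Half-open index ranges of source voxel centers inside each target box."""
    o = src_coords[0]
    h = src_coords[1] - src_coords[0] if n_src > 1 else 1.0
    lo = np.ceil((centers - width / 2 - o) / h - 1e-9).astype(int)
    hi = np.ceil((centers + width / 2 - o) / h - 1e-9).astype(int)
    return np.clip(lo, 0, n_src), np.clip(hi, 0, n_src)


def emulate_modality(
    field: StructuredVelocityField, modality: ModalitySpec, seed: int | None = None,
) -> StructuredVelocityField:
    """Degrade a fine field to a modality's resolution.

    Box-averages the source over each target voxel (with the z box
    widened to ``depth_averaging`` when larger than the z pitch), then
    adds i.i.d. Gaussian component noise with SD ``noise_sd``.  Non-lumen
    source voxels contribute zero velocity (stationary-wall partial
    volume).  A target voxel is lumen iff at least half of its
    contributing source voxels are.
    """
    h_src = field.spacing
    h_tgt = np.asarray(modality.spacing, dtype=float)
    if np.any(h_tgt < h_src - 1e-12):
        raise ValueError(
            f"modality spacing {h_tgt} must be >= field spacing {h_src} componentwise"
        )
    widths = h_tgt.copy()
    widths[2] = max(widths[2], modality.depth_averaging)

    dims_src = np.array(field.dims)
    extent = (dims_src - 1) * h_src
    dims_tgt = np.maximum(np.floor(extent / h_tgt + 1e-9).astype(int) + 1, 1)

    u_src = np.where(field.mask[..., None], field.u, 0.0)
    # integral images, zero-padded at index 0, for O(1) box sums
    cs_u = np.zeros((dims_src[0] + 1, dims_src[1] + 1, dims_src[2] + 1, 3))
    cs_u[1:, 1:, 1:] = u_src.cumsum(0).cumsum(1).cumsum(2)
    cs_m = np.zeros(dims_src + 1)
    cs_m[1:, 1:, 1:] = field.mask.astype(float).cumsum(0).cumsum(1).cumsum(2)

    ranges = []
    for ax in range(3):
        centers = field.origin[ax] + np.arange(dims_tgt[ax]) * h_tgt[ax]
        src_ax = field.axis_coords(ax)
        lo, hi = _box_ranges(src_ax, centers, widths[ax], dims_src[ax])
        ranges.append((lo, hi))

    def box_sum(cs: np.ndarray) -> np.ndarray:
        (lx, hx), (ly, hy), (lz, hz) = ranges
        def pick(ix, iy, iz):
            return cs[np.ix_(ix, iy, iz)]
        return (
            pick(hx, hy, hz) - pick(lx, hy, hz) - pick(hx, ly, hz) - pick(hx, hy, lz)
            + pick(lx, ly, hz) + pick(lx, hy, lz) + pick(hx, ly, lz) - pick(lx, ly, lz)
        )

    counts = 1.0
    for ax, (lo, hi) in enumerate(ranges):
        shape = [1, 1, 1]
        shape[ax] = dims_tgt[ax]
        counts = counts * np.maximum(hi - lo, 0).reshape(shape)
    counts = np.broadcast_to(counts, tuple(dims_tgt)).astype(float)

    u_sum = np.stack([box_sum(cs_u[..., c]) for c in range(3)], axis=-1)
    m_sum = box_sum(cs_m)
    with np.errstate(invalid="ignore", divide="ignore"):
        u_tgt = u_sum / np.where(counts > 0, counts, 1.0)[..., None]
    u_tgt[counts == 0] = 0.0
    mask_tgt = (counts > 0) & (m_sum >= 0.5 * counts)

    if modality.noise_sd > 0:
        rng = np.random.default_rng(seed)
        u_tgt = u_tgt + rng.normal(0.0, modality.noise_sd, size=u_tgt.shape)

    return StructuredVelocityField(
        origin=field.origin.copy(), spacing=h_tgt, u=u_tgt, mask=mask_tgt
    )
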