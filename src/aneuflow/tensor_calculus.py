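"""Velocity-gradient tensor and derived quantities on masked structured grids.

Derivatives use central differences where both axis neighbors are lumen,
first-order one-sided differences where only one neighbor is lumen, and
mark the voxel invalid along that axis otherwise.  One-sided stencils at
mask boundaries are kept (rather than discarding boundary voxels) because
near-wall gradients drive the wall shear stress.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import StructuredVelocityField
from .similarity_scaling import SimilaritySpec

__all__ = [
    "GradientField",
    "DeformationSplit",
    "gradient_tensor",
    "deformation_split",
    "vorticity",
    "vorticity_z_scaled",
    "q_criterion",
    "divergence",
]


@dataclass
class GradientField:
    """Per-voxel velocity-gradient tensor.

    ``g[..., i, j] = du_i/dx_j`` in 1/s; ``valid`` is False where the
    difference stencil left the lumen mask on some axis.
    """

    g: np.ndarray          # (nx, ny, nz, 3, 3)
    valid: np.ndarray      # (nx, ny, nz) bool
    spacing: np.ndarray
    origin: np.ndarray
    mask: np.ndarray       # lumen mask of the source field

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.g.shape[:3]


@dataclass
class DeformationSplit:
    """Symmetric (rate-of-deformation) and antisymmetric (rotation) parts."""

    S: np.ndarray
    W: np.ndarray


def _shift(arr: np.ndarray, axis: int, step: int, fill) -> np.ndarray:
    """Return arr sampled at index+step along axis, padded with *fill*."""
    out = np.full_like(arr, fill)
    n = arr.shape[axis]
    src = [slice(None)] * arr.ndim
    dst = [slice(None)] * arr.ndim
    if step > 0:
        src[axis] = slice(step, n)
        dst[axis] = slice(0, n - step)
    else:
        src[axis] = slice(0, n + step)
        dst[axis] = slice(-step, n)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def gradient_tensor(field: StructuredVelocityField) -> GradientField:
    """Finite-difference velocity-gradient tensor on the lumen mask.

    Exact (to round-off) on affine velocity fields wherever the central
    stencil applies; first-order one-sided at mask boundaries.
    """
    if min(field.dims) < 2:
        raise ValueError(f"need >= 2 voxels along every axis, got dims {field.dims}")
    nx, ny, nz = field.dims
    g = np.zeros((nx, ny, nz, 3, 3))
    valid = field.mask.copy()
    u = np.where(field.mask[..., None], field.u, 0.0)
    for axis in range(3):
        h = field.spacing[axis]
        mp = _shift(field.mask, axis, +1, False)
        mm = _shift(field.mask, axis, -1, False)
        up = _shift(u, axis, +1, 0.0)
        um = _shift(u, axis, -1, 0.0)
        central = mp & mm
        fwd = mp & ~mm
        bwd = ~mp & mm
        d = np.zeros_like(u)
        d[central] = (up[central] - um[central]) / (2 * h)
        d[fwd] = (up[fwd] - u[fwd]) / h
        d[bwd] = (u[bwd] - um[bwd]) / h
        g[..., :, axis] = d
        valid &= (mp | mm)
    g[~valid] = 0.0
    return GradientField(
        g=g, valid=valid, spacing=field.spacing.copy(),
        origin=field.origin.copy(), mask=field.mask.copy(),
    )


def deformation_split(G: GradientField | np.ndarray) -> DeformationSplit:
    """Split g into S = (g + g^T)/2 and W = (g - g^T)/2 per voxel."""
    g = G.g if isinstance(G, GradientField) else np.asarray(G)
    gt = np.swapaxes(g, -1, -2)
    return DeformationSplit(S=(g + gt) / 2.0, W=(g - gt) / 2.0)


def vorticity(G: GradientField) -> np.ndarray:
    """Curl of the velocity field, per voxel, 1/s; shape (..., 3)."""
    g = G.g
    wx = g[..., 2, 1] - g[..., 1, 2]
    wy = g[..., 0, 2] - g[..., 2, 0]
    wz = g[..., 1, 0] - g[..., 0, 1]
    return np.stack([wx, wy, wz], axis=-1)


def vorticity_z_scaled(G: GradientField, sim: SimilaritySpec) -> np.ndarray:
    """Out-of-plane vorticity rescaled by the inlet velocity and size ratios.

    omega_z · (u_vivo/u_vitro) · (d_vitro/d_vivo), making phantom-frame
    vorticity comparable with the patient-scale measurement.
    """
    wz = G.g[..., 1, 0] - G.g[..., 0, 1]
    return wz * sim.u_ratio * sim.d_ratio


def q_criterion(G: GradientField) -> np.ndarray:
    """Q = (||W||^2 - ||S||^2)/2 with Frobenius norms, per voxel, 1/s^2.

    Positive where rotation dominates strain (vortex cores).
    """
    split = deformation_split(G)
    s2 = np.sum(split.S**2, axis=(-2, -1))
    w2 = np.sum(split.W**2, axis=(-2, -1))
    return 0.5 * (w2 - s2)


def divergence(G: GradientField) -> np.ndarray:
    """Trace of the gradient tensor (discrete div u), per voxel, 1/s."""
    return np.trace(G.g, axis1=-2, axis2=-1)
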