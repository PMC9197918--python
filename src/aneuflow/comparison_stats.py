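"""Resolution matching and agreement statistics between modalities.

Velocity normalization by a reference speed, trilinear down-sampling to
a coarser grid, line-profile extraction, Pearson correlation of
profiles, and Bland–Altman limits-of-agreement analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import StructuredVelocityField

__all__ = [
    "ProfileLine",
    "BlandAltmanResult",
    "normalize_velocity",
    "downsample",
    "resample_like",
    "extract_profile",
    "pearson",
    "bland_altman",
    "proportional_bias",
]


@dataclass
class ProfileLine:
    """Equally spaced samples of velocity magnitude along a straight line.

    Samples falling outside the lumen are NaN ("missing").
    """

    start: np.ndarray
    end: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float).reshape(3)
        self.end = np.asarray(self.end, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        if self.n_samples < 2:
            raise ValueError("a profile needs at least 2 samples")

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def points(self) -> np.ndarray:
        t = np.linspace(0.0, 1.0, self.n_samples)[:, None]
        return self.start + t * (self.end - self.start)


@dataclass(frozen=True)
class BlandAltmanResult:
    """Mean difference, SD of differences and 1.96-SD limits of agreement."""

    mean_diff: float
    sd: float
    loa_low: float
    loa_high: float
    pairs: int
    means: np.ndarray = None
    diffs: np.ndarray = None


# ---------------------------------------------------------------------------
# Field operations
# ---------------------------------------------------------------------------

def normalize_velocity(field: StructuredVelocityField, v_ref: float) -> StructuredVelocityField:
    """Divide every velocity component by a reference speed (> 0)."""
    if v_ref <= 0:
        raise ValueError("v_ref must be > 0")
    out = field.copy()
    out.u /= v_ref
    return out


def _trilinear_weights(field: StructuredVelocityField, points: np.ndarray):
    """Corner indices/weights and the strict all-8-corners-lumen flag."""
    rel = (points - field.origin) / field.spacing
    dims = np.array(field.dims)
    i0 = np.floor(rel).astype(int)
    frac = rel - i0
    inb = np.all((i0 >= 0) & (i0 + 1 <= dims - 1), axis=1)
    i0c = np.clip(i0, 0, np.maximum(dims - 2, 0))
    return i0c, frac, inb


def _sample_trilinear(field: StructuredVelocityField, values: np.ndarray,
                      points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear interpolation of per-voxel *values* at arbitrary points.

    Returns ``(sampled, inside)`` where ``inside`` is True only when the
    point lies in a cell whose 8 corners are all in-bounds and lumen.
    """
    i0, frac, inb = _trilinear_weights(field, points)
    res = np.zeros((len(points),) + values.shape[3:])
    all_lumen = np.ones(len(points), dtype=bool)
    for dx in (0, 1):
        wx = np.where(dx, frac[:, 0], 1 - frac[:, 0])
        for dy in (0, 1):
            wy = np.where(dy, frac[:, 1], 1 - frac[:, 1])
            for dz in (0, 1):
                wz = np.where(dz, frac[:, 2], 1 - frac[:, 2])
                ii = np.clip(i0[:, 0] + dx, 0, field.dims[0] - 1)
                jj = np.clip(i0[:, 1] + dy, 0, field.dims[1] - 1)
                kk = np.clip(i0[:, 2] + dz, 0, field.dims[2] - 1)
                w = wx * wy * wz
                res += values[ii, jj, kk] * w.reshape((-1,) + (1,) * (values.ndim - 3))
                all_lumen &= field.mask[ii, jj, kk]
    inside = inb & all_lumen
    return res, inside


def downsample(field: StructuredVelocityField, target_spacing) -> StructuredVelocityField:
    """Resample to a coarser grid by trilinear interpolation.

    Target voxels are lumen only when all 8 enclosing source corners
    are; exact on affine fields at every in-lumen target center.
    """
    h_tgt = np.asarray(target_spacing, dtype=float)
    if h_tgt.ndim == 0:
        h_tgt = np.repeat(h_tgt, 3)
    h_tgt = h_tgt.reshape(3)
    if np.any(h_tgt < field.spacing - 1e-12):
        raise ValueError(
            f"target spacing {h_tgt} must be >= source spacing {field.spacing}"
        )
    extent = (np.array(field.dims) - 1) * field.spacing
    dims_tgt = np.floor(extent / h_tgt + 1e-9).astype(int) + 1
    if np.any(dims_tgt < 1):
        raise ValueError("target grid is empty")
    axes = [field.origin[a] + np.arange(dims_tgt[a]) * h_tgt[a] for a in range(3)]
    XX, YY, ZZ = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([XX.ravel(), YY.ravel(), ZZ.ravel()], axis=-1)
    u, inside = _sample_trilinear(field, field.u, pts)
    u_tgt = u.reshape((*dims_tgt, 3))
    mask_tgt = inside.reshape(tuple(dims_tgt))
    u_tgt[~mask_tgt] = 0.0
    return StructuredVelocityField(
        origin=field.origin.copy(), spacing=h_tgt, u=u_tgt, mask=mask_tgt
    )


def resample_like(field: StructuredVelocityField,
                  template: StructuredVelocityField) -> StructuredVelocityField:
    """Trilinearly sample *field* at the voxel centers of *template*'s grid."""
    axes = [template.axis_coords(a) for a in range(3)]
    XX, YY, ZZ = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([XX.ravel(), YY.ravel(), ZZ.ravel()], axis=-1)
    u, inside = _sample_trilinear(field, field.u, pts)
    u_tgt = u.reshape((*template.dims, 3))
    mask_tgt = inside.reshape(template.dims)
    u_tgt[~mask_tgt] = 0.0
    return StructuredVelocityField(
        origin=template.origin.copy(), spacing=template.spacing.copy(),
        u=u_tgt, mask=mask_tgt,
    )


def extract_profile(
    field: StructuredVelocityField, start, end, n_samples: int,
) -> ProfileLine:
    """Velocity magnitude sampled trilinearly along a line segment.

    Samples outside the lumen are NaN; raises if every sample is.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    start = np.asarray(start, dtype=float).reshape(3)
    end = np.asarray(end, dtype=float).reshape(3)
    t = np.linspace(0.0, 1.0, n_samples)[:, None]
    pts = start + t * (end - start)
    mag, inside = _sample_trilinear(field, field.magnitude[..., None], pts)
    values = np.where(inside, mag[:, 0], np.nan)
    if not np.any(inside):
        raise ValueError("profile line lies entirely outside the lumen")
    return ProfileLine(start=start, end=end, values=values)


# ---------------------------------------------------------------------------
# Agreement statistics
# ---------------------------------------------------------------------------

def _shared(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    keep = np.isfinite(a) & np.isfinite(b)
    return a[keep], b[keep]


def pearson(a: ProfileLine, b: ProfileLine) -> float:
    """Sample Pearson correlation over shared non-missing samples."""
    if a.n_samples != b.n_samples:
        raise ValueError(
            f"profiles have different sample counts: {a.n_samples} vs {b.n_samples}"
        )
    va, vb = _shared(a.values, b.values)
    if len(va) < 2:
        raise ValueError("need at least 2 shared non-missing samples")
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("undefined correlation: zero variance in a profile")
    return float(stats.pearsonr(va, vb).statistic)


def bland_altman(a, b) -> BlandAltmanResult:
    """Bland–Altman agreement of paired values.

    diffs = a - b; limits of agreement are mean_diff +- 1.96 * SD with
    the sample (n-1) standard deviation.  Non-finite pairs are dropped.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    a, b = _shared(a, b)
    if len(a) < 2:
        raise ValueError("need at least 2 finite pairs")
    diffs = a - b
    means = (a + b) / 2.0
    mean_diff = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd=sd,
        loa_low=mean_diff - 1.96 * sd,
        loa_high=mean_diff + 1.96 * sd,
        pairs=len(a),
        means=means,
        diffs=diffs,
    )


def proportional_bias(result: BlandAltmanResult) -> float:
    """Least-squares slope of difference against pair mean.

    Descriptive trend statistic for whether disagreement grows with
    magnitude; needs >= 3 pairs and non-degenerate mean variance.
    """
    if result.pairs < 3:
        raise ValueError("proportional bias needs at least 3 pairs")
    x = result.means
    y = result.diffs
    if np.ptp(x) == 0:
        raise ValueError("undefined slope: pair means have zero variance")
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)
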