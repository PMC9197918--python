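"""Core data containers and file I/O.

Internal units are SI throughout (m, m/s, Pa, Pa·s).  Readers accept a
``units`` hint (``"m"`` or ``"mm"``) and convert lengths on load.

Supported formats
-----------------
* STL triangle meshes, binary and ASCII dialects.
* VTK legacy STRUCTURED_POINTS (ASCII) carrying a 3-component vector
  array and an optional integer mask scalar.
* A CSV grid dialect with header ``i,j,k,x,y,z,ux,uy,uz,mask``.
* Plain CSV tables ('.' decimal, ',' separator, header row).

Grid convention: index ``(i, j, k)`` maps to axes ``(x, y, z)``,
0-based, with voxel centers at ``origin + index * spacing``.
"""

from __future__ import annotations

import configparser
import csv
import io
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "StructuredVelocityField",
    "TriSurface",
    "PipelineConfig",
    "FormatError",
    "read_stl",
    "write_stl",
    "read_velocity_grid",
    "write_velocity_grid",
    "write_table",
    "read_table",
    "load_config",
]

_LEN_SCALE = {"m": 1.0, "mm": 1e-3}


class FormatError(ValueError):
    """Raised when a file does not conform to its declared format."""


def _length_scale(units: str) -> float:
    try:
        return _LEN_SCALE[units]
    except KeyError:
        raise ValueError(f"unknown length unit {units!r}; expected one of {sorted(_LEN_SCALE)}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class StructuredVelocityField:
    """Regular-grid, three-component velocity field with a lumen mask.

    Attributes
    ----------
    origin : (3,) float array, m
        Position of the voxel center at index (0, 0, 0).
    spacing : (3,) float array, m/voxel, strictly positive.
    u : (nx, ny, nz, 3) float array, m/s
        Velocity components (ux, uy, uz) at voxel centers.
    mask : (nx, ny, nz) bool array
        True where the voxel is lumen (valid fluid).
    """

    origin: np.ndarray
    spacing: np.ndarray
    u: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 4 or self.u.shape[-1] != 3:
            raise ValueError(f"u must have shape (nx, ny, nz, 3), got {self.u.shape}")
        if self.mask is None:
            self.mask = np.ones(self.u.shape[:3], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.u.shape[:3]:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match field dims {self.u.shape[:3]}"
            )
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.u[self.mask])):
            raise ValueError("masked-true voxels must carry finite velocity values")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.u.shape[:3]

    def voxel_centers(self) -> np.ndarray:
        """Voxel-center coordinates, shape (nx, ny, nz, 3)."""
        axes = [self.origin[a] + np.arange(self.dims[a]) * self.spacing[a] for a in range(3)]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        return np.stack([xx, yy, zz], axis=-1)

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + np.arange(self.dims[axis]) * self.spacing[axis]

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.u, axis=-1)

    def copy(self) -> "StructuredVelocityField":
        return StructuredVelocityField(
            self.origin.copy(), self.spacing.copy(), self.u.copy(), self.mask.copy()
        )


@dataclass
class TriSurface:
    """Triangulated lumen wall.

    ``normals`` are per-vertex unit vectors; ``inward`` records the
    orientation convention (True once normals have been oriented toward
    the lumen interior by :func:`aneuflow.wall_shear.compute_vertex_normals`).
    """

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray | None = None
    inward: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)
            if len(self.normals) != len(self.vertices):
                raise ValueError("normals must be per-vertex")
            norms = np.linalg.norm(self.normals, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("normals must have unit length within 1e-6")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_normals_areas(self) -> tuple[np.ndarray, np.ndarray]:
        """Raw face normals (from winding) and triangle areas."""
        v = self.vertices
        e1 = v[self.faces[:, 1]] - v[self.faces[:, 0]]
        e2 = v[self.faces[:, 2]] - v[self.faces[:, 0]]
        cross = np.cross(e1, e2)
        area2 = np.linalg.norm(cross, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            n = np.where(area2[:, None] > 0, cross / np.where(area2 == 0, 1, area2)[:, None], 0.0)
        return n, 0.5 * area2


@dataclass
class PipelineConfig:
    """Bundle of knobs consumed by the CLI."""

    fluid_density: float = 1060.0
    fluid_viscosity: float = 0.0035
    modality: str = "cfd"
    idw_power: float = 2.0
    idw_neighbors: int = 8
    output: str | None = None

    def __post_init__(self) -> None:
        if self.idw_power <= 0:
            raise ValueError("idw_power must be > 0")
        if self.idw_neighbors < 1:
            raise ValueError("idw_neighbors must be >= 1")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a flat ``key = value`` or INI-style config file."""
    text = Path(path).read_text()
    parser = configparser.ConfigParser()
    try:
        parser.read_string(text)
        flat: dict[str, str] = {}
        for section in parser.sections():
            flat.update(parser[section])
        flat.update(parser.defaults())
    except configparser.MissingSectionHeaderError:
        parser.read_string("[root]\n" + text)
        flat = dict(parser["root"])
    kwargs: dict = {}
    for key in ("fluid_density", "fluid_viscosity", "idw_power"):
        if key in flat:
            kwargs[key] = float(flat[key])
    if "idw_neighbors" in flat:
        kwargs["idw_neighbors"] = int(flat["idw_neighbors"])
    for key in ("modality", "output"):
        if key in flat:
            kwargs[key] = flat[key]
    return PipelineConfig(**kwargs)


# ---------------------------------------------------------------------------
# STL
# ---------------------------------------------------------------------------

_BIN_TRI = struct.Struct("<12fH")  # normal, 3 vertices, attribute count


def _dedup_vertices(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse exactly-equal coordinate triples; returns (unique, face indices)."""
    seen: dict[tuple[float, float, float], int] = {}
    index = np.empty(len(raw), dtype=np.int64)
    verts: list[tuple[float, float, float]] = []
    for i, p in enumerate(raw):
        key = (float(p[0]), float(p[1]), float(p[2]))
        j = seen.get(key)
        if j is None:
            j = len(verts)
            seen[key] = j
            verts.append(key)
        index[i] = j
    return np.array(verts, dtype=float).reshape(-1, 3), index.reshape(-1, 3)


def read_stl(path: str | Path, units: str = "m") -> TriSurface:
    """Read a binary or ASCII STL file.

    Vertices are deduplicated by exact coordinate equality.  Normals are
    left unset; compute them with
    :func:`aneuflow.wall_shear.compute_vertex_normals`.
    """
    scale = _length_scale(units)
    data = Path(path).read_bytes()
    if _looks_ascii_stl(data):
        raw = _parse_ascii_stl(data.decode("ascii", errors="replace"))
    else:
        raw = _parse_binary_stl(data)
    vertices, faces = _dedup_vertices(raw * scale)
    return TriSurface(vertices=vertices, faces=faces)


def _looks_ascii_stl(data: bytes) -> bool:
    head = data[:512].lstrip()
    if not head.startswith(b"solid"):
        return False
    # Binary files sometimes start with "solid" in the 80-byte header;
    # a genuine ASCII file must mention "facet" somewhere.
    return b"facet" in data[:2048] or b"endsolid" in data


def _parse_ascii_stl(text: str) -> np.ndarray:
    pts: list[list[float]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        tokens = line.split()
        if not tokens:
            continue
        if tokens[0] == "vertex":
            if len(tokens) != 4:
                raise FormatError(f"malformed vertex line {lineno}: {line.strip()!r}")
            pts.append([float(t) for t in tokens[1:]])
    if len(pts) % 3 != 0:
        raise FormatError(f"ASCII STL vertex count {len(pts)} is not a multiple of 3")
    return np.asarray(pts, dtype=float)


def _parse_binary_stl(data: bytes) -> np.ndarray:
    if len(data) < 84:
        raise FormatError(f"binary STL truncated at byte {len(data)}: header needs 84 bytes")
    (count,) = struct.unpack_from("<I", data, 80)
    expected = 84 + 50 * count
    if len(data) != expected:
        raise FormatError(
            f"binary STL triangle count mismatch: header declares {count} triangles "
            f"({expected} bytes) but file has {len(data)} bytes (error at byte offset 80)"
        )
    raw = np.empty((3 * count, 3), dtype=float)
    for t in range(count):
        rec = _BIN_TRI.unpack_from(data, 84 + 50 * t)
        raw[3 * t] = rec[3:6]
        raw[3 * t + 1] = rec[6:9]
        raw[3 * t + 2] = rec[9:12]
    return raw


def write_stl(surface: TriSurface, path: str | Path, dialect: str = "binary") -> None:
    """Write *surface* as STL; ``dialect`` is ``"binary"`` or ``"ascii"``.

    Note the STL format stores float32 coordinates: vertices not exactly
    representable in single precision are rounded on write.
    """
    v = surface.vertices
    f = surface.faces
    fn, _ = surface.face_normals_areas()
    if dialect == "binary":
        buf = io.BytesIO()
        buf.write(b"aneuflow binary STL".ljust(80, b" "))
        buf.write(struct.pack("<I", len(f)))
        for i, tri in enumerate(f):
            buf.write(
                _BIN_TRI.pack(
                    *fn[i], *v[tri[0]], *v[tri[1]], *v[tri[2]], 0
                )
            )
        Path(path).write_bytes(buf.getvalue())
    elif dialect == "ascii":
        lines = ["solid aneuflow"]
        for i, tri in enumerate(f):
            lines.append(f"  facet normal {_g(fn[i][0])} {_g(fn[i][1])} {_g(fn[i][2])}")
            lines.append("    outer loop")
            for vid in tri:
                p = np.float32(v[vid])  # match binary dialect precision
                lines.append(f"      vertex {_g(p[0])} {_g(p[1])} {_g(p[2])}")
            lines.append("    endloop")
            lines.append("  endfacet")
        lines.append("endsolid aneuflow")
        Path(path).write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown STL dialect {dialect!r}")


def _g(x: float) -> str:
    """Shortest decimal string that round-trips a float."""
    return repr(float(x))


# ---------------------------------------------------------------------------
# Velocity grids: VTK legacy structured points (ASCII) and CSV dialect
# ---------------------------------------------------------------------------

def read_velocity_grid(path: str | Path, units: str = "m") -> StructuredVelocityField:
    """Read a velocity grid from VTK legacy structured points or the CSV dialect.

    The dialect is sniffed from the first line.  An absent mask array
    yields an all-true mask.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# vtk"):
        return _read_vtk_grid(path, units)
    return _read_csv_grid(path, units)


def _read_vtk_grid(path: Path, units: str) -> StructuredVelocityField:
    scale = _length_scale(units)
    lines = Path(path).read_text().splitlines()
    it = iter(enumerate(lines, start=1))
    dims = origin = spacing = None
    vectors = None
    mask = None
    npoints = None

    def tokens_after(n_needed: int, start_line: int) -> list[str]:
        toks: list[str] = []
        for _, ln in it:
            toks.extend(ln.split())
            if len(toks) >= n_needed:
                return toks
        raise FormatError(
            f"unexpected end of file after line {start_line}: needed {n_needed} values"
        )

    for lineno, line in it:
        parts = line.split()
        if not parts:
            continue
        key = parts[0].upper()
        if key == "DATASET":
            if parts[1].upper() != "STRUCTURED_POINTS":
                raise FormatError(f"line {lineno}: unsupported dataset {parts[1]!r}")
        elif key == "DIMENSIONS":
            dims = tuple(int(p) for p in parts[1:4])
        elif key == "ORIGIN":
            origin = np.array([float(p) for p in parts[1:4]]) * scale
        elif key == "SPACING":
            spacing = np.array([float(p) for p in parts[1:4]]) * scale
        elif key == "POINT_DATA":
            npoints = int(parts[1])
        elif key == "VECTORS":
            if dims is None or npoints is None:
                raise FormatError(f"line {lineno}: VECTORS before DIMENSIONS/POINT_DATA")
            vals = tokens_after(3 * npoints, lineno)
            vectors = np.array([float(t) for t in vals[: 3 * npoints]], dtype=float)
        elif key == "SCALARS":
            name = parts[1]
            vals = None
            for lineno2, ln in it:  # skip LOOKUP_TABLE line
                if ln.split() and ln.split()[0].upper() == "LOOKUP_TABLE":
                    break
            vals = tokens_after(npoints, lineno)
            arr = np.array([float(t) for t in vals[:npoints]])
            if name.lower() == "mask":
                mask = arr
    if dims is None or origin is None or spacing is None:
        raise FormatError("missing DIMENSIONS/ORIGIN/SPACING header")
    if vectors is None:
        raise FormatError("missing vector array (VECTORS) in VTK file")
    nx, ny, nz = dims
    if npoints != nx * ny * nz:
        raise FormatError(
            f"POINT_DATA count {npoints} inconsistent with DIMENSIONS {dims}"
        )
    # VTK point order: x varies fastest -> Fortran order for (nx, ny, nz)
    u = vectors.reshape(npoints, 3).reshape((nx, ny, nz, 3), order="F")
    m = None
    if mask is not None:
        m = (mask.reshape((nx, ny, nz), order="F") != 0)
    return StructuredVelocityField(origin=origin, spacing=spacing, u=u, mask=m)


_CSV_HEADER = ["i", "j", "k", "x", "y", "z", "ux", "uy", "uz", "mask"]


def _read_csv_grid(path: Path, units: str) -> StructuredVelocityField:
    scale = _length_scale(units)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != _CSV_HEADER:
            raise FormatError(
                f"CSV grid header must be {','.join(_CSV_HEADER)!r}, got {header!r}"
            )
        rows = [r for r in reader if r]
    if not rows:
        raise FormatError("CSV grid has no data rows")
    idx = np.array([[int(r[0]), int(r[1]), int(r[2])] for r in rows])
    xyz = np.array([[float(r[3]), float(r[4]), float(r[5])] for r in rows]) * scale
    uvw = np.array([[float(r[6]), float(r[7]), float(r[8])] for r in rows])
    msk = np.array([int(float(r[9])) for r in rows]) != 0
    dims = idx.max(axis=0) + 1
    if len(rows) != int(np.prod(dims)):
        raise FormatError(
            f"CSV grid has {len(rows)} rows but indices imply dims {tuple(dims)}"
        )
    u = np.full((*dims, 3), np.nan)
    mask = np.zeros(tuple(dims), dtype=bool)
    u[idx[:, 0], idx[:, 1], idx[:, 2]] = uvw
    mask[idx[:, 0], idx[:, 1], idx[:, 2]] = msk
    # recover origin/spacing from coordinate columns
    origin = np.empty(3)
    spacing = np.empty(3)
    for a in range(3):
        at0 = idx[:, a] == 0
        origin[a] = xyz[at0, a][0]
        if dims[a] > 1:
            at1 = idx[:, a] == 1
            spacing[a] = xyz[at1, a][0] - origin[a]
        else:
            spacing[a] = 1.0 * scale
    return StructuredVelocityField(origin=origin, spacing=spacing, u=u, mask=mask)


def write_velocity_grid(
    field: StructuredVelocityField, path: str | Path, dialect: str = "vtk",
    extra_scalars: Mapping[str, np.ndarray] | None = None,
) -> None:
    """Write a velocity grid losslessly (double precision survives a round-trip).

    ``extra_scalars`` maps array names to per-voxel scalars, written as
    additional SCALARS arrays in the VTK dialect (ignored for CSV).
    """
    path = Path(path)
    if dialect == "vtk":
        _write_vtk_grid(field, path, extra_scalars or {})
    elif dialect == "csv":
        _write_csv_grid(field, path)
    else:
        raise ValueError(f"unknown grid dialect {dialect!r}")


def _write_vtk_grid(
    field: StructuredVelocityField, path: Path, extra: Mapping[str, np.ndarray]
) -> None:
    nx, ny, nz = field.dims
    n = nx * ny * nz
    out = io.StringIO()
    out.write("# vtk DataFile Version 3.0\n")
    out.write("aneuflow velocity grid\n")
    out.write("ASCII\n")
    out.write("DATASET STRUCTURED_POINTS\n")
    out.write(f"DIMENSIONS {nx} {ny} {nz}\n")
    out.write(f"ORIGIN {_g(field.origin[0])} {_g(field.origin[1])} {_g(field.origin[2])}\n")
    out.write(f"SPACING {_g(field.spacing[0])} {_g(field.spacing[1])} {_g(field.spacing[2])}\n")
    out.write(f"POINT_DATA {n}\n")
    out.write("VECTORS velocity double\n")
    flat = field.u.reshape((n, 3), order="F")
    for row in flat:
        out.write(f"{_g(row[0])} {_g(row[1])} {_g(row[2])}\n")
    out.write("SCALARS mask int 1\nLOOKUP_TABLE default\n")
    for v in field.mask.astype(int).flatten(order="F"):
        out.write(f"{v}\n")
    for name, arr in extra.items():
        arr = np.asarray(arr, dtype=float)
        if arr.shape != field.dims:
            raise ValueError(f"extra scalar {name!r} shape {arr.shape} != dims {field.dims}")
        out.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
        for v in arr.flatten(order="F"):
            out.write(f"{_g(v)}\n")
    path.write_text(out.getvalue())


def _write_csv_grid(field: StructuredVelocityField, path: Path) -> None:
    nx, ny, nz = field.dims
    centers = field.voxel_centers()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_HEADER)
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    p = centers[i, j, k]
                    u = field.u[i, j, k]
                    w.writerow(
                        [i, j, k, _g(p[0]), _g(p[1]), _g(p[2]),
                         _g(u[0]), _g(u[1]), _g(u[2]), int(field.mask[i, j, k])]
                    )


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_table(rows: Sequence[Mapping[str, object]], path: str | Path,
                columns: Sequence[str] | None = None) -> None:
    """Write dict rows to CSV; '.' decimal, ',' separator, header row.

    An empty row list produces a header-only file (``columns`` required
    then, else a bare newline header).
    """
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(columns)
        for row in rows:
            w.writerow([_fmt_cell(row.get(c, "")) for c in columns])


def _fmt_cell(v: object) -> object:
    if isinstance(v, float) or isinstance(v, np.floating):
        return _g(float(v))
    return v


def read_table(path: str | Path) -> list[dict[str, str]]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))
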