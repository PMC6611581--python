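"""Height-map data model, text I/O, preprocessing, and mesh export.

A height map is a rectangular grid of surface heights z(x, y) in micrometres
sampled at a uniform lateral step (profilometer-style data).  Heights are kept
in μm internally; mesh export converts to mm for fabrication.

Two plain-text dialects are supported:

``ascii-grid``
    A three-line header followed by whitespace-separated rows::

        PERISURF-GRID 1
        <rows> <cols>
        step_x=<μm> step_y=<μm> units=um sentinel=<value>

    Cells equal to the sentinel are invalid (missing) points.

``csv-matrix``
    A bare matrix of comma-separated heights.  Step sizes come from a sidecar
    file ``<path>.meta`` with ``key=value`` lines (``step_x``, ``step_y``,
    optional ``sentinel``), or from keyword arguments.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import griddata

__all__ = [
    "HeightMap",
    "MeshExport",
    "FormatError",
    "ConfigurationError",
    "MissingDataError",
    "read_heightmap",
    "write_heightmap",
    "preprocess",
    "export_mesh",
]

DEFAULT_SENTINEL = -999999.0
_MAGIC = "PERISURF-GRID 1"


class FormatError(ValueError):
    """Raised when a height-map file does not parse as a rectangular grid."""


class ConfigurationError(ValueError):
    """Raised when required metadata (step sizes) is missing."""


class MissingDataError(ValueError):
    """Raised when a scan has too many missing points to be usable."""


@dataclass
class HeightMap:
    """Rectangular grid of surface heights with lateral sampling metadata.

    Parameters
    ----------
    heights : ndarray, shape (rows, cols)
        Surface heights in μm.  Invalid entries may hold any value; validity
        is carried by `valid_mask`.
    step_x, step_y : float
        Lateral sample spacing along columns (x) and rows (y), μm.
    valid_mask : ndarray of bool, optional
        True where the point is a real measurement.  Defaults to all-valid.
    origin_note : str
        Free-text provenance.
    """

    heights: np.ndarray
    step_x: float
    step_y: float
    valid_mask: np.ndarray = None
    origin_note: str = ""

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2 or self.heights.size == 0:
            raise ValueError("heights must be a non-empty 2-D grid")
        if not (self.step_x > 0 and self.step_y > 0):
            raise ValueError("step sizes must be positive")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.heights.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.heights.shape:
                raise ValueError("valid_mask shape must match heights")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def missing_fraction(self) -> float:
        """Fraction of grid points that are invalid."""
        return 1.0 - self.valid_mask.mean()

    @property
    def cell_area(self) -> float:
        """Area of one sample cell, μm²."""
        return self.step_x * self.step_y

    @property
    def eval_area(self) -> float:
        """Evaluation area A(N) of the full grid, μm²."""
        return self.heights.size * self.cell_area

    def z(self) -> np.ndarray:
        """Valid heights as a flat array."""
        return self.heights[self.valid_mask]

    def copy_with(self, **kw) -> "HeightMap":
        return replace(self, **kw)


@dataclass
class MeshExport:
    """Watertight triangle mesh of a height map on a closed base.

    Attributes
    ----------
    mesh : trimesh.Trimesh
        Watertight solid; top-surface vertex heights equal the height map's
        values after unit conversion.
    units : str
        Linear unit of the mesh coordinates.
    base_thickness : float
        Base slab thickness below the lowest surface point (mesh units).
    """

    mesh: "object"
    units: str = "mm"
    base_thickness: float = 7.0

    @property
    def is_watertight(self) -> bool:
        return bool(self.mesh.is_watertight)

    def save_stl(self, path: str) -> None:
        self.mesh.export(path, file_type="stl")


# ---------------------------------------------------------------------------
# I/O


def _parse_meta_lines(lines) -> dict:
    out = {}
    for ln in lines:
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        for tok in ln.split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                out[k.strip()] = v.strip()
    return out


def _load_matrix(lines, sep=None) -> np.ndarray:
    rows = []
    for ln in lines:
        ln = ln.strip()
        if not ln:
            continue
        parts = ln.split(sep) if sep else ln.split()
        try:
            rows.append([float(p) for p in parts])
        except ValueError as e:
            raise FormatError(f"non-numeric entry in height matrix: {e}") from None
    if not rows:
        raise FormatError("empty height matrix")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise FormatError("ragged rows: matrix is not rectangular")
    return np.array(rows, dtype=float)


def read_heightmap(path: str, format: str = "ascii-grid", *, step_x: float = None,
                   step_y: float = None, sentinel: float = None) -> HeightMap:
    """Read a height map from a plain-text file.

    Parameters
    ----------
    path : str
        Input file.
    format : {"ascii-grid", "csv-matrix"}
        File dialect (see module docstring).
    step_x, step_y : float, optional
        Override / supply step sizes (required for ``csv-matrix`` when no
        sidecar ``<path>.meta`` exists).
    sentinel : float, optional
        Missing-point marker; overrides the file's value.
    """
    with open(path) as fh:
        lines = fh.readlines()

    if format == "ascii-grid":
        if len(lines) < 4 or lines[0].strip() != _MAGIC:
            raise FormatError(f"not an ascii-grid file (expected '{_MAGIC}' header)")
        try:
            nrows, ncols = (int(t) for t in lines[1].split())
        except ValueError:
            raise FormatError("malformed dimension line") from None
        meta = _parse_meta_lines([lines[2]])
        sx = step_x if step_x is not None else float(meta.get("step_x", "nan"))
        sy = step_y if step_y is not None else float(meta.get("step_y", "nan"))
        if not (np.isfinite(sx) and np.isfinite(sy)):
            raise ConfigurationError("ascii-grid header missing step_x/step_y")
        sent = sentinel if sentinel is not None else float(meta.get("sentinel", DEFAULT_SENTINEL))
        grid = _load_matrix(lines[3:])
        if grid.shape != (nrows, ncols):
            raise FormatError(
                f"matrix shape {grid.shape} disagrees with header ({nrows}, {ncols})")
    elif format == "csv-matrix":
        meta = {}
        meta_path = path + ".meta"
        if os.path.exists(meta_path):
            with open(meta_path) as fh:
                meta = _parse_meta_lines(fh.readlines())
        sx = step_x if step_x is not None else float(meta.get("step_x", "nan"))
        sy = step_y if step_y is not None else float(meta.get("step_y", "nan"))
        if not (np.isfinite(sx) and np.isfinite(sy)):
            raise ConfigurationError(
                "csv-matrix needs step sizes via sidecar .meta file or keyword arguments")
        sent = sentinel if sentinel is not None else float(meta.get("sentinel", DEFAULT_SENTINEL))
        grid = _load_matrix(lines, sep=",")
    else:
        raise ValueError(f"unknown format {format!r}")

    mask = grid != sent
    return HeightMap(grid, sx, sy, valid_mask=mask, origin_note=f"read:{path}")


def write_heightmap(hm: HeightMap, path: str, format: str = "ascii-grid",
                    sentinel: float = DEFAULT_SENTINEL) -> None:
    """Write a height map; invalid points are stored as the sentinel value."""
    grid = hm.heights.copy()
    grid[~hm.valid_mask] = sentinel
    nr, nc = grid.shape
    if format == "ascii-grid":
        with open(path, "w") as fh:
            fh.write(f"{_MAGIC}\n{nr} {nc}\n")
            fh.write(f"step_x={hm.step_x!r} step_y={hm.step_y!r} units=um "
                     f"sentinel={sentinel!r}\n")
            np.savetxt(fh, grid, fmt="%.9g")
    elif format == "csv-matrix":
        np.savetxt(path, grid, fmt="%.9g", delimiter=",")
        with open(path + ".meta", "w") as fh:
            fh.write(f"step_x={hm.step_x!r}\nstep_y={hm.step_y!r}\n"
                     f"units=um\nsentinel={sentinel!r}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Preprocessing


def _fill_missing(hm: HeightMap) -> np.ndarray:
    """Fill invalid points: bilinear from valid neighbours, nearest at edges."""
    z = hm.heights.copy()
    if hm.valid_mask.all():
        return z
    rr, cc = np.nonzero(hm.valid_mask)
    pts = np.column_stack([rr * hm.step_y, cc * hm.step_x])
    vals = z[hm.valid_mask]
    mr, mc = np.nonzero(~hm.valid_mask)
    q = np.column_stack([mr * hm.step_y, mc * hm.step_x])
    filled = griddata(pts, vals, q, method="linear")
    bad = ~np.isfinite(filled)
    if bad.any():  # outside the convex hull of valid points
        filled[bad] = griddata(pts, vals, q[bad], method="nearest")
    z[mr, mc] = filled
    return z


def _plane_fit(z: np.ndarray, step_x: float, step_y: float) -> np.ndarray:
    nr, nc = z.shape
    y, x = np.mgrid[0:nr, 0:nc]
    A = np.column_stack([np.ones(z.size), (x * step_x).ravel(), (y * step_y).ravel()])
    coef, *_ = np.linalg.lstsq(A, z.ravel(), rcond=None)
    return (A @ coef).reshape(z.shape)


def preprocess(hm: HeightMap, max_missing_fraction: float = 0.10,
               level: bool = True) -> HeightMap:
    """Fill missing points and (optionally) remove the least-squares plane.

    Scans whose missing-point fraction reaches `max_missing_fraction` are
    rejected, mirroring the retention rule applied to the field scans (only
    scans with under 10% missing data are analysed).

    After levelling the mean height is 0 and all points are valid, which the
    parameter computations assume.
    """
    frac = hm.missing_fraction
    if frac >= max_missing_fraction:
        raise MissingDataError(
            f"missing fraction {frac:.3f} >= allowed {max_missing_fraction:.3f}")
    z = _fill_missing(hm)
    if level:
        z = z - _plane_fit(z, hm.step_x, hm.step_y)
    else:
        z = z - z.mean()
    return HeightMap(z, hm.step_x, hm.step_y,
                     valid_mask=np.ones_like(z, dtype=bool),
                     origin_note=hm.origin_note + "|preprocessed")


# ---------------------------------------------------------------------------
# Mesh export


def export_mesh(hm: HeightMap, base_thickness: float = 7.0,
                unit_scale: float = 1e-3) -> MeshExport:
    """Turn a preprocessed height map into a watertight printable solid.

    The top surface is the height grid (converted to mm by `unit_scale`,
    default μm→mm); a flat base sits `base_thickness` mm below the lowest
    surface point, closed by side walls.  Bounding-box height is therefore
    (max − min height) + base_thickness.
    """
    import trimesh

    if base_thickness <= 0:
        raise ValueError("base_thickness must be positive")
    nr, nc = hm.shape
    if nr < 2 or nc < 2:
        raise ValueError("grid must be at least 2x2 to build a mesh")

    zt = hm.heights * unit_scale
    x = np.arange(nc) * hm.step_x * unit_scale
    y = np.arange(nr) * hm.step_y * unit_scale
    xx, yy = np.meshgrid(x, y)
    z_bot = zt.min() - base_thickness

    top = np.column_stack([xx.ravel(), yy.ravel(), zt.ravel()])
    bot = np.column_stack([xx.ravel(), yy.ravel(), np.full(nr * nc, z_bot)])
    verts = np.vstack([top, bot])
    nt = nr * nc  # offset of bottom vertices

    def vid(r, c):
        return r * nc + c

    faces = []
    for r in range(nr - 1):
        for c in range(nc - 1):
            a, b = vid(r, c), vid(r, c + 1)
            d, e = vid(r + 1, c), vid(r + 1, c + 1)
            faces += [[a, e, b], [a, d, e]]                    # top, +z out
            faces += [[nt + a, nt + b, nt + e], [nt + a, nt + e, nt + d]]  # bottom
    # side walls along the four boundary edges
    for c in range(nc - 1):
        a, b = vid(0, c), vid(0, c + 1)
        faces += [[a, b, nt + b], [a, nt + b, nt + a]]
        a, b = vid(nr - 1, c), vid(nr - 1, c + 1)
        faces += [[b, a, nt + a], [b, nt + a, nt + b]]
    for r in range(nr - 1):
        a, b = vid(r, 0), vid(r + 1, 0)
        faces += [[b, a, nt + a], [b, nt + a, nt + b]]
        a, b = vid(r, nc - 1), vid(r + 1, nc - 1)
        faces += [[a, b, nt + b], [a, nt + b, nt + a]]

    mesh = trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)
    return MeshExport(mesh=mesh, units="mm", base_thickness=base_thickness)
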