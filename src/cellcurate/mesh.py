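"""Cell meshes, contours and midlines.

A detected bacterial cell is represented as a *mesh*: an n x 4 matrix whose
first two columns are the (x, y) coordinates of the left side of the cell and
whose last two columns are those of the right side. The first and last rows
are the cell poles; corresponding rows on the two sides face each other across
the cell body. Coordinates are 0-based, pixel-centre, subpixel allowed, with
x = column axis and y = row axis.

A mesh and the closed subpixel *contour* that outlines the cell are
interconvertible: the contour is the left side followed by the reversed right
side; a contour is turned back into a mesh by picking the two mutually
farthest vertices as poles, splitting the outline into two sides, and
resampling both sides at arc-length-uniform positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

from .exceptions import ValidationError

__all__ = [
    "CellMesh",
    "Contour",
    "CellRecord",
    "Midline",
    "contour_from_mesh",
    "mesh_from_contour",
    "midline_from_mesh",
]


def _as_float_array(values, name, shape_cols):
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != shape_cols:
        raise ValidationError(
            f"{name} must be a 2-D array with {shape_cols} columns, "
            f"got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite coordinates")
    return arr


@dataclass(frozen=True)
class CellMesh:
    """n x 4 coordinate matrix (x_left, y_left, x_right, y_right), poles first/last."""

    coords: np.ndarray

    def __post_init__(self):
        arr = _as_float_array(self.coords, "mesh", 4)
        if arr.shape[0] < 4:
            raise ValidationError(
                f"mesh needs at least 4 rows, got {arr.shape[0]}"
            )
        object.__setattr__(self, "coords", arr)

    @property
    def n_rows(self) -> int:
        return self.coords.shape[0]

    @property
    def left(self) -> np.ndarray:
        """(n, 2) left-side points."""
        return self.coords[:, :2]

    @property
    def right(self) -> np.ndarray:
        """(n, 2) right-side points."""
        return self.coords[:, 2:]

    @property
    def widths(self) -> np.ndarray:
        """Per-row left-to-right distance in pixels (>= 0 by construction)."""
        return np.linalg.norm(self.left - self.right, axis=1)

    def translated(self, dx: float, dy: float) -> "CellMesh":
        shift = np.array([dx, dy, dx, dy], dtype=float)
        return CellMesh(self.coords + shift)

    def scaled(self, s: float) -> "CellMesh":
        return CellMesh(self.coords * float(s))

    def __eq__(self, other):
        return isinstance(other, CellMesh) and np.array_equal(
            self.coords, other.coords
        )


@dataclass(frozen=True)
class Contour:
    """Closed subpixel polygon; the closing edge last->first is implicit.

    Orientation is normalized to counter-clockwise (positive shoelace signed
    area in x-right / y-up convention) unless ``normalize=False``.
    """

    vertices: np.ndarray
    normalize: bool = field(default=True, compare=False)

    def __post_init__(self):
        arr = _as_float_array(self.vertices, "contour", 2)
        if arr.shape[0] >= 2 and np.allclose(arr[0], arr[-1]):
            arr = arr[:-1]
        if np.unique(arr, axis=0).shape[0] < 3:
            raise ValidationError("contour needs at least 3 distinct vertices")
        if self.normalize and _signed_area(arr) < 0:
            arr = arr[::-1].copy()
        object.__setattr__(self, "vertices", arr)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def signed_area(self) -> float:
        return _signed_area(self.vertices)

    @property
    def is_simple(self) -> bool:
        return _ShapelyPolygon(self.vertices).is_valid

    def as_polygon(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)

    def __eq__(self, other):
        return isinstance(other, Contour) and np.array_equal(
            self.vertices, other.vertices
        )


@dataclass(frozen=True)
class CellRecord:
    """One detection: (frame, cell_id, mesh)."""

    frame: int
    cell_id: int
    mesh: CellMesh

    def __post_init__(self):
        if self.frame < 0 or self.cell_id < 0:
            raise ValidationError("frame and cell_id must be non-negative")


@dataclass(frozen=True)
class Midline:
    """Per-row midpoints between the two mesh sides, pole to pole."""

    points: np.ndarray

    def __post_init__(self):
        arr = _as_float_array(self.points, "midline", 2)
        object.__setattr__(self, "points", arr)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


def _signed_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


_DEDUP_TOL = 1e-6  # px; coincident poles are equal only up to float fuzz


def _dedup_consecutive(points: np.ndarray, tol: float = _DEDUP_TOL) -> np.ndarray:
    """Drop consecutive (near-)duplicates, including the wrap-around pair."""
    keep = np.ones(len(points), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(points, axis=0), axis=1) > tol
    points = points[keep]
    if len(points) > 1 and np.linalg.norm(points[-1] - points[0]) <= tol:
        points = points[:-1]
    return points


def contour_from_mesh(mesh: CellMesh, *, record=None) -> Contour:
    """Build the closed cell outline from a mesh.

    Left-side points pole to pole, then right-side points in reverse;
    coincident pole duplicates are collapsed so the result is a simple
    polygon.
    """
    points = np.vstack([mesh.left, mesh.right[::-1]])
    points = _dedup_consecutive(points)
    contour = Contour(points, normalize=False)
    if not contour.is_simple:
        where = f" for record {record}" if record is not None else ""
        raise ValidationError(f"mesh produces a self-intersecting contour{where}")
    return contour


def _farthest_vertex_pair(vertices: np.ndarray) -> tuple[int, int]:
    """Indices of the two mutually farthest vertices, ties to lowest indices."""
    d2 = np.sum((vertices[:, None, :] - vertices[None, :, :]) ** 2, axis=-1)
    iu = np.triu_indices(len(vertices), k=1)
    flat = d2[iu]
    best = int(np.argmax(flat))  # argmax returns the first (lowest-index) max
    return int(iu[0][best]), int(iu[1][best])


def _resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline at n arc-length-uniform positions (endpoints kept)."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        return np.repeat(points[:1], n, axis=0)
    t = np.linspace(0.0, total, n)
    x = np.interp(t, s, points[:, 0])
    y = np.interp(t, s, points[:, 1])
    return np.column_stack([x, y])


def mesh_from_contour(contour: Contour, n_rows: int) -> CellMesh:
    """Convert a closed contour back into an n_rows x 4 mesh.

    Poles are the two mutually farthest contour vertices; the outline is split
    at the poles into two sides, each resampled at ``n_rows`` arc-length-
    uniform positions and paired index-wise. Rows 0 and n_rows-1 hold the pole
    point on both sides (zero width).
    """
    if n_rows < 4:
        raise ValidationError("n_rows must be >= 4")
    verts = contour.vertices
    if verts.shape[0] < 4:
        raise ValidationError("contour too small to mesh (need >= 4 vertices)")
    i, j = _farthest_vertex_pair(verts)
    idx_a = np.arange(i, j + 1)
    idx_b = np.concatenate([np.arange(j, len(verts)), np.arange(0, i + 1)])
    side_a = verts[idx_a]
    side_b = verts[idx_b][::-1]  # reversed so both sides run pole i -> pole j
    left = _resample_polyline(side_a, n_rows)
    right = _resample_polyline(side_b, n_rows)
    left[0] = right[0] = verts[i]
    left[-1] = right[-1] = verts[j]
    return CellMesh(np.hstack([left, right]))


def midline_from_mesh(mesh: CellMesh) -> Midline:
    """Polyline of per-row midpoints between the left and right sides."""
    return Midline((mesh.left + mesh.right) / 2.0)
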