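"""Geometric kernel: triangle surfaces, plane sectioning, contours, cutting.

This module implements the cross-sectioning primitive at the heart of the
automated aneurysm measurement pipeline: a cutting plane is intersected with
a triangulated vessel surface, the resulting line segments are chained into
planar contours, and the longest contour's maximum chord is the measured
diameter at that station.

Conventions
-----------
* All coordinates are millimetres in a right-handed world frame.
* Plane-side classification treats vertices within ``ON_PLANE_TOL`` of the
  plane as lying on the *positive* side, which makes the per-triangle
  intersection deterministic and avoids double-counted segments when a mesh
  vertex falls exactly on the plane.
* Segment endpoints produced by shared mesh edges are bitwise-near
  identical, so chaining matches endpoints within ``TOL_CHAIN`` (1e-6 mm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import ConvexHull, QhullError, cKDTree
from scipy.spatial.distance import pdist

from .errors import (
    EmptyResultError,
    FormatError,
    NoContourError,
    ValidationError,
)

#: vertices with |signed distance| <= ON_PLANE_TOL count as positive side
ON_PLANE_TOL = 1e-9
#: contour points must lie on their plane within this tolerance (mm)
TOL_PLANE = 1e-6
#: chaining tolerance for matching segment endpoints (mm)
TOL_CHAIN = 1e-6


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TriangleSurface:
    """Triangulated 3D surface in mm world coordinates.

    Open (non-watertight) meshes are permitted; clipped vessel parts have
    open rims by construction.
    """

    vertices: np.ndarray
    faces: np.ndarray
    units: str = "mm"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.vertices) < 4 or len(self.faces) < 4:
            raise ValidationError(
                "surface needs at least 4 vertices and 4 faces, got "
                f"{len(self.vertices)} vertices / {len(self.faces)} faces"
            )
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= len(self.vertices):
            raise ValidationError("face index out of range")
        f = self.faces
        if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
            raise ValidationError("degenerate face with repeated vertex index")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def area(self) -> float:
        """Total surface area in mm^2."""
        a = self.vertices[self.faces[:, 0]]
        b = self.vertices[self.faces[:, 1]]
        c = self.vertices[self.faces[:, 2]]
        return float(0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1).sum())

    def bounds(self) -> np.ndarray:
        """(2, 3) array of [min; max] corner of the axis-aligned bbox."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh) -> "TriangleSurface":
        return cls(np.asarray(mesh.vertices, dtype=float), np.asarray(mesh.faces))


@dataclass
class SectionPlane:
    """Oriented plane given by an origin point and a unit normal (mm)."""

    origin: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise ValidationError("plane normal has zero length")
        self.normal = n / norm

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.origin) @ self.normal


@dataclass
class PlanarContour:
    """Ordered point loop (or open chain) from a plane-mesh intersection.

    For closed contours the last point is *not* a duplicate of the first;
    closure is implicit.
    """

    points: np.ndarray
    closed: bool
    plane: SectionPlane

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 2:
            raise ValidationError("contour needs at least 2 points")

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# surface I/O
# ---------------------------------------------------------------------------

_FORMATS = {"stl", "ply"}


def _resolve_format(path: str, fmt: str) -> str:
    if fmt == "auto":
        ext = str(path).rsplit(".", 1)[-1].lower()
        if ext not in _FORMATS:
            raise FormatError(f"cannot infer mesh format from extension {ext!r}")
        return ext
    if fmt not in _FORMATS:
        raise FormatError(f"unsupported mesh format {fmt!r}")
    return fmt


def read_surface(path: str, fmt: str = "auto") -> TriangleSurface:
    """Read an STL (binary or ASCII) or PLY surface file.

    Coordinates are taken as mm.  Raises :class:`FormatError` when the file
    does not parse or contains no faces.
    """
    fmt = _resolve_format(path, fmt)
    try:
        mesh = trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    except OSError:
        raise
    except Exception as exc:  # trimesh raises a zoo of parse errors
        raise FormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise FormatError(f"{path}: no triangle faces found ({fmt})")
    return TriangleSurface.from_trimesh(mesh)


def write_surface(surface: TriangleSurface, path: str, fmt: str = "auto") -> None:
    """Write a surface as binary STL or ASCII PLY.

    The surface invariants are re-checked before anything is written.
    """
    fmt = _resolve_format(path, fmt)
    # re-validate (catches arrays mutated after construction)
    TriangleSurface(surface.vertices, surface.faces)
    mesh = surface.to_trimesh()
    if fmt == "ply":
        mesh.export(str(path), file_type="ply", encoding="ascii")
    else:
        mesh.export(str(path), file_type="stl")


# ---------------------------------------------------------------------------
# plane sectioning
# ---------------------------------------------------------------------------


def _intersection_segments(surface: TriangleSurface, plane: SectionPlane) -> np.ndarray:
    """Per-triangle plane crossings as an (m, 2, 3) array of segments.

    Endpoints are linear interpolations along triangle edges at the
    signed-distance zero crossing; vertices on the plane count as positive.
    """
    v = surface.vertices
    d = plane.signed_distance(v)
    pos = d >= -ON_PLANE_TOL
    f = surface.faces
    fp = pos[f]
    crossing = fp.any(axis=1) & ~fp.all(axis=1)
    if not crossing.any():
        return np.empty((0, 2, 3))
    tris = f[crossing]
    # the three directed edges of each crossing triangle
    edges = np.stack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]], axis=1)
    cross_edge = pos[edges[..., 0]] != pos[edges[..., 1]]  # exactly 2 per row
    sel = edges[cross_edge].reshape(-1, 2, 2)  # (m, 2 crossings, [a, b])
    da = d[sel[..., 0]]
    db = d[sel[..., 1]]
    t = (da / (da - db))[..., None]
    pts = v[sel[..., 0]] + t * (v[sel[..., 1]] - v[sel[..., 0]])  # (m, 2, 3)
    # drop degenerate segments from vertices sitting exactly on the plane
    seg_len = np.linalg.norm(pts[:, 0] - pts[:, 1], axis=1)
    return pts[seg_len > TOL_CHAIN]


def _chain_segments(segments: np.ndarray, plane: SectionPlane, tol: float) -> list[PlanarContour]:
    """Chain (m, 2, 3) segments into ordered contours, matching endpoints
    within ``tol``.  Deterministic: components are emitted in order of their
    lowest segment index."""
    m = len(segments)
    if m == 0:
        return []
    pts = segments.reshape(-1, 3)

    # union endpoints within tol into nodes
    parent = np.arange(2 * m)

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    tree = cKDTree(pts)
    for a, b in tree.query_pairs(tol, output_type="ndarray"):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    label = np.fromiter((find(i) for i in range(2 * m)), dtype=np.int64)
    adj: dict[int, list[tuple[int, int]]] = {}
    for s in range(m):
        for e in (0, 1):
            adj.setdefault(label[2 * s + e], []).append((s, e))

    visited = np.zeros(m, dtype=bool)
    contours: list[PlanarContour] = []

    for s0 in range(m):
        if visited[s0]:
            continue
        # walk backwards from s0's first endpoint to find a chain start
        seen = {s0}
        node = label[2 * s0 + 0]
        while True:
            nxt = [(s, e) for (s, e) in adj[node] if s not in seen and not visited[s]]
            if not nxt:
                break
            s, e = nxt[0]
            seen.add(s)
            node = label[2 * s + (1 - e)]
        start_node = node

        # forward walk collecting ordered points
        points: list[np.ndarray] = []
        cur = start_node
        n_segs = 0
        while True:
            nxt = [(s, e) for (s, e) in adj[cur] if not visited[s]]
            if not nxt:
                break
            s, e = nxt[0]
            visited[s] = True
            if not points:
                points.append(pts[2 * s + e])
            points.append(pts[2 * s + (1 - e)])
            cur = label[2 * s + (1 - e)]
            n_segs += 1
        closed = bool(cur == start_node and n_segs >= 3)
        if closed:
            points.pop()  # implicit closure: drop duplicated first point
        if len(points) >= 2:
            contours.append(PlanarContour(np.array(points), closed, plane))
    return contours


def plane_section(surface: TriangleSurface, plane: SectionPlane) -> list[PlanarContour]:
    """Intersect a plane with a surface and chain the crossings into contours.

    Each triangle straddling the plane contributes one line segment; segments
    sharing endpoints (within ``TOL_CHAIN``) are chained into ordered
    contours.  Chains whose free ends coincide are marked closed.  An empty
    list is a valid result when no triangle crosses the plane.
    """
    segments = _intersection_segments(surface, plane)
    return _chain_segments(segments, plane, TOL_CHAIN)


# ---------------------------------------------------------------------------
# contour measurements
# ---------------------------------------------------------------------------


def contour_length(contour: PlanarContour) -> float:
    """Polyline length of a contour (mm), plus the closing segment if closed."""
    p = contour.points
    length = float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())
    if contour.closed:
        length += float(np.linalg.norm(p[-1] - p[0]))
    return length


def longest_contour(contours: list[PlanarContour]) -> PlanarContour:
    """The contour maximizing :func:`contour_length`; ties break to the
    lowest list index so selection is deterministic."""
    if not contours:
        raise NoContourError("no contours to select from")
    lengths = [contour_length(c) for c in contours]
    return contours[int(np.argmax(lengths))]


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal in-plane axes for a given unit normal."""
    a = np.zeros(3)
    a[int(np.argmin(np.abs(normal)))] = 1.0
    u = np.cross(normal, a)
    u /= np.linalg.norm(u)
    w = np.cross(normal, u)
    return u, w


def max_contour_diameter(contour: PlanarContour) -> float:
    """Maximum Euclidean distance over all point pairs (the max chord, mm).

    For large contours the convex hull of the in-plane projection is taken
    first (the farthest pair is always a pair of hull vertices); the result
    is identical to the brute-force pairwise maximum.
    """
    pts = contour.points
    if len(pts) < 2:
        raise ValidationError("contour diameter needs at least 2 points")
    if len(pts) <= 32:
        return float(pdist(pts).max())
    u, w = _plane_basis(contour.plane.normal)
    xy = np.column_stack([(pts - contour.plane.origin) @ u, (pts - contour.plane.origin) @ w])
    try:
        hull = ConvexHull(xy)
    except QhullError:
        return float(pdist(pts).max())
    return float(pdist(pts[hull.vertices]).max())


# ---------------------------------------------------------------------------
# half-space cutting
# ---------------------------------------------------------------------------


def cut_surface_by_plane(
    surface: TriangleSurface, plane: SectionPlane, keep: str = "positive"
) -> TriangleSurface:
    """Clip a surface to one side of a plane.

    Triangles crossing the plane are clipped at the plane, so the result's
    extent does not exceed the half-space by more than the on-plane
    tolerance.  The cut boundary is left open (no capping).  Raises
    :class:`EmptyResultError` when no geometry lies on the requested side.
    """
    if keep not in ("positive", "negative"):
        raise ValidationError(f"keep must be 'positive' or 'negative', got {keep!r}")
    v = surface.vertices
    d = plane.signed_distance(v)
    if keep == "negative":
        d = -d
    kept = d >= -ON_PLANE_TOL

    f = surface.faces
    kf = kept[f]
    n_kept = kf.sum(axis=1)
    if np.all(n_kept == 3):
        return TriangleSurface(v.copy(), f.copy())

    new_vertices: list[np.ndarray] = [v]
    extra: list[np.ndarray] = []
    next_idx = len(v)
    faces_out: list[tuple[int, int, int]] = [tuple(tri) for tri in f[n_kept == 3]]

    for tri in f[(n_kept == 1) | (n_kept == 2)]:
        # Sutherland-Hodgman clip of one triangle against the half-space
        poly: list[int] = []
        for i in range(3):
            a, b = tri[i], tri[(i + 1) % 3]
            if kept[a]:
                poly.append(int(a))
            if kept[a] != kept[b]:
                t = d[a] / (d[a] - d[b])
                extra.append(v[a] + t * (v[b] - v[a]))
                poly.append(next_idx)
                next_idx += 1
        for i in range(1, len(poly) - 1):  # fan triangulation keeps winding
            faces_out.append((poly[0], poly[i], poly[i + 1]))

    if not faces_out:
        raise EmptyResultError("no geometry on the requested side of the plane")
    all_v = np.vstack(new_vertices + [np.array(extra)]) if extra else v.copy()
    faces_arr = np.array(faces_out, dtype=np.int64)
    # compact to referenced vertices only
    used = np.unique(faces_arr)
    remap = np.full(len(all_v), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriangleSurface(all_v[used], remap[faces_arr])
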