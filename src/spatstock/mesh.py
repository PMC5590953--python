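"""Triangulation of the survey domain and its finite-element matrices.

The latent Matérn field is represented on a triangulation with piecewise
linear basis functions, one per vertex: the field value anywhere in the
domain is the linear interpolation of the vertex weights of the containing
triangle.  This module builds that triangulation from survey locations
(``build_mesh``), assembles the lumped mass matrix ``C`` and stiffness
matrix ``G`` needed for the SPDE precision (``fem_matrices``), and maps
vertex weights to arbitrary locations through a sparse barycentric
projector (``projection_matrix``).

Coordinates are treated as planar Euclidean: survey longitude/latitude in
degrees are used as-is, so ranges are reported in degrees.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from matplotlib.tri import Triangulation, TrapezoidMapTriFinder
from scipy import sparse
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import MultiPoint, Point

from .errors import DegenerateDomainError, OutOfDomainError, SingularElementError

__all__ = [
    "TriangulationMesh",
    "FemMatrices",
    "Projector",
    "build_mesh",
    "fem_matrices",
    "projection_matrix",
]


@dataclass
class TriangulationMesh:
    """A planar triangulation with per-vertex linear basis functions.

    Attributes
    ----------
    vertices : (n, 2) array
        Vertex coordinates (degrees lon/lat treated as planar).
    triangles : (m, 3) int array
        Index triples into ``vertices``.
    boundary_flags : (n,) bool array
        True for vertices on the outer boundary of the triangulation.
    data_vertex_index : int array
        Indices of vertices that represent (cutoff-merged) data locations.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    boundary_flags: np.ndarray
    data_vertex_index: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (e, 2) index array."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def edge_lengths(self) -> np.ndarray:
        e = self.edges()
        d = self.vertices[e[:, 0]] - self.vertices[e[:, 1]]
        return np.hypot(d[:, 0], d[:, 1])

    def triangle_areas(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        v1 = p[:, 1] - p[:, 0]
        v2 = p[:, 2] - p[:, 0]
        return 0.5 * np.abs(v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])

    def min_interior_angle(self) -> float:
        """Smallest interior angle over all triangles, in degrees."""
        p = self.vertices[self.triangles]
        angles = []
        for i in range(3):
            a = p[:, (i + 1) % 3] - p[:, i]
            b = p[:, (i + 2) % 3] - p[:, i]
            cosang = np.einsum("ij,ij->i", a, b) / (
                np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
            )
            angles.append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        return float(np.min(angles))

    def to_json(self) -> str:
        return json.dumps(
            {
                "vertices": self.vertices.tolist(),
                "triangles": self.triangles.tolist(),
                "boundary_flags": self.boundary_flags.astype(int).tolist(),
                "data_vertex_index": self.data_vertex_index.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TriangulationMesh":
        d = json.loads(text)
        return cls(
            vertices=np.asarray(d["vertices"], float),
            triangles=np.asarray(d["triangles"], int),
            boundary_flags=np.asarray(d["boundary_flags"], bool),
            data_vertex_index=np.asarray(d.get("data_vertex_index", []), int),
        )


@dataclass
class FemMatrices:
    """Lumped mass matrix C (diagonal) and stiffness matrix G."""

    mass: sparse.csc_matrix
    stiffness: sparse.csc_matrix

    @property
    def n_vertices(self) -> int:
        return self.mass.shape[0]


@dataclass
class Projector:
    """Sparse matrix mapping vertex weights to field values at locations."""

    matrix: sparse.csr_matrix
    inside: np.ndarray  # bool per location


def _merge_by_cutoff(points: np.ndarray, cutoff: float) -> np.ndarray:
    """Greedy cluster points within ``cutoff``; keep cluster centroids.

    Points are scanned in input order; each point joins the first existing
    cluster whose seed is within ``cutoff`` (ties broken by input order),
    otherwise it seeds a new cluster.
    """
    seeds: list[np.ndarray] = []
    members: list[list[np.ndarray]] = []
    for p in points:
        placed = False
        for k, s in enumerate(seeds):
            if np.hypot(*(p - s)) <= cutoff:
                members[k].append(p)
                placed = True
                break
        if not placed:
            seeds.append(p)
            members.append([p])
    return np.array([np.mean(m, axis=0) for m in members])


def _boundary_ring(data_points: np.ndarray, offset: float, spacing: float) -> np.ndarray:
    """Extension ring: the data hull buffered by ``offset``, with bulges.

    Straight boundary stretches are subdivided at ``spacing`` and the
    subdivision points are pushed slightly outward (parabolic bulge), so
    no three consecutive ring points are collinear.  This matters because
    qhull silently drops collinear hull points, which would leave
    boundary edges longer than ``max_edge`` that midpoint refinement can
    never split.
    """
    hull = MultiPoint([tuple(p) for p in data_points]).convex_hull
    poly = hull.buffer(offset, quad_segs=4)
    coords = np.array(poly.exterior.coords)  # closed ring, first == last
    centroid = np.array(poly.centroid.coords[0])
    step = 0.9 * spacing
    sagitta = 0.15 * spacing
    out: list[np.ndarray] = []
    for p0, p1 in zip(coords[:-1], coords[1:]):
        seg = p1 - p0
        L = float(np.hypot(*seg))
        if L < 1e-12:
            continue
        out.append(p0)
        k = int(math.ceil(L / step))
        if k > 1:
            normal = np.array([seg[1], -seg[0]]) / L
            mid = 0.5 * (p0 + p1)
            if np.dot(normal, mid - centroid) < 0:  # ensure outward
                normal = -normal
            for j in range(1, k):
                t = j / k
                out.append(p0 + t * seg + (4.0 * t * (1.0 - t) * sagitta) * normal)
    return np.array(out)


def build_mesh(
    locations,
    max_edge: float,
    cutoff: float,
    offset_factor: float = 1.0,
    max_refine_iter: int = 30,
) -> TriangulationMesh:
    """Triangulate the survey domain from data locations.

    Data locations within ``cutoff`` of each other are merged to a single
    vertex (cluster centroid) so that near-duplicate trawl positions do not
    force needle triangles.  The convex hull of the merged points is
    extended outward by ``offset_factor * max_edge`` to push the mesh
    boundary (and its Neumann artefacts) away from the data.  Long edges
    are bisected until none exceeds ``max_edge``.

    Parameters
    ----------
    locations : array-like of shape (m, 2)
    max_edge : float
        Maximum allowed triangle side length, in coordinate units.
    cutoff : float
        Merge radius for near-duplicate locations; must satisfy
        ``0 < cutoff < max_edge``.
    """
    pts = np.atleast_2d(np.asarray(locations, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 2 or not np.all(np.isfinite(pts)):
        raise DegenerateDomainError("locations must be a finite (m, 2) array")
    if not (max_edge > cutoff > 0):
        raise ValueError("require max_edge > cutoff > 0")

    data = _merge_by_cutoff(pts, cutoff)
    if data.shape[0] < 3:
        raise DegenerateDomainError(
            f"need at least 3 distinct locations after cutoff merging, got {data.shape[0]}"
        )
    # collinearity: area of the convex hull must be genuinely 2-D
    centered = data - data.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-10 * max(sv[0], 1.0):
        raise DegenerateDomainError("input locations are collinear")

    ring = _boundary_ring(data, offset_factor * max_edge, max_edge)
    points = np.vstack([data, ring])
    n_data = data.shape[0]

    # hexagonal interior fill at ~0.8 max_edge spacing, keeping clear of
    # existing points so Delaunay angles stay healthy
    hull_poly = MultiPoint([tuple(p) for p in points]).convex_hull
    spacing = 0.8 * max_edge
    minx, miny, maxx, maxy = hull_poly.bounds
    xs = np.arange(minx, maxx + spacing, spacing)
    ys = np.arange(miny, maxy + spacing, spacing * math.sqrt(3) / 2.0)
    cand = []
    for irow, yy in enumerate(ys):
        offs = 0.5 * spacing if irow % 2 else 0.0
        for xx in xs + offs:
            cand.append((xx, yy))
    cand = np.array(cand)
    if len(cand):
        inside = np.array([hull_poly.contains(Point(p)) for p in cand])
        cand = cand[inside]
        if len(cand):
            tree = cKDTree(points)
            dist, _ = tree.query(cand)
            cand = cand[dist > 0.55 * max_edge]
            points = np.vstack([points, cand])

    # bisect long edges of the *filtered* triangulation (slivers along
    # the hull are dropped before measuring) until every edge fits
    mesh = None
    for _ in range(max_refine_iter):
        points, triangles = _filtered_delaunay(points, n_data, max_edge)
        mesh = TriangulationMesh(points, triangles, np.zeros(len(points), bool))
        e = mesh.edges()
        lengths = mesh.edge_lengths()
        too_long = lengths > max_edge
        if not too_long.any():
            break
        seg = points[e[too_long, 1]] - points[e[too_long, 0]]
        mids = points[e[too_long, 0]] + 0.5 * seg
        normals = np.column_stack([-seg[:, 1], seg[:, 0]])
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        dist, _ = cKDTree(points).query(mids)
        rng_jit = np.random.default_rng(len(points))
        new_pts = []
        for mid, nrm, d in zip(mids, normals, dist):
            if d <= 0.05 * max_edge:
                # a point already sits essentially on this edge yet the
                # edge survived (the Delaunay lens fell on one side only);
                # split both sides explicitly
                new_pts.append(mid + 1e-3 * max_edge * nrm)
                new_pts.append(mid - 1e-3 * max_edge * nrm)
            else:
                # jitter off the edge: qhull drops exactly-collinear
                # points, and a midpoint on the wrong side leaves the
                # opposite triangle (and the edge) intact
                new_pts.append(mid + (2e-4 * max_edge * rng_jit.uniform(0.5, 1.0)) * nrm)
        new_pts = np.asarray(new_pts)
        keep = np.ones(len(new_pts), bool)
        ntree = cKDTree(new_pts)
        for i, j in sorted(ntree.query_pairs(1e-4 * max_edge)):
            if keep[i]:
                keep[j] = False
        points = np.vstack([points, new_pts[keep]])
    else:  # pragma: no cover - refinement always terminates by halving
        raise DegenerateDomainError("edge refinement did not terminate")

    boundary = np.zeros(len(mesh.vertices), bool)
    edge_counts: dict = {}
    for t in mesh.triangles:
        for i, j in ((0, 1), (1, 2), (2, 0)):
            key = (min(t[i], t[j]), max(t[i], t[j]))
            edge_counts[key] = edge_counts.get(key, 0) + 1
    for (i, j), cnt in edge_counts.items():
        if cnt == 1:
            boundary[i] = boundary[j] = True
    mesh.boundary_flags = boundary
    mesh.data_vertex_index = np.arange(n_data)
    return mesh


def _filtered_delaunay(points: np.ndarray, n_data: int, max_edge: float):
    """Delaunay triangulation with near-duplicate vertices merged and
    hairline slivers (along the curved hull) removed.

    Data vertices occupy the first ``n_data`` rows and are always kept;
    the data region is strictly interior and unaffected by the filter.
    """
    dup = cKDTree(points).query_pairs(1e-5 * max_edge)
    if dup:
        drop = {max(i, j) for i, j in dup if max(i, j) >= n_data}
        keep_mask = np.ones(len(points), bool)
        keep_mask[list(drop)] = False
        points = points[keep_mask]

    tri = Delaunay(points)
    mesh = TriangulationMesh(points, tri.simplices, np.zeros(len(points), bool))
    areas = mesh.triangle_areas()
    keep = areas > max(1e-14, 1e-5 * np.median(areas))
    p = points[tri.simplices]
    min_ang = np.full(len(tri.simplices), 180.0)
    for i in range(3):
        a = p[:, (i + 1) % 3] - p[:, i]
        b = p[:, (i + 2) % 3] - p[:, i]
        cosang = np.einsum("ij,ij->i", a, b) / np.maximum(
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1), 1e-300
        )
        min_ang = np.minimum(min_ang, np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    keep &= min_ang >= 0.5
    triangles = tri.simplices[keep]
    used = np.unique(triangles)
    if len(used) < len(points):
        remap = -np.ones(len(points), int)
        remap[used] = np.arange(len(used))
        if np.any(remap[:n_data] < 0):  # pragma: no cover - data is interior
            raise DegenerateDomainError("a data vertex fell only in degenerate triangles")
        points = points[used]
        triangles = remap[triangles]
    return points, triangles


def fem_matrices(mesh: TriangulationMesh) -> FemMatrices:
    """Assemble the lumped mass matrix C and stiffness matrix G.

    For each triangle with area ``A`` the three linear basis gradients are
    constant; the local stiffness is ``A * grad_i . grad_j`` and the lumped
    mass contributes ``A/3`` to each vertex, so ``sum(C)`` equals the total
    meshed area and the rows of ``G`` sum to zero (constants are in the
    null space of the Laplacian).
    """
    verts = mesh.vertices
    tris = mesh.triangles
    n = mesh.n_vertices
    areas = mesh.triangle_areas()
    if np.any(areas <= 1e-14):
        bad = np.where(areas <= 1e-14)[0]
        raise SingularElementError(f"zero-area triangles at indices {bad.tolist()}")

    c_diag = np.zeros(n)
    rows, cols, vals = [], [], []
    for t, area in zip(tris, areas):
        p = verts[t]
        # gradients of the three barycentric basis functions
        # grad lambda_i = perp(opposite edge) / (2A)
        g = np.empty((3, 2))
        for i in range(3):
            a, b = p[(i + 1) % 3], p[(i + 2) % 3]
            edge = b - a
            g[i] = np.array([-edge[1], edge[0]])
        # orient so that grad points toward vertex i
        for i in range(3):
            if np.dot(g[i], p[i] - p[(i + 1) % 3]) < 0:
                g[i] = -g[i]
        g /= 2.0 * area
        local = area * (g @ g.T)
        for i in range(3):
            c_diag[t[i]] += area / 3.0
            for j in range(3):
                rows.append(t[i])
                cols.append(t[j])
                vals.append(local[i, j])

    G = sparse.csc_matrix((vals, (rows, cols)), shape=(n, n))
    G = 0.5 * (G + G.T)  # symmetrize away round-off
    C = sparse.diags(c_diag, format="csc")
    return FemMatrices(mass=C, stiffness=G)


def projection_matrix(mesh: TriangulationMesh, locations, allow_outside: bool = False) -> Projector:
    """Barycentric interpolation matrix A from vertices to ``locations``.

    Each in-domain row holds the (at most 3) barycentric coordinates of the
    containing triangle and sums to one; a location coincident with vertex
    ``l`` yields a unit indicator row.  Out-of-domain locations raise
    :class:`OutOfDomainError` unless ``allow_outside`` is set, in which case
    their rows are zero and flagged in ``Projector.inside``.
    """
    locs = np.atleast_2d(np.asarray(locations, dtype=float))
    if not np.all(np.isfinite(locs)):
        raise OutOfDomainError("locations must be finite")
    mtri = Triangulation(mesh.vertices[:, 0], mesh.vertices[:, 1], mesh.triangles)
    finder = TrapezoidMapTriFinder(mtri)
    tri_idx = finder(locs[:, 0], locs[:, 1])
    outside = tri_idx < 0
    if outside.any() and not allow_outside:
        raise OutOfDomainError(
            f"{int(outside.sum())} locations outside the triangulation",
            rows=np.where(outside)[0],
        )

    rows, cols, vals = [], [], []
    for i, (loc, ti) in enumerate(zip(locs, tri_idx)):
        if ti < 0:
            continue
        t = mesh.triangles[ti]
        p = mesh.vertices[t]
        T = np.column_stack([p[1] - p[0], p[2] - p[0]])
        lam12 = np.linalg.solve(T, loc - p[0])
        lam = np.array([1.0 - lam12.sum(), lam12[0], lam12[1]])
        lam = np.clip(lam, 0.0, None)
        lam /= lam.sum()
        for j in range(3):
            rows.append(i)
            cols.append(t[j])
            vals.append(lam[j])
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(len(locs), mesh.n_vertices))
    return Projector(matrix=A, inside=~outside)
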