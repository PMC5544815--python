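"""Closed triangulated surface meshes and discrete surface operators.

Geometry convention: coordinates in millimetres, faces as 0-based vertex
triples with outward-consistent winding. Meshes used by the forward model
must be closed orientable 2-manifolds (every edge shared by exactly two
faces); sphere-topology surfaces have Euler characteristic 2.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import sparse


class MeshError(ValueError):
    """Raised when a surface violates the closed-2-manifold requirements."""


@dataclass
class TriSurfaceMesh:
    """A closed, outward-oriented triangle mesh.

    Attributes
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array, 0-based, consistent outward winding
    """

    vertices: np.ndarray
    faces: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be an (m, 3) array")

    # -- basic counts ------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(),
                               process=False)

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "TriSurfaceMesh":
        return cls(np.asarray(tm.vertices, float), np.asarray(tm.faces))

    # -- validation --------------------------------------------------------
    def validate(self, require_sphere_topology: bool = True) -> None:
        """Check the closed-manifold invariants; raise MeshError on failure."""
        tm = self.to_trimesh()
        if not tm.is_watertight:
            raise MeshError("mesh is not closed (open edges present)")
        if not tm.is_winding_consistent:
            raise MeshError("mesh winding is inconsistent")
        if np.any(self.face_areas() < 1e-12):
            raise MeshError("mesh contains a zero-area face")
        euler = self.n_vertices - len(self.edges()) + self.n_faces
        if require_sphere_topology and euler != 2:
            raise MeshError(f"Euler characteristic {euler} != 2")
        if tm.volume < 0:
            raise MeshError("winding is inward (negative enclosed volume)")

    # -- cached derived quantities ----------------------------------------
    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) array of vertex indices."""
        if "edges" not in self._cache:
            e = np.sort(
                np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                                self.faces[:, [2, 0]]]), axis=1)
            self._cache["edges"] = np.unique(e, axis=0)
        return self._cache["edges"]

    def edge_lengths(self) -> np.ndarray:
        if "edge_lengths" not in self._cache:
            e = self.edges()
            self._cache["edge_lengths"] = np.linalg.norm(
                self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
        return self._cache["edge_lengths"]

    def face_areas(self) -> np.ndarray:
        if "face_areas" not in self._cache:
            v = self.vertices
            f = self.faces
            cr = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
            self._cache["face_areas"] = 0.5 * np.linalg.norm(cr, axis=1)
        return self._cache["face_areas"]

    def face_normals(self) -> np.ndarray:
        if "face_normals" not in self._cache:
            v = self.vertices
            f = self.faces
            cr = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
            self._cache["face_normals"] = cr / np.linalg.norm(
                cr, axis=1, keepdims=True)
        return self._cache["face_normals"]

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted outward unit normals at vertices."""
        if "vertex_normals" not in self._cache:
            fn = self.face_normals() * self.face_areas()[:, None]
            vn = np.zeros_like(self.vertices)
            for k in range(3):
                np.add.at(vn, self.faces[:, k], fn)
            self._cache["vertex_normals"] = vn / np.linalg.norm(
                vn, axis=1, keepdims=True)
        return self._cache["vertex_normals"]

    def vertex_dual_areas(self) -> np.ndarray:
        """Barycentric dual areas: one third of each incident face area."""
        if "vertex_dual_areas" not in self._cache:
            fa = self.face_areas() / 3.0
            w = np.zeros(self.n_vertices)
            for k in range(3):
                np.add.at(w, self.faces[:, k], fa)
            self._cache["vertex_dual_areas"] = w
        return self._cache["vertex_dual_areas"]

    def adjacency(self, weights: np.ndarray | None = None) -> sparse.csr_matrix:
        """Symmetric vertex adjacency; optional per-edge weights."""
        e = self.edges()
        w = np.ones(len(e)) if weights is None else np.asarray(weights, float)
        i = np.concatenate([e[:, 0], e[:, 1]])
        j = np.concatenate([e[:, 1], e[:, 0]])
        return sparse.csr_matrix((np.concatenate([w, w]), (i, j)),
                                 shape=(self.n_vertices, self.n_vertices))

    def graph_distances(self, source: int) -> np.ndarray:
        """Edge-weighted geodesic (graph) distances from one vertex, mm."""
        from scipy.sparse.csgraph import dijkstra
        adj = self.adjacency(self.edge_lengths())
        return dijkstra(adj, directed=False, indices=source)

    def face_gradient_operators(self):
        """Sparse (n_faces, n_vertices) operators for the x/y/z components
        of the per-face linear-interpolation surface gradient.

        For a linear field on a triangle, grad(phi) = sum_i phi_i grad(lambda_i)
        with grad(lambda_i) = (n x e_i) / (2 A), e_i the edge opposite vertex i.
        Constant fields are annihilated exactly.
        """
        if "face_grad" not in self._cache:
            v, f = self.vertices, self.faces
            n = self.face_normals()
            a2 = 2.0 * self.face_areas()
            rows, cols, gx, gy, gz = [], [], [], [], []
            for k in range(3):
                # edge opposite vertex k, winding order
                e = v[f[:, (k + 2) % 3]] - v[f[:, (k + 1) % 3]]
                g = np.cross(n, e) / a2[:, None]
                rows.append(np.arange(len(f)))
                cols.append(f[:, k])
                gx.append(g[:, 0])
                gy.append(g[:, 1])
                gz.append(g[:, 2])
            rows = np.concatenate(rows)
            cols = np.concatenate(cols)
            shape = (self.n_faces, self.n_vertices)
            ops = tuple(
                sparse.csr_matrix((np.concatenate(c), (rows, cols)), shape=shape)
                for c in (gx, gy, gz))
            self._cache["face_grad"] = ops
        return self._cache["face_grad"]

    def face_to_vertex_weights(self) -> sparse.csr_matrix:
        """Area-weighted averaging matrix from faces onto vertices."""
        if "f2v" not in self._cache:
            fa = self.face_areas()
            rows = np.concatenate([self.faces[:, k] for k in range(3)])
            cols = np.tile(np.arange(self.n_faces), 3)
            vals = np.tile(fa, 3)
            w = sparse.csr_matrix((vals, (rows, cols)),
                                  shape=(self.n_vertices, self.n_faces))
            norm = np.asarray(w.sum(axis=1)).ravel()
            w = sparse.diags(1.0 / norm) @ w
            self._cache["f2v"] = w.tocsr()
        return self._cache["f2v"]


# ---------------------------------------------------------------------------
# Point queries (rtree-free)
# ---------------------------------------------------------------------------

def points_inside(mesh: TriSurfaceMesh, points: np.ndarray,
                  chunk: int = 256) -> np.ndarray:
    """Strict containment test via the generalized winding number.

    Sums the signed solid angles of all faces as seen from each query point
    (van Oosterom & Strackee); points inside a closed outward-oriented
    surface see a total of 4*pi.
    """
    points = np.atleast_2d(np.asarray(points, float))
    v, f = mesh.vertices, mesh.faces
    out = np.empty(len(points), dtype=bool)
    for s in range(0, len(points), chunk):
        p = points[s:s + chunk]
        a = v[f[:, 0]][None] - p[:, None]
        b = v[f[:, 1]][None] - p[:, None]
        c = v[f[:, 2]][None] - p[:, None]
        la = np.linalg.norm(a, axis=2)
        lb = np.linalg.norm(b, axis=2)
        lc = np.linalg.norm(c, axis=2)
        num = np.einsum("pfk,pfk->pf", a, np.cross(b, c))
        den = (la * lb * lc + np.einsum("pfk,pfk->pf", a, b) * lc
               + np.einsum("pfk,pfk->pf", b, c) * la
               + np.einsum("pfk,pfk->pf", a, c) * lb)
        omega = 2.0 * np.arctan2(num, den)
        wind = omega.sum(axis=1) / (4.0 * np.pi)
        out[s:s + chunk] = wind > 0.5
    return out


def distance_to_surface(mesh: TriSurfaceMesh, points: np.ndarray) -> np.ndarray:
    """Unsigned distance from each point to the surface, evaluated exactly on
    the faces incident to the few nearest vertices (adequate for points at or
    near the surface, as electrodes are)."""
    from trimesh.triangles import closest_point as tri_closest
    points = np.atleast_2d(np.asarray(points, float))
    v, f = mesh.vertices, mesh.faces
    # faces incident to each vertex
    incident: list[list[int]] = [[] for _ in range(mesh.n_vertices)]
    for fi, face in enumerate(f):
        for vi in face:
            incident[vi].append(fi)
    from scipy.spatial import cKDTree
    _, nearest = cKDTree(v).query(points, k=min(4, mesh.n_vertices))
    nearest = np.atleast_2d(nearest)
    dists = np.empty(len(points))
    for i, p in enumerate(points):
        fids = sorted({fi for vi in nearest[i] for fi in incident[vi]})
        tris = v[f[fids]]
        cp = tri_closest(tris, np.tile(p, (len(tris), 1)))
        dists[i] = np.min(np.linalg.norm(cp - p, axis=1))
    return dists


# ---------------------------------------------------------------------------
# Mesh construction
# ---------------------------------------------------------------------------

def fibonacci_sphere_points(n: int, radius: float = 1.0) -> np.ndarray:
    """Quasi-uniform points on a sphere via the golden-angle spiral."""
    if n < 4:
        raise ValueError("need at least 4 points")
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    theta = 2.0 * np.pi * i / phi
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return radius * pts


def sphere_mesh(radius: float, n_vertices: int,
                center: np.ndarray | None = None,
                scale: tuple[float, float, float] = (1.0, 1.0, 1.0),
                ) -> TriSurfaceMesh:
    """Closed sphere (optionally anisotropically scaled to an ellipsoid)
    triangulated over quasi-uniform Fibonacci points via the convex hull.
    """
    pts = fibonacci_sphere_points(n_vertices, radius)
    hull = trimesh.PointCloud(pts).convex_hull
    if len(hull.vertices) != n_vertices:
        # hull vertex order may differ; all sphere points are extreme points
        raise MeshError("convex hull dropped sphere vertices unexpectedly")
    v = np.asarray(hull.vertices, float) * np.asarray(scale, float)
    if center is not None:
        v = v + np.asarray(center, float)
    mesh = TriSurfaceMesh(v, np.asarray(hull.faces))
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# ASCII PLY / OFF I/O (via trimesh)
# ---------------------------------------------------------------------------

def write_mesh(mesh: TriSurfaceMesh, path: str) -> None:
    """Write a mesh as ASCII PLY or OFF, chosen by file extension."""
    ext = os.path.splitext(path)[1].lower()
    tm = mesh.to_trimesh()
    if ext == ".ply":
        data = trimesh.exchange.ply.export_ply(tm, encoding="ascii")
    elif ext == ".off":
        data = trimesh.exchange.off.export_off(tm)
    else:
        raise ValueError(f"unsupported mesh format: {ext}")
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


def read_mesh(path: str) -> TriSurfaceMesh:
    """Read a PLY or OFF mesh from disk."""
    ext = os.path.splitext(path)[1].lower()
    if ext not in (".ply", ".off"):
        raise ValueError(f"unsupported mesh format: {ext}")
    tm = trimesh.load(path, file_type=ext[1:], process=False)
    return TriSurfaceMesh.from_trimesh(tm)
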