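"""Lightweight triangle-mesh container and geometric queries.

Meshes live in world millimetres.  The container is deliberately minimal —
vertices, faces and a handful of cached derived quantities — so that vertex
ordering is fully deterministic (no silent re-indexing as done by generic
mesh libraries).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree


@dataclass
class TriangleMesh:
    """Triangulated surface in world mm.

    vertices : (n, 3) float array
    faces    : (m, 3) int array of vertex indices, consistently oriented
    """

    vertices: np.ndarray
    faces: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")

    # -- basic counts -----------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        """Same connectivity, new vertex positions."""
        return TriangleMesh(np.asarray(vertices, float), self.faces.copy())

    # -- derived structure (cached on first use) --------------------------
    @property
    def edges_unique(self) -> np.ndarray:
        if "edges_unique" not in self._cache:
            e = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
            self._cache["edges_unique"] = np.unique(e, axis=0)
        return self._cache["edges_unique"]

    @property
    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges_unique) + self.n_faces

    @property
    def vertex_neighbors(self) -> list[np.ndarray]:
        """1-ring neighbour indices per vertex (sorted, unique)."""
        if "vertex_neighbors" not in self._cache:
            e = self.edges_unique
            order = np.concatenate([e[:, 0], e[:, 1]])
            other = np.concatenate([e[:, 1], e[:, 0]])
            idx = np.argsort(order, kind="stable")
            order, other = order[idx], other[idx]
            starts = np.searchsorted(order, np.arange(self.n_vertices + 1))
            self._cache["vertex_neighbors"] = [
                np.sort(other[starts[i]:starts[i + 1]])
                for i in range(self.n_vertices)
            ]
        return self._cache["vertex_neighbors"]

    @property
    def neighbor_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """(indptr, indices) CSR of the vertex adjacency graph."""
        if "neighbor_csr" not in self._cache:
            nb = self.vertex_neighbors
            indptr = np.zeros(self.n_vertices + 1, dtype=np.int64)
            indptr[1:] = np.cumsum([len(a) for a in nb])
            indices = np.concatenate(nb) if nb else np.empty(0, np.int64)
            self._cache["neighbor_csr"] = (indptr, indices)
        return self._cache["neighbor_csr"]

    # -- geometry ---------------------------------------------------------
    @property
    def triangles(self) -> np.ndarray:
        return self.vertices[self.faces]

    @property
    def face_normals(self) -> np.ndarray:
        t = self.triangles
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        return n  # area-weighted (not normalized)

    @property
    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_normals, axis=1)

    @property
    def area(self) -> float:
        return float(self.face_areas.sum())

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted unit vertex normals."""
        fn = self.face_normals
        vn = np.zeros_like(self.vertices)
        for c in range(3):
            np.add.at(vn, self.faces[:, c], fn)
        norms = np.linalg.norm(vn, axis=1)
        norms[norms == 0] = 1.0
        return vn / norms[:, None]

    @property
    def volume(self) -> float:
        """Signed enclosed volume (divergence theorem); positive for
        consistently outward-oriented closed meshes."""
        t = self.triangles
        return float(np.einsum("ij,ij->i", t[:, 0],
                               np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    # -- validity ---------------------------------------------------------
    def is_closed_manifold(self) -> bool:
        """Every edge shared by exactly two faces."""
        e = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def orient_outward(self) -> "TriangleMesh":
        """Flip all faces if the signed volume is negative."""
        if self.volume < 0:
            return TriangleMesh(self.vertices.copy(), self.faces[:, ::-1].copy())
        return self

    def to_trimesh(self):
        import trimesh
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(),
                               process=False)


# ---------------------------------------------------------------------------
# graph smoothing (used for scalar maps and displacement fields)

def smooth_vertex_values(mesh: TriangleMesh, values: np.ndarray,
                         n_iterations: int, lam: float = 0.5,
                         conservative: bool = True) -> np.ndarray:
    """Iterative graph diffusion of per-vertex values.

    conservative=True (default) uses a symmetric-Laplacian step
    ``v_i += (lam/d_max) * sum_{j~i} (v_j - v_i)`` which conserves the sum
    (hence the mean) exactly on any closed mesh; on a regular graph it is
    identical to 1-ring averaging ``v <- (1-lam) v + lam mean(neighbours)``,
    which is what conservative=False computes.  Works for (n,) scalars or
    (n, k) vector fields.
    """
    indptr, indices = mesh.neighbor_csr
    counts = np.diff(indptr).astype(float)
    safe_counts = np.where(counts == 0, 1.0, counts)
    d_max = float(counts.max()) if len(counts) else 1.0
    v = np.asarray(values, dtype=float).copy()
    vec = v.ndim > 1

    def neighbor_sum(x):
        if vec:
            out = np.empty_like(x)
            for c in range(x.shape[1]):
                s = np.add.reduceat(x[indices, c], indptr[:-1])
                s[counts == 0] = 0.0
                out[:, c] = s
            return out
        s = np.add.reduceat(x[indices], indptr[:-1])
        s[counts == 0] = 0.0
        return s

    for _ in range(int(n_iterations)):
        s = neighbor_sum(v)
        if conservative:
            deg = counts[:, None] if vec else counts
            v = v + (lam / d_max) * (s - deg * v)
        else:
            mean = s / (safe_counts[:, None] if vec else safe_counts)
            v = (1.0 - lam) * v + lam * mean
    return v


# ---------------------------------------------------------------------------
# exact point -> mesh distance

def closest_point_on_triangles(points: np.ndarray, tri: np.ndarray):
    """Closest point on each triangle for each point.

    points : (p, 3);  tri : (p, 3, 3) one triangle per point.
    Returns (closest (p,3), squared distance (p,)).
    Region-based algorithm (Eberly) vectorized over all point/triangle pairs.
    """
    p = np.asarray(points, float)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]; done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]; done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]; done |= m

    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = d1 - d3
    t = np.where(denom != 0, d1 / np.where(denom == 0, 1, denom), 0.0)
    out[m] = a[m] + t[m, None] * ab[m]; done |= m

    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = d2 - d6
    t = np.where(denom != 0, d2 / np.where(denom == 0, 1, denom), 0.0)
    out[m] = a[m] + t[m, None] * ac[m]; done |= m

    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    denom = (d4 - d3) + (d5 - d6)
    t = np.where(denom != 0, (d4 - d3) / np.where(denom == 0, 1, denom), 0.0)
    out[m] = b[m] + t[m, None] * (c[m] - b[m]); done |= m

    # interior
    m = ~done
    denom = va + vb + vc
    denom = np.where(denom == 0, 1, denom)
    v = vb / denom
    w = vc / denom
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]

    d2_out = np.einsum("ij,ij->i", p - out, p - out)
    return out, d2_out


class MeshProximity:
    """Exact nearest-point queries against a triangle mesh.

    Candidate triangles come from a KD-tree on triangle centroids; the
    search radius is grown until the exact point-triangle distance is
    provably minimal (centroid distance minus the largest triangle radius
    bounds the true distance from below).
    """

    def __init__(self, mesh: TriangleMesh):
        self.mesh = mesh
        self.tri = mesh.triangles
        self.centroids = self.tri.mean(axis=1)
        self.radii = np.linalg.norm(
            self.tri - self.centroids[:, None, :], axis=2).max(axis=1)
        self.max_radius = float(self.radii.max()) if len(self.radii) else 0.0
        self.tree = cKDTree(self.centroids)

    def query(self, points: np.ndarray, k: int = 8):
        """Returns (distances (p,), closest points (p,3), face ids (p,))."""
        points = np.atleast_2d(np.asarray(points, float))
        n = len(points)
        k = min(k, len(self.centroids))
        cd, ci = self.tree.query(points, k=k)
        if k == 1:
            cd = cd[:, None]; ci = ci[:, None]
        best_d2 = np.full(n, np.inf)
        best_pt = np.zeros((n, 3))
        best_f = np.zeros(n, dtype=np.int64)
        for col in range(k):
            fid = ci[:, col]
            cp, d2 = closest_point_on_triangles(points, self.tri[fid])
            upd = d2 < best_d2
            best_d2[upd] = d2[upd]
            best_pt[upd] = cp[upd]
            best_f[upd] = fid[upd]
        # guarantee exactness: any triangle whose centroid is farther than
        # best + max_radius cannot beat the current best
        bound = np.sqrt(best_d2) + self.max_radius + 1e-12
        need = cd[:, -1] < bound
        for i in np.nonzero(need)[0]:
            cand = self.tree.query_ball_point(points[i], bound[i])
            cand = np.asarray(cand, dtype=np.int64)
            if len(cand) == 0:
                continue
            cp, d2 = closest_point_on_triangles(
                np.repeat(points[i][None], len(cand), axis=0), self.tri[cand])
            j = int(np.argmin(d2))
            if d2[j] < best_d2[i]:
                best_d2[i] = d2[j]
                best_pt[i] = cp[j]
                best_f[i] = cand[j]
        return np.sqrt(best_d2), best_pt, best_f


# ---------------------------------------------------------------------------
# exact triangle-triangle intersection census

def _tri_tri_intersect(t1: np.ndarray, t2: np.ndarray) -> np.ndarray:
    """Vectorized Moller (1997) triangle-triangle intersection test.

    t1, t2 : (n, 3, 3).  Returns boolean (n,).  Pairs that merely touch at
    shared vertices should be filtered out by the caller.
    """
    eps = 1e-12
    n2 = np.cross(t2[:, 1] - t2[:, 0], t2[:, 2] - t2[:, 0])
    d2 = -np.einsum("ij,ij->i", n2, t2[:, 0])
    dv1 = np.einsum("ij,ikj->ik", n2, t1) + d2[:, None]
    dv1[np.abs(dv1) < eps] = 0.0

    n1 = np.cross(t1[:, 1] - t1[:, 0], t1[:, 2] - t1[:, 0])
    d1 = -np.einsum("ij,ij->i", n1, t1[:, 0])
    dv2 = np.einsum("ij,ikj->ik", n1, t2) + d1[:, None]
    dv2[np.abs(dv2) < eps] = 0.0

    res = np.ones(len(t1), dtype=bool)
    # same-side rejection
    res &= ~((dv1 > 0).all(axis=1) | (dv1 < 0).all(axis=1))
    res &= ~((dv2 > 0).all(axis=1) | (dv2 < 0).all(axis=1))
    active = np.nonzero(res)[0]
    if len(active) == 0:
        return res

    # coplanar pairs are rare on float meshes; treat zero-plane pairs as
    # non-intersecting (a touching contact, not a crossing)
    coplanar = (dv1[active] == 0).all(axis=1)
    res[active[coplanar]] = False
    active = active[~coplanar]
    if len(active) == 0:
        return res

    D = np.cross(n1[active], n2[active])
    axis = np.argmax(np.abs(D), axis=1)
    p1 = np.take_along_axis(t1[active, :, :],
                            axis[:, None, None], axis=2)[:, :, 0]
    p2 = np.take_along_axis(t2[active, :, :],
                            axis[:, None, None], axis=2)[:, :, 0]

    def interval(proj, dv):
        # isolate the vertex on its own side of the other triangle's plane
        n = len(proj)
        iv = np.empty((n, 2))
        ok = np.ones(n, dtype=bool)
        for i in range(n):
            d = dv[i]
            signs = np.sign(d)
            # choose the odd vertex out
            lone = None
            for cand in range(3):
                others = [x for x in range(3) if x != cand]
                if signs[cand] != 0 and (
                        signs[others[0]] * signs[cand] <= 0
                        and signs[others[1]] * signs[cand] <= 0):
                    lone = cand
                    break
            if lone is None:
                # degenerate: triangle touches plane only
                ok[i] = False
                iv[i] = 0
                continue
            o = [x for x in range(3) if x != lone]
            t_a = proj[i, o[0]] + (proj[i, lone] - proj[i, o[0]]) * (
                d[o[0]] / (d[o[0]] - d[lone]))
            t_b = proj[i, o[1]] + (proj[i, lone] - proj[i, o[1]]) * (
                d[o[1]] / (d[o[1]] - d[lone]))
            iv[i] = sorted((t_a, t_b))
        return iv, ok

    iv1, ok1 = interval(p1, dv1[active])
    iv2, ok2 = interval(p2, dv2[active])
    ok = ok1 & ok2
    overlap = (iv1[:, 0] < iv2[:, 1] - eps) & (iv2[:, 0] < iv1[:, 1] - eps)
    res[active] = ok & overlap
    return res


def self_intersection_pairs(mesh: TriangleMesh) -> np.ndarray:
    """Pairs of non-adjacent triangles that intersect, found by a spatial
    hash over triangle bounding boxes and decided by the exact interval
    test."""
    tri = mesh.triangles
    m = len(tri)
    if m == 0:
        return np.empty((0, 2), dtype=np.int64)
    lo = tri.min(axis=1)
    hi = tri.max(axis=1)
    cent = tri.mean(axis=1)
    radii = np.linalg.norm(tri - cent[:, None, :], axis=2).max(axis=1)
    cell = max(2.0 * float(np.median(radii)), 1e-6)

    buckets: dict = {}
    ilo = np.floor(lo / cell).astype(np.int64)
    ihi = np.floor(hi / cell).astype(np.int64)
    for t in range(m):
        for cx in range(ilo[t, 0], ihi[t, 0] + 1):
            for cy in range(ilo[t, 1], ihi[t, 1] + 1):
                for cz in range(ilo[t, 2], ihi[t, 2] + 1):
                    buckets.setdefault((cx, cy, cz), []).append(t)

    cand = set()
    for members in buckets.values():
        if len(members) < 2:
            continue
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                cand.add((a, b) if a < b else (b, a))
    if not cand:
        return np.empty((0, 2), dtype=np.int64)
    pairs = np.array(sorted(cand), dtype=np.int64)

    # AABB overlap filter
    ok = np.all(lo[pairs[:, 0]] <= hi[pairs[:, 1]], axis=1) \
        & np.all(lo[pairs[:, 1]] <= hi[pairs[:, 0]], axis=1)
    pairs = pairs[ok]
    if len(pairs) == 0:
        return pairs
    f = mesh.faces
    shared = np.zeros(len(pairs), dtype=bool)
    fa = f[pairs[:, 0]]
    fb = f[pairs[:, 1]]
    for i in range(3):
        for j in range(3):
            shared |= fa[:, i] == fb[:, j]
    pairs = pairs[~shared]
    if len(pairs) == 0:
        return pairs
    hits = _tri_tri_intersect(tri[pairs[:, 0]], tri[pairs[:, 1]])
    return pairs[hits]


def count_self_intersections(mesh: TriangleMesh, pad: float = 0.0) -> int:
    """Number of pairs of non-adjacent triangles that intersect."""
    return int(len(self_intersection_pairs(mesh)))
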