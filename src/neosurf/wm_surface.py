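"""WM/GM interface extraction with a guaranteed spherical topology.

The topology guarantee comes from collapsing a filled ellipsoid that
encloses the WM mask onto the mask by homotopic erosion: only simple points
outside the mask are removed, ordered farthest-from-mask first, so the
result deformation-retracts to the ellipsoid (genus zero) while hugging the
mask everywhere the mask itself is well-formed.  Handles are bridged by
membranes, cavities stay filled.  The collapse runs under the 6/26
connectivity pair, the pair consistent with the marching-cubes case table
used afterwards, so the triangulated surface of the corrected mask is a
single closed genus-zero mesh.

The mesh is then coarsened by link-condition edge collapse, inflated to a
sphere by iterative Laplacian smoothing, and resampled onto a subdivided
icosahedron (20*4^level triangles) to give every subject identical
connectivity.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .mesh import MeshProximity, TriangleMesh, count_self_intersections
from .topology import NEIGHBOR_OFFSETS, is_simple_6, pack_neighborhood
from .volume_io import VoxelGrid


@dataclass
class SphereMap:
    """Unit-sphere coordinates paired with the mesh they parameterize."""

    mesh: TriangleMesh
    sphere_coords: np.ndarray  # (n, 3), unit norm

    def __post_init__(self):
        norms = np.linalg.norm(self.sphere_coords, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("sphere coordinates must have unit norm")

    def sphere_mesh(self) -> TriangleMesh:
        return TriangleMesh(self.sphere_coords.copy(), self.mesh.faces.copy())

    def flipped_triangle_count(self) -> int:
        """Spherical triangles whose orientation (sign of the triple
        product) disagrees with the outward orientation."""
        t = self.sphere_coords[self.mesh.faces]
        signs = np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2]))
        return int((signs <= 0).sum())


# ---------------------------------------------------------------------------
# topology-corrected mask and meshing

def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
    if n == 0:
        raise ValueError("empty mask")
    if n == 1:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def _enclosing_ellipsoid(mask: np.ndarray, dilate: int = 2) -> np.ndarray:
    """Filled ellipsoid (axis-aligned) covering the mask bounding box."""
    idx = np.nonzero(mask)
    lo = np.array([a.min() for a in idx], dtype=float)
    hi = np.array([a.max() for a in idx], dtype=float)
    c = (lo + hi) / 2.0
    # semi-axes: half-extent * sqrt(3) covers the box corners; + margin
    semi = (hi - lo) / 2.0 * np.sqrt(3.0) + dilate
    semi = np.minimum(semi, np.array(mask.shape) / 2.0 - 1.5)
    semi = np.maximum(semi, (hi - lo) / 2.0 + 1.0)  # never thinner than box
    grids = np.ogrid[[slice(0, s) for s in mask.shape]]
    q = sum(((g - cc) / ss) ** 2 for g, cc, ss in zip(grids, c, semi))
    ell = q <= 1.0
    if not (ell | mask).sum() == ell.sum():
        # mask corners outside the clipped ellipsoid: union them in
        ell = ell | ndimage.binary_dilation(mask)
    return ell


def homotopic_collapse(mask: np.ndarray, verbose: bool = False) -> np.ndarray:
    """Collapse an enclosing ellipsoid onto ``mask`` by removing simple
    points (6/26 pair) outside the mask, farthest from the mask first.

    Returns a topology-corrected superset of the mask with the ellipsoid's
    (spherical) topology.
    """
    mask = np.asarray(mask, dtype=bool)
    obj = _enclosing_ellipsoid(mask) | mask
    dist = ndimage.distance_transform_edt(~mask)

    heap = []
    counter = 0
    in_heap = np.zeros(mask.shape, dtype=bool)
    border = obj & ~ndimage.binary_erosion(obj)
    for i, j, k in zip(*np.nonzero(border & ~mask)):
        heapq.heappush(heap, (-dist[i, j, k], counter, i, j, k))
        counter += 1
        in_heap[i, j, k] = True

    nx, ny, nz = mask.shape
    offs = NEIGHBOR_OFFSETS
    removed = 0
    while heap:
        _, _, i, j, k = heapq.heappop(heap)
        in_heap[i, j, k] = False
        if not obj[i, j, k] or mask[i, j, k]:
            continue
        if not is_simple_6(pack_neighborhood(obj, i, j, k)):
            continue
        obj[i, j, k] = False
        removed += 1
        for dx, dy, dz in offs:
            if dx == dy == dz == 0:
                continue
            x, y, z = i + dx, j + dy, k + dz
            if (0 <= x < nx and 0 <= y < ny and 0 <= z < nz
                    and obj[x, y, z] and not mask[x, y, z]
                    and not in_heap[x, y, z]):
                heapq.heappush(heap, (-dist[x, y, z], counter, x, y, z))
                counter += 1
                in_heap[x, y, z] = True
    if verbose:
        print(f"homotopic collapse removed {removed} voxels")
    return obj


def extract_wm_mesh(wm_mask: VoxelGrid | np.ndarray,
                    affine: np.ndarray | None = None) -> TriangleMesh:
    """Closed, manifold, genus-zero mesh on the boundary of the
    topology-corrected WM mask (world-mm coordinates)."""
    if isinstance(wm_mask, VoxelGrid):
        affine = wm_mask.affine
        mask = wm_mask.data.astype(bool)
    else:
        mask = np.asarray(wm_mask, dtype=bool)
        affine = np.eye(4) if affine is None else np.asarray(affine, float)
    if not mask.any():
        raise ValueError("empty WM mask")
    mask = _largest_component(mask)

    pad = 3
    mask_p = np.pad(mask, pad)
    corrected = homotopic_collapse(mask_p)

    verts, faces, _, _ = measure.marching_cubes(
        corrected.astype(np.float32), level=0.5)
    m = TriangleMesh(verts, faces)
    if not m.is_closed_manifold():  # pragma: no cover - guarded by collapse
        warnings.warn("marching cubes produced a non-manifold mesh",
                      stacklevel=2)
    # voxel -> world (account for padding)
    v = m.vertices - pad
    world = v @ affine[:3, :3].T + affine[:3, 3]
    return TriangleMesh(world, m.faces).orient_outward()


# ---------------------------------------------------------------------------
# edge-collapse coarsening

def coarsen_mesh(mesh: TriangleMesh, target_vertex_count: int) -> TriangleMesh:
    """Shortest-edge collapse decimation preserving the closed manifold.

    Each collapse merges an edge to its midpoint and is applied only when
    the link condition holds (the two endpoints share exactly the two
    opposite vertices of their common faces) and no incident triangle
    flips.  Stops at the target or when no further collapse is valid.
    """
    if target_vertex_count >= mesh.n_vertices:
        return mesh.copy()

    verts = [tuple(v) for v in mesh.vertices]
    pos = np.array(mesh.vertices, dtype=float)
    faces = {fi: tuple(f) for fi, f in enumerate(mesh.faces)}
    vert_faces: dict[int, set] = {i: set() for i in range(len(verts))}
    for fi, f in faces.items():
        for v in f:
            vert_faces[v].add(fi)
    alive = np.ones(len(verts), dtype=bool)

    def neighbors(u):
        nb = set()
        for fi in vert_faces[u]:
            nb.update(faces[fi])
        nb.discard(u)
        return nb

    heap = []
    counter = 0

    def push_edges(u):
        nonlocal counter
        for v in neighbors(u):
            a, b = (u, v) if u < v else (v, u)
            d = float(np.linalg.norm(pos[a] - pos[b]))
            heapq.heappush(heap, (d, counter, a, b))
            counter += 1

    for u in range(len(verts)):
        for v in neighbors(u):
            if u < v:
                d = float(np.linalg.norm(pos[u] - pos[v]))
                heapq.heappush(heap, (d, counter, u, v))
                counter += 1

    n_alive = int(alive.sum())
    while heap and n_alive > target_vertex_count:
        d, _, u, v = heapq.heappop(heap)
        if not (alive[u] and alive[v]):
            continue
        nu = neighbors(u)
        if v not in nu:
            continue
        if abs(float(np.linalg.norm(pos[u] - pos[v])) - d) > 1e-12:
            continue  # stale entry
        nv = neighbors(v)
        # link condition for closed manifolds
        if len(nu & nv) != 2:
            continue
        shared_faces = vert_faces[u] & vert_faces[v]
        if len(shared_faces) != 2:
            continue
        mid = (pos[u] + pos[v]) / 2.0

        # flip check: surviving faces keep normal direction
        ok = True
        changed = (vert_faces[u] | vert_faces[v]) - shared_faces
        for fi in changed:
            f = faces[fi]
            old = [pos[x] for x in f]
            new = [mid if x in (u, v) else pos[x] for x in f]
            n_old = np.cross(old[1] - old[0], old[2] - old[0])
            n_new = np.cross(new[1] - new[0], new[2] - new[0])
            if np.dot(n_old, n_new) <= 1e-12:
                ok = False
                break
        if not ok:
            continue

        # collapse v into u
        pos[u] = mid
        alive[v] = False
        n_alive -= 1
        for fi in shared_faces:
            for x in faces[fi]:
                vert_faces[x].discard(fi)
            del faces[fi]
        for fi in list(vert_faces[v]):
            f = faces[fi]
            faces[fi] = tuple(u if x == v else x for x in f)
            vert_faces[v].discard(fi)
            vert_faces[u].add(fi)
        vert_faces[v] = set()
        push_edges(u)

    if n_alive > target_vertex_count:
        warnings.warn(
            f"coarsening stopped at {n_alive} vertices "
            f"(target {target_vertex_count})", stacklevel=2)

    remap = -np.ones(len(verts), dtype=np.int64)
    remap[alive] = np.arange(n_alive)
    new_faces = np.array([[remap[x] for x in f] for f in faces.values()],
                         dtype=np.int64)
    return TriangleMesh(pos[alive], new_faces)


# ---------------------------------------------------------------------------
# inflation and icosahedral resampling

def inflate_to_sphere(mesh: TriangleMesh, lam: float = 0.5,
                      max_iterations: int = 500,
                      convexity_target: float = 1.0,
                      untangle_iterations: int = 200) -> SphereMap:
    """Inflate a genus-zero mesh to the unit sphere.

    Iterative Laplacian smoothing until the convexity proxy (fraction of
    vertices whose 1-ring mean lies inside, i.e. outward-positive mean
    curvature) reaches ``convexity_target``; then project radially and
    untangle any flipped spherical triangles by tangential smoothing.
    """
    if mesh.euler_characteristic != 2:
        raise ValueError("inflation requires a genus-zero closed mesh")
    from .mesh import smooth_vertex_values

    v = mesh.vertices.copy()
    work = mesh.with_vertices(v)
    for it in range(max_iterations):
        c = v.mean(axis=0)
        radial = v - c
        rn = np.linalg.norm(radial, axis=1, keepdims=True)
        rn[rn == 0] = 1.0
        radial /= rn
        mean_nb = smooth_vertex_values(work, v, 1, lam=1.0,
                                       conservative=False)
        lap = mean_nb - v
        convex = np.einsum("ij,ij->i", lap, radial) <= 1e-10
        if convex.mean() >= convexity_target and it > 0:
            break
        v = v + lam * lap
        work = mesh.with_vertices(v)

    c = v.mean(axis=0)
    s = v - c
    s /= np.linalg.norm(s, axis=1, keepdims=True)
    sm = SphereMap(mesh, s)

    for _ in range(untangle_iterations):
        if sm.flipped_triangle_count() == 0:
            break
        mean_nb = smooth_vertex_values(mesh.with_vertices(s), s, 1,
                                       lam=1.0, conservative=False)
        s = s + 0.5 * (mean_nb - s)
        s /= np.linalg.norm(s, axis=1, keepdims=True)
        sm = SphereMap(mesh, s)
    return sm


def icosahedron_mesh(level: int) -> TriangleMesh:
    """Subdivided icosahedron on the unit sphere: 20*4^level triangles,
    10*4^level + 2 vertices, deterministic ordering."""
    import trimesh
    ico = trimesh.creation.icosphere(subdivisions=int(level), radius=1.0)
    return TriangleMesh(np.array(ico.vertices), np.array(ico.faces))


def icosahedron_resample(mesh: TriangleMesh, sphere: SphereMap,
                         level: int) -> TriangleMesh:
    """Resample ``mesh`` onto a subdivided icosahedron via the sphere map.

    Each icosahedral vertex is located on the spherical triangulation
    (nearest triangle; exact for an unflipped map) and its barycentric
    coordinates are pulled back to the original mesh.
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    ico = icosahedron_mesh(level)
    smesh = sphere.sphere_mesh()
    prox = MeshProximity(smesh)
    _, cp, fid = prox.query(ico.vertices)

    tri = smesh.triangles[fid]
    # barycentric coordinates of cp in tri
    v0 = tri[:, 1] - tri[:, 0]
    v1 = tri[:, 2] - tri[:, 0]
    v2 = cp - tri[:, 0]
    d00 = np.einsum("ij,ij->i", v0, v0)
    d01 = np.einsum("ij,ij->i", v0, v1)
    d11 = np.einsum("ij,ij->i", v1, v1)
    d20 = np.einsum("ij,ij->i", v2, v0)
    d21 = np.einsum("ij,ij->i", v2, v1)
    denom = d00 * d11 - d01 * d01
    denom[denom == 0] = 1.0
    b1 = (d11 * d20 - d01 * d21) / denom
    b2 = (d00 * d21 - d01 * d20) / denom
    b0 = 1.0 - b1 - b2
    bary = np.clip(np.stack([b0, b1, b2], axis=1), 0.0, 1.0)
    bary /= bary.sum(axis=1, keepdims=True)

    orig_tri = mesh.triangles[fid]
    new_verts = np.einsum("ik,ikj->ij", bary, orig_tri)
    return TriangleMesh(new_verts, ico.faces)


# ---------------------------------------------------------------------------
# self-proximity

def enforce_self_proximity(mesh: TriangleMesh, min_separation: float = 0.25,
                           max_iterations: int = 10,
                           normal_dot_max: float = 0.3) -> TriangleMesh:
    """Push apart non-adjacent, opposing mesh regions closer than
    ``min_separation`` mm until no triangle pair intersects.

    Vertex pairs are candidates when they are within the separation, at
    graph distance > 2, and their normals oppose (dot < normal_dot_max) —
    the configuration of two sheets about to touch.
    """
    from scipy.spatial import cKDTree

    v = mesh.vertices.copy()
    nb = mesh.vertex_neighbors
    near_sets = [set(a.tolist()) | {i} for i, a in enumerate(nb)]
    two_ring = []
    for i, s in enumerate(near_sets):
        acc = set(s)
        for j in nb[i]:
            acc |= near_sets[j]
        two_ring.append(acc)

    for _ in range(max_iterations):
        work = mesh.with_vertices(v)
        normals = work.vertex_normals()
        tree = cKDTree(v)
        pairs = tree.query_pairs(min_separation, output_type="ndarray")
        if len(pairs):
            keep = np.array([
                b not in two_ring[a] for a, b in pairs], dtype=bool)
            pairs = pairs[keep]
        if len(pairs):
            dots = np.einsum("ij,ij->i", normals[pairs[:, 0]],
                             normals[pairs[:, 1]])
            pairs = pairs[dots < normal_dot_max]
        if len(pairs) == 0:
            if count_self_intersections(work) == 0:
                break
            # intersecting but no close pairs: relax toward 1-ring means
            from .mesh import smooth_vertex_values
            v = smooth_vertex_values(work, v, 1, lam=0.3,
                                     conservative=False)
            continue
        disp = np.zeros_like(v)
        cnt = np.zeros(len(v))
        d = v[pairs[:, 0]] - v[pairs[:, 1]]
        dn = np.linalg.norm(d, axis=1)
        dn[dn == 0] = 1e-9
        push = (min_separation - dn) / 2.0
        unit = d / dn[:, None]
        np.add.at(disp, pairs[:, 0], 0.6 * push[:, None] * unit)
        np.add.at(disp, pairs[:, 1], -0.6 * push[:, None] * unit)
        np.add.at(cnt, pairs[:, 0], 1)
        np.add.at(cnt, pairs[:, 1], 1)
        scale = np.where(cnt > 0, 1.0 / np.maximum(cnt, 1), 0.0)
        v = v + disp * scale[:, None]
    return mesh.with_vertices(v)
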