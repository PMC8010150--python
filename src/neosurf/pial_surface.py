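"""Pial surface reconstruction by Laplacian-field expansion of the WM mesh.

A harmonic potential is solved on the cortical GM domain with the WM
boundary at 0 and the outer boundary — visible CSF, the sulcal skeleton and
the brain hull — at 1.  Each WM vertex is carried outward along the
potential's gradient streamline; streamlines of a harmonic field never
cross, so the mapping is one-to-one and the expanded (intermediate pial)
surface keeps the WM mesh connectivity without topological defects.  A
short-range gradient refinement then fine-tunes the surface to the actual
GM/CSF edge wherever image contrast supports one, with the skeleton acting
as a barrier against crossing into the opposite sulcal bank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .csf_skeleton import SkeletonVoxels, UnionVolume, build_union
from .gradient_refine import DeformationParams, ProfileParams, deform_to_edges
from .mesh import TriangleMesh
from .volume_io import LabelVolume, VoxelGrid

_B6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class LaplacianField:
    """Discrete harmonic potential on the cortical domain."""

    potential: VoxelGrid
    interior: np.ndarray       # voxels iterated by the solver
    fixed_zero: np.ndarray     # WM-side Dirichlet boundary
    fixed_one: np.ndarray      # skeleton + hull + visible-CSF boundary
    residuals: list = field(default_factory=list)
    excluded: np.ndarray | None = None  # interior voxels unreachable from
    #                                     either boundary


@dataclass
class StreamlineMap:
    """Per-WM-vertex streamline summary; arrival points define the
    intermediate pial surface with WM connectivity."""

    arrival_points: np.ndarray
    lengths: np.ndarray
    flagged: np.ndarray        # exceeded max length or stalled
    arrival_potential: np.ndarray
    polylines: list | None = None


def solve_laplace(domain: UnionVolume, skeleton: SkeletonVoxels | np.ndarray,
                  csf_as_boundary: bool = True, tol: float = 1e-5,
                  max_sweeps: int = 5000, omega: float = 1.9
                  ) -> LaplacianField:
    """Solve the 6-neighbour discrete Laplace equation on the GM domain.

    Dirichlet conditions: 0 on WM voxels, 1 on skeleton + hull voxels and —
    by default — on visible CSF voxels, which realizes the rule that the
    expansion targets the real GM/CSF boundary where one is observed and
    the hypothesized skeleton where it is not.  Red-black successive
    over-relaxation; the recorded residual is the largest absolute update
    per sweep.
    """
    skel_mask = skeleton.mask if isinstance(skeleton, SkeletonVoxels) \
        else np.asarray(skeleton, bool)
    one = (skel_mask | domain.hull)
    if csf_as_boundary:
        one = one | domain.csf
    zero = domain.wm
    interior = domain.union & ~one & ~zero

    # exclude interior voxels with no path to the outer boundary
    lab, n = ndimage.label(interior | one, structure=_B6)
    good = np.unique(lab[one])
    good = good[good > 0]
    excluded = interior & ~np.isin(lab, good)
    interior = interior & ~excluded
    if not interior.any() and not one.any():
        raise ValueError("no conducting path between WM boundary and "
                         "skeleton/hull")

    pot = np.zeros(domain.union.shape, dtype=np.float64)
    pot[one] = 1.0

    # red-black ordering on the 6-neighbour stencil
    idx = np.indices(pot.shape).sum(axis=0)
    red = interior & (idx % 2 == 0)
    black = interior & (idx % 2 == 1)
    padded = np.pad(pot, 1)
    core = tuple(slice(1, -1) for _ in range(3))
    residuals = []

    def neighbor_mean(p):
        return (p[2:, 1:-1, 1:-1] + p[:-2, 1:-1, 1:-1]
                + p[1:-1, 2:, 1:-1] + p[1:-1, :-2, 1:-1]
                + p[1:-1, 1:-1, 2:] + p[1:-1, 1:-1, :-2]) / 6.0

    for sweep in range(max_sweeps):
        max_update = 0.0
        for color in (red, black):
            padded[core] = pot
            nm = neighbor_mean(padded)
            upd = (1 - omega) * pot[color] + omega * nm[color]
            max_update = max(max_update,
                             float(np.max(np.abs(upd - pot[color])))
                             if color.any() else 0.0)
            pot[color] = upd
        residuals.append(max_update)
        if max_update < tol:
            break

    return LaplacianField(potential=VoxelGrid(pot, domain.affine),
                          interior=interior, fixed_zero=zero, fixed_one=one,
                          residuals=residuals, excluded=excluded)


# ---------------------------------------------------------------------------
# streamline tracing

def _direction_field(field: LaplacianField):
    grid = field.potential
    sp = grid.spacing
    g = np.gradient(grid.data, *sp)
    # index-axis gradient -> world direction through the rotation part
    direction = grid.affine[:3, :3] / sp
    return g, direction


def trace_streamlines(field: LaplacianField, wm_mesh: TriangleMesh,
                      step_fraction: float = 0.25, eps: float = 0.02,
                      max_length: float = 30.0,
                      keep_polylines: bool = False,
                      record_every: int = 4
                      ) -> tuple[StreamlineMap, TriangleMesh]:
    """Integrate each WM vertex along the normalized potential gradient
    (trilinear interpolation, midpoint RK2) until the potential reaches
    1 - eps or the point enters the Dirichlet-1 boundary.

    Returns the streamline map and the intermediate pial mesh (arrival
    points with WM connectivity).  Streamlines exceeding ``max_length`` mm
    (no conducting path, e.g. non-cortical surface patches) are flagged
    and keep their starting position.
    """
    grid = field.potential
    sp = grid.spacing
    step = step_fraction * float(np.min(sp))
    rot = grid.affine[:3, :3] / sp

    # tracing copy of the potential: continue the value 1 a few voxels
    # beyond the Dirichlet-1 boundary so the gradient never reverses as a
    # streamline crosses the (blocky) boundary shell
    pot_trace = grid.data.copy()
    outside = ~(field.interior | field.fixed_one | field.fixed_zero)
    ring = ndimage.binary_dilation(field.fixed_one, structure=_B6,
                                   iterations=3) & outside
    pot_trace[ring] = 1.0
    gx, gy, gz = np.gradient(pot_trace, *sp)

    one_f = field.fixed_one.astype(np.float64)

    def interp(arr, pts):
        vox = np.atleast_2d(grid.voxel_from_world(pts))
        return ndimage.map_coordinates(arr, vox.T, order=1, mode="nearest")

    normals = wm_mesh.vertex_normals() if wm_mesh.n_faces else \
        np.zeros_like(wm_mesh.vertices)

    def world_dir(pts, fallback):
        comps = np.stack([interp(gx, pts), interp(gy, pts), interp(gz, pts)],
                         axis=1)
        d = comps @ rot.T
        norm = np.linalg.norm(d, axis=1, keepdims=True)
        weak = norm[:, 0] < 1e-9
        d = d / np.maximum(norm, 1e-12)
        # zero-gradient pockets (e.g. a vertex still just inside the WM
        # side): continue along the vertex normal until the field picks up
        d[weak] = fallback[weak]
        return d

    pts = wm_mesh.vertices.copy()
    n = len(pts)
    active = np.ones(n, dtype=bool)
    lengths = np.zeros(n)
    flagged = np.zeros(n, dtype=bool)
    polylines = [[p.copy()] for p in pts] if keep_polylines else None

    pot0 = interp(pot_trace, pts)
    active &= pot0 < 1.0 - eps

    max_steps = int(np.ceil(max_length / step))
    for it in range(max_steps):
        if not active.any():
            break
        p = pts[active]
        fb = normals[active]
        d1 = world_dir(p, fb)
        mid = p + 0.5 * step * d1
        d2 = world_dir(mid, fb)
        newp = p + step * d2

        pts[active] = newp
        lengths[active] += step
        if keep_polylines and it % record_every == 0:
            for i, ai in enumerate(np.nonzero(active)[0]):
                polylines[ai].append(newp[i].copy())

        pot = interp(pot_trace, newp)
        in_one = interp(one_f, newp) > 0.5
        done = (pot >= 1.0 - eps) | in_one
        idx_active = np.nonzero(active)[0]
        active[idx_active[done]] = False

    flagged[active] = True  # ran out of length budget
    if flagged.any():
        # a flagged streamline (no conducting path, e.g. a non-cortical
        # patch of the WM surface) keeps its starting position
        pts[flagged] = wm_mesh.vertices[flagged]
        lengths[flagged] = 0.0

    arrival_pot = interp(grid.data, pts)
    if keep_polylines:
        for i in range(n):
            polylines[i].append(pts[i].copy())
    smap = StreamlineMap(arrival_points=pts, lengths=lengths,
                         flagged=flagged, arrival_potential=arrival_pot,
                         polylines=polylines)
    intermediate = wm_mesh.with_vertices(pts)
    return smap, intermediate


# ---------------------------------------------------------------------------
# full pial reconstruction

def build_pial(wm_mesh: TriangleMesh, labels: LabelVolume,
               intensity: VoxelGrid, skeleton: SkeletonVoxels | np.ndarray,
               pparams: ProfileParams | None = None,
               dparams: DeformationParams | None = None,
               union: UnionVolume | None = None,
               refine: bool = True
               ) -> tuple[TriangleMesh, TriangleMesh, StreamlineMap]:
    """WM mesh -> Laplace -> streamlines -> short-range gradient refinement.

    Returns (pial mesh, intermediate pial mesh, streamline map); all meshes
    share the WM mesh connectivity, so thickness can be measured between
    linked vertices.
    """
    if union is None:
        union = build_union(labels)
    field = solve_laplace(union, skeleton)
    smap, intermediate = trace_streamlines(field, wm_mesh)
    if not refine:
        return intermediate, intermediate, smap

    pparams = pparams or ProfileParams(search_distance=1.5, search_step=0.25,
                                       expected_sign="auto")
    dparams = dparams or DeformationParams(
        resolution_schedule=((1.5, 0.5), (1.0, 0.25)))
    skel_mask = skeleton.mask if isinstance(skeleton, SkeletonVoxels) \
        else np.asarray(skeleton, bool)
    brain = ndimage.binary_closing(labels.data > 0, structure=_B6)
    pial = deform_to_edges(intermediate, intensity, pparams, dparams,
                           barrier=skel_mask & ~union.csf,
                           csf_mask=union.csf,
                           brain_mask=brain)
    return pial, intermediate, smap
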