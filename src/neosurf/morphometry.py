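"""Cortical morphometry: thickness, surface smoothing, sulcal depth,
landmark QA and depth-based template selection.

Thickness is measured in native space between the WM and pial surfaces;
the default uses the one-to-one vertex correspondence created by the
Laplacian expansion (linked), with nearest-point and symmetric variants.
Per-vertex maps are smoothed by iterative graph diffusion calibrated to a
requested Gaussian FWHM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import MeshProximity, TriangleMesh, smooth_vertex_values


@dataclass
class VertexScalarMap:
    """Per-vertex measurement bound to a specific mesh."""

    values: np.ndarray
    mesh: TriangleMesh
    name: str = ""
    fwhm: float = 0.0          # 0 = raw

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) != self.mesh.n_vertices:
            raise ValueError(
                f"map length {len(self.values)} != vertex count "
                f"{self.mesh.n_vertices}")


# ---------------------------------------------------------------------------
# thickness

def cortical_thickness(wm_mesh: TriangleMesh, pial_mesh: TriangleMesh,
                       method: str = "linked") -> VertexScalarMap:
    """Cortical thickness as the shortest distance between the WM and pial
    surfaces.

    linked    : Euclidean distance between corresponding vertices (requires
                shared connectivity, which the Laplacian expansion
                guarantees);
    nearest   : distance from each WM vertex to the pial surface
                (exact point-to-triangle);
    symmetric : mean of the two directed nearest distances per linked pair.
    """
    if method == "linked":
        if wm_mesh.n_vertices != pial_mesh.n_vertices or \
                not np.array_equal(wm_mesh.faces, pial_mesh.faces):
            raise ValueError("linked thickness requires meshes with "
                             "identical connectivity")
        t = np.linalg.norm(pial_mesh.vertices - wm_mesh.vertices, axis=1)
        return VertexScalarMap(t, wm_mesh, name="thickness-linked")
    if method == "nearest":
        d, _, _ = MeshProximity(pial_mesh).query(wm_mesh.vertices)
        return VertexScalarMap(d, wm_mesh, name="thickness-nearest")
    if method == "symmetric":
        d1, _, _ = MeshProximity(pial_mesh).query(wm_mesh.vertices)
        d2, _, _ = MeshProximity(wm_mesh).query(pial_mesh.vertices)
        if len(d1) != len(d2):
            raise ValueError("symmetric thickness requires equal vertex "
                             "counts")
        return VertexScalarMap((d1 + d2) / 2.0, wm_mesh,
                               name="thickness-symmetric")
    raise ValueError(f"unknown thickness method {method!r}")


# ---------------------------------------------------------------------------
# surface smoothing

def smoothing_iterations(mesh: TriangleMesh, fwhm: float,
                         lam: float = 0.5) -> int:
    """Number of graph-diffusion iterations approximating a Gaussian kernel
    of the requested FWHM (mm).

    Each symmetric-Laplacian step with strength ``lam`` adds about
    ``0.6 * lam * h^2`` to the surface variance of an impulse (h = mean
    edge length; the 0.6 lattice constant was calibrated against the
    measured impulse spread on icospheres); a 2-D Gaussian of the
    requested FWHM has radial variance 2 * (FWHM / 2.355)^2.
    """
    h = float(np.linalg.norm(
        mesh.vertices[mesh.edges_unique[:, 0]]
        - mesh.vertices[mesh.edges_unique[:, 1]], axis=1).mean())
    sigma2 = 2.0 * (fwhm / 2.355) ** 2
    return max(1, int(round(sigma2 / (0.6 * lam * h * h))))


def smooth_scalar_map(mesh: TriangleMesh, smap: VertexScalarMap | np.ndarray,
                      fwhm: float = 10.0) -> VertexScalarMap:
    """Diffusion-smooth a per-vertex map to approximately ``fwhm`` mm.

    The mean is conserved exactly (symmetric weighting); the variance
    decreases.  If ``fwhm`` is below the mesh edge length the raw map is
    returned with a warning.
    """
    import warnings

    values = smap.values if isinstance(smap, VertexScalarMap) \
        else np.asarray(smap, float)
    h = float(np.linalg.norm(
        mesh.vertices[mesh.edges_unique[:, 0]]
        - mesh.vertices[mesh.edges_unique[:, 1]], axis=1).mean())
    if fwhm < h:
        warnings.warn(f"fwhm {fwhm} mm below mean edge length {h:.2f} mm; "
                      "returning raw map", stacklevel=2)
        return VertexScalarMap(values.copy(), mesh, fwhm=0.0)
    n = smoothing_iterations(mesh, fwhm)
    sm = smooth_vertex_values(mesh, values, n, lam=0.5)
    name = smap.name if isinstance(smap, VertexScalarMap) else ""
    return VertexScalarMap(sm, mesh, name=name, fwhm=fwhm)


# ---------------------------------------------------------------------------
# sulcal depth

def sulcal_depth(mesh: TriangleMesh, hull_mesh: TriangleMesh
                 ) -> VertexScalarMap:
    """Per-vertex shortest Euclidean distance to the brain-hull surface —
    a burial-depth proxy: 0 on gyral crowns touching the hull, largest at
    sulcal fundi."""
    d, _, _ = MeshProximity(hull_mesh).query(mesh.vertices)
    return VertexScalarMap(d, mesh, name="sulcal-depth")


# ---------------------------------------------------------------------------
# landmark QA

def landmark_distances(landmarks: np.ndarray, mesh: TriangleMesh
                       ) -> tuple[np.ndarray, float, float]:
    """Exact point-to-surface distance for each landmark (world mm).

    Returns (per-landmark distances, mean, sd)."""
    landmarks = np.atleast_2d(np.asarray(landmarks, float))
    if landmarks.size == 0:
        raise ValueError("empty landmark set")
    if not np.isfinite(landmarks).all():
        raise ValueError("landmarks must be finite")
    d, _, _ = MeshProximity(mesh).query(landmarks)
    return d, float(d.mean()), float(d.std())


# ---------------------------------------------------------------------------
# template selection

def select_template(depth_map: np.ndarray,
                    template_maps) -> tuple[int, np.ndarray]:
    """Pick the template whose sulcal-depth pattern correlates best
    (Pearson) with the individual's.

    Vertex correspondence across maps is assumed.  Zero-variance maps give
    undefined correlation and are excluded (NaN in the returned vector);
    ties break toward the smaller index (older-to-younger template
    ordering).
    """
    x = np.asarray(depth_map, float).ravel()
    if x.std() == 0:
        raise ValueError("individual depth map has zero variance")
    cors = np.full(len(template_maps), np.nan)
    for i, t in enumerate(template_maps):
        t = np.asarray(t, float).ravel()
        if len(t) != len(x):
            raise ValueError(f"template {i} has {len(t)} vertices, "
                             f"expected {len(x)}")
        if t.std() == 0:
            continue
        cors[i] = float(np.corrcoef(x, t)[0, 1])
    if np.all(np.isnan(cors)):
        raise ValueError("no template with nonzero variance")
    best = int(np.nanargmax(cors))
    return best, cors
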