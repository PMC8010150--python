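"""Synthetic neonatal-like phantoms with analytic ground truth.

Three geometries exercise the whole reconstruction chain:

``shell``
    WM ball of radius r1, a cortical shell out to r2, a CSF rim beyond —
    the analytic workhorse for thickness and Laplace checks.

``folded_slab``
    A tissue slab whose top is cut by parallel, slit-like sulci: CSF slits
    of width ``sulcal_gap`` descend ``fold_amplitude`` mm from the top
    plane, spaced ``fold_wavelength`` mm apart, and a cortical layer of
    constant thickness coats the outer boundary.  When ``sulcal_gap`` is
    below the voxel size the downsampled labels contain no pure-CSF voxel
    inside the sulci — the invisible-CSF condition of small neonatal
    brains, where opposing sulcal banks appear fused.  The geometry is
    invariant along y, so every quantity has a closed-form 2-D description:
    the inter-bank medial surface is exactly the slit mid-plane.

``folded_sphere``
    A ball with longitudinal sinusoidal folds of the WM surface; used to
    exercise closed-topology code paths on a folded object.

Intensities are synthesised by assigning per-tissue means on a supersampled
grid, box-averaging down (which creates genuine partial-volume mixtures at
every boundary) and adding Gaussian noise.  The default tissue means mimic
pre-term T1w contrast: GM brightest, WM dark and close to CSF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage

from .mesh import MeshProximity, TriangleMesh
from .volume_io import (LABEL_BACKGROUND, LABEL_CSF, LABEL_GM, LABEL_WM,
                        LabelVolume, VoxelGrid)

# (CSF, GM, WM) intensity means, arbitrary units
NEONATAL_TISSUE_MEANS = (40.0, 70.0, 48.0)   # low WM-GM contrast, CSF ~ WM
ADULT_TISSUE_MEANS = (30.0, 70.0, 110.0)


@dataclass
class PhantomSpec:
    kind: str = "shell"                  # shell | folded_slab | folded_sphere
    inner_radius: float = 20.0           # r1: WM radius / base level, mm
    outer_radius: float = 22.0           # r2: pial level; thickness = r2 - r1
    fold_amplitude: float = 10.0         # sulcal depth, mm
    fold_wavelength: float = 16.0        # inter-sulcus spacing, mm
    sulcal_gap: float = 0.2              # CSF slit width at fundi, mm
    tissue_means: tuple = NEONATAL_TISSUE_MEANS
    noise_sd: float = 0.0
    spacing: float = 1.0
    supersample: int = 2
    seed: int = 0
    csf_rim: float = 2.0                 # visible CSF beyond the pial surface
    margin: float = 4.0                  # background border, mm
    n_sulci: int = 3                     # folded_slab only
    thickness_variation: float = 0.0     # fractional sinusoidal variation

    def __post_init__(self):
        if self.outer_radius <= self.inner_radius or self.inner_radius <= 0:
            raise ValueError("need outer_radius > inner_radius > 0")
        if self.spacing <= 0 or self.supersample < 1:
            raise ValueError("spacing > 0 and supersample >= 1 required")

    @property
    def thickness(self) -> float:
        return self.outer_radius - self.inner_radius


@dataclass
class PhantomTruth:
    """Analytic ground truth bundled with callables for QA.

    ``inner_mesh``/``outer_mesh`` sample the analytic WM/GM and GM/CSF
    surfaces (open extruded sheets for the slab).  ``thickness`` is the true
    cortical thickness field; ``label_at`` reproduces the generator's exact
    label rule at arbitrary world points.
    """

    kind: str
    thickness_mean: float
    inner_mesh: TriangleMesh
    outer_mesh: TriangleMesh
    label_at: Callable[[np.ndarray], np.ndarray]
    thickness_at: Callable[[np.ndarray], np.ndarray]
    sample_outer_points: Callable[[int, np.random.Generator], np.ndarray]
    params: dict = field(default_factory=dict)

    def cortical_vertex_mask(self, vertices: np.ndarray) -> np.ndarray:
        """Vertices lying in the region where the cortical model (and hence
        thickness truth) applies; everything for closed phantoms, the sulcal
        top region for the slab."""
        v = np.asarray(vertices)
        if self.kind != "folded_slab":
            return np.ones(len(v), dtype=bool)
        p = self.params
        return ((v[:, 2] > p["fundus_z"] - self.thickness_mean - 1.0)
                & (v[:, 0] > p["block_x"][0] + 2.0)
                & (v[:, 0] < p["block_x"][1] - 2.0)
                & (v[:, 1] > p["block_y"][0] + 2.0)
                & (v[:, 1] < p["block_y"][1] - 2.0))


# ---------------------------------------------------------------------------
# grids

def _grids(spec: PhantomSpec, extent):
    """Final and supersampled voxel-centre coordinate axes for a world box
    [0, X] x [0, Y] x [0, Z]."""
    s, ss = spec.spacing, spec.supersample
    shape = tuple(int(round(e / s)) for e in extent)
    affine = np.diag([s, s, s, 1.0])
    affine[:3, 3] = s / 2.0
    hs = s / ss
    axes_hi = [hs / 2.0 + hs * np.arange(n * ss) for n in shape]
    return shape, affine, axes_hi


def _majority_downsample(labels_hi: np.ndarray, ss: int) -> np.ndarray:
    """Per-voxel majority vote over ss^3 supersampled cells.  Ties resolve
    toward the lower label code (background first)."""
    if ss == 1:
        return labels_hi.astype(np.int16)
    x, y, z = (n // ss for n in labels_hi.shape)
    view = labels_hi[:x * ss, :y * ss, :z * ss].reshape(x, ss, y, ss, z, ss)
    counts = np.stack([(view == c).sum(axis=(1, 3, 5))
                       for c in (LABEL_BACKGROUND, LABEL_CSF,
                                 LABEL_GM, LABEL_WM)], axis=-1)
    return np.argmax(counts, axis=-1).astype(np.int16)


def synthesize_intensity(labels_hi: np.ndarray, spec: PhantomSpec,
                         affine: np.ndarray) -> VoxelGrid:
    """Partial-volume intensity model: tissue means on the supersampled
    grid, box-average down by the supersample factor, then Gaussian noise."""
    ss = spec.supersample
    means = np.array([0.0, *spec.tissue_means])
    vals = means[labels_hi]
    if ss > 1:
        x, y, z = (n // ss for n in labels_hi.shape)
        vals = vals[:x * ss, :y * ss, :z * ss] \
            .reshape(x, ss, y, ss, z, ss).mean(axis=(1, 3, 5))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vals = vals + rng.normal(0.0, spec.noise_sd, size=vals.shape)
    return VoxelGrid(vals, affine)


# ---------------------------------------------------------------------------
# shell

def make_shell_phantom(spec: PhantomSpec):
    if spec.kind != "shell":
        raise ValueError("spec.kind must be 'shell'")
    if spec.thickness < spec.spacing:
        warnings.warn("shell thinner than a voxel; labels will be dominated "
                      "by partial volume", stacklevel=2)
    r1, r2, rim = spec.inner_radius, spec.outer_radius, spec.csf_rim
    half = r2 + rim + spec.margin
    extent = (2 * half,) * 3
    shape, affine, axes = _grids(spec, extent)
    c = half

    xs, ys, zs = np.meshgrid(*axes, indexing="ij", sparse=True)
    r = np.sqrt((xs - c) ** 2 + (ys - c) ** 2 + (zs - c) ** 2)
    labels_hi = np.full(r.shape, LABEL_BACKGROUND, dtype=np.int16)
    labels_hi[r <= r2 + rim] = LABEL_CSF
    labels_hi[r <= r2] = LABEL_GM
    labels_hi[r <= r1] = LABEL_WM

    labels = LabelVolume(_majority_downsample(labels_hi, spec.supersample),
                         affine)
    intensity = synthesize_intensity(labels_hi, spec, affine)

    import trimesh
    center = np.array([c, c, c])
    inner = trimesh.creation.icosphere(subdivisions=4, radius=r1)
    outer = trimesh.creation.icosphere(subdivisions=4, radius=r2)
    inner_mesh = TriangleMesh(np.array(inner.vertices) + center,
                              np.array(inner.faces))
    outer_mesh = TriangleMesh(np.array(outer.vertices) + center,
                              np.array(outer.faces))

    def label_at(points):
        rr = np.linalg.norm(np.atleast_2d(points) - center, axis=1)
        out = np.full(len(rr), LABEL_BACKGROUND, dtype=np.int16)
        out[rr <= r2 + rim] = LABEL_CSF
        out[rr <= r2] = LABEL_GM
        out[rr <= r1] = LABEL_WM
        return out

    def sample_outer(n, rng):
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        return center + r2 * v

    truth = PhantomTruth(
        kind="shell", thickness_mean=spec.thickness,
        inner_mesh=inner_mesh, outer_mesh=outer_mesh,
        label_at=label_at,
        thickness_at=lambda p: np.full(len(np.atleast_2d(p)), spec.thickness),
        sample_outer_points=sample_outer,
        params={"center": center, "r1": r1, "r2": r2, "rim": rim})
    return intensity, labels, truth


# ---------------------------------------------------------------------------
# folded slab

def _slab_layout(spec: PhantomSpec):
    m, lam, n = spec.margin, spec.fold_wavelength, spec.n_sulci
    T, A, rim = spec.thickness, spec.fold_amplitude, spec.csf_rim
    X = n * lam + 2 * m
    Y = 16.0 + 2 * m
    wm_base = 5.0
    z_top = m + wm_base + T + A
    Z = z_top + rim + m
    sulci_x = m + lam / 2.0 + lam * np.arange(n)
    return dict(X=X, Y=Y, Z=Z, z_top=z_top, fundus_z=z_top - A,
                sulci_x=sulci_x, block_x=(m, X - m), block_y=(m, Y - m),
                block_z0=m)


def _slab_dist_to_csf(x, z, layout, gap):
    """2-D distance (in the x-z cross-section) to the CSF/outside region
    C = {z > z_top} union vertical slits of width ``gap`` descending to
    ``fundus_z``.  Zero inside C."""
    d = np.maximum(layout["z_top"] - z, 0.0)
    for xk in layout["sulci_x"]:
        dx = np.maximum(np.abs(x - xk) - gap / 2.0, 0.0)
        dz = np.maximum(layout["fundus_z"] - z, 0.0)
        d = np.minimum(d, np.hypot(dx, dz))
    return d


def _extrude_polyline(poly_xz: np.ndarray, y0: float, y1: float,
                      n_y: int = 9) -> TriangleMesh:
    """Triangulate the surface swept by a 2-D polyline along y."""
    ny = max(2, n_y)
    ys = np.linspace(y0, y1, ny)
    npt = len(poly_xz)
    verts = np.empty((ny * npt, 3))
    for i, y in enumerate(ys):
        verts[i * npt:(i + 1) * npt, 0] = poly_xz[:, 0]
        verts[i * npt:(i + 1) * npt, 1] = y
        verts[i * npt:(i + 1) * npt, 2] = poly_xz[:, 1]
    faces = []
    for i in range(ny - 1):
        a = i * npt + np.arange(npt - 1)
        b = a + 1
        c = a + npt
        d = b + npt
        faces.append(np.stack([a, b, c], axis=1))
        faces.append(np.stack([b, d, c], axis=1))
    return TriangleMesh(verts, np.concatenate(faces))


def _slab_outer_polyline(layout, gap):
    """Exact polyline of the pial boundary in the x-z plane: top plane
    broken by slit walls and fundus bottoms."""
    x0, x1 = layout["block_x"]
    zt, zf = layout["z_top"], layout["fundus_z"]
    pts = [(x0, zt)]
    for xk in layout["sulci_x"]:
        pts += [(xk - gap / 2, zt), (xk - gap / 2, zf),
                (xk + gap / 2, zf), (xk + gap / 2, zt)]
    pts.append((x1, zt))
    # densify long segments for even landmark sampling
    out = []
    for (ax, az), (bx, bz) in zip(pts[:-1], pts[1:]):
        n = max(2, int(np.hypot(bx - ax, bz - az) / 0.5) + 1)
        seg = np.stack([np.linspace(ax, bx, n), np.linspace(az, bz, n)],
                       axis=1)
        out.append(seg[:-1])
    out.append(np.array([pts[-1]]))
    return np.concatenate(out)


def _slab_inner_polyline(layout, gap, thickness):
    """Level set {dist-to-CSF == thickness}: the WM/GM interface, sampled
    from the analytic distance field on a fine cross-section grid."""
    from skimage import measure
    x0, x1 = layout["block_x"]
    h = 0.05
    xs = np.arange(x0, x1 + h, h)
    zs = np.arange(layout["block_z0"], layout["z_top"] + 1.0, h)
    d = _slab_dist_to_csf(xs[:, None], zs[None, :], layout, gap)
    contours = measure.find_contours(d, thickness)
    poly = max(contours, key=len)
    return np.stack([x0 + poly[:, 0] * h,
                     layout["block_z0"] + poly[:, 1] * h], axis=1)


def make_folded_slab(spec: PhantomSpec):
    layout = _slab_layout(spec)
    T, gap = spec.thickness, spec.sulcal_gap
    extent = (layout["X"], layout["Y"], layout["Z"])
    shape, affine, axes = _grids(spec, extent)

    xs, ys, zs = axes
    d2d = _slab_dist_to_csf(xs[:, None], zs[None, :], layout, gap)
    in_c_2d = d2d == 0.0

    if spec.thickness_variation:
        t_of_y = T * (1.0 + spec.thickness_variation
                      * np.sin(2 * np.pi * (ys - layout["block_y"][0])
                               / (layout["block_y"][1] - layout["block_y"][0])))
    else:
        t_of_y = np.full(len(ys), T)

    labels_hi = np.zeros((len(xs), len(ys), len(zs)), dtype=np.int16)
    in_block_y = (ys >= layout["block_y"][0]) & (ys <= layout["block_y"][1])
    in_block_x = (xs >= layout["block_x"][0]) & (xs <= layout["block_x"][1])
    above_base = zs >= layout["block_z0"]
    below_rim = zs <= layout["z_top"] + spec.csf_rim

    wm_2d = d2d[:, None, :] > t_of_y[None, :, None]
    gm_2d = (~wm_2d) & (d2d[:, None, :] > 0.0)
    csf_2d = in_c_2d[:, None, :] & below_rim[None, None, :]
    block = (in_block_x[:, None, None] & in_block_y[None, :, None]
             & above_base[None, None, :])
    labels_hi[block & csf_2d] = LABEL_CSF
    labels_hi[block & gm_2d] = LABEL_GM
    labels_hi[block & wm_2d] = LABEL_WM

    labels = LabelVolume(_majority_downsample(labels_hi, spec.supersample),
                         affine)
    intensity = synthesize_intensity(labels_hi, spec, affine)

    y0, y1 = layout["block_y"]
    outer_poly = _slab_outer_polyline(layout, gap)
    inner_poly = _slab_inner_polyline(layout, gap, T)
    outer_mesh = _extrude_polyline(outer_poly, y0, y1)
    inner_mesh = _extrude_polyline(inner_poly, y0, y1)

    def label_at(points):
        p = np.atleast_2d(points)
        d = _slab_dist_to_csf(p[:, 0], p[:, 2], layout, gap)
        tt = np.interp(p[:, 1], ys, t_of_y)
        out = np.full(len(p), LABEL_BACKGROUND, dtype=np.int16)
        inside = ((p[:, 0] >= layout["block_x"][0])
                  & (p[:, 0] <= layout["block_x"][1])
                  & (p[:, 1] >= y0) & (p[:, 1] <= y1)
                  & (p[:, 2] >= layout["block_z0"]))
        out[inside & (d == 0) & (p[:, 2] <= layout["z_top"] + spec.csf_rim)] \
            = LABEL_CSF
        out[inside & (d > 0) & (d <= tt)] = LABEL_GM
        out[inside & (d > tt)] = LABEL_WM
        return out

    seg = outer_poly
    seg_len = np.hypot(*np.diff(seg, axis=0).T)
    cum = np.concatenate([[0], np.cumsum(seg_len)])

    def sample_outer(n, rng):
        s = rng.uniform(2.0, cum[-1] - 2.0, size=n)
        idx = np.searchsorted(cum, s) - 1
        idx = np.clip(idx, 0, len(seg) - 2)
        f = (s - cum[idx]) / np.maximum(seg_len[idx], 1e-12)
        xz = seg[idx] + f[:, None] * (seg[idx + 1] - seg[idx])
        yy = rng.uniform(y0 + 2.0, y1 - 2.0, size=n)
        return np.stack([xz[:, 0], yy, xz[:, 1]], axis=1)

    def thickness_at(points):
        p = np.atleast_2d(points)
        return np.interp(p[:, 1], ys, t_of_y)

    truth = PhantomTruth(
        kind="folded_slab", thickness_mean=float(np.mean(t_of_y)),
        inner_mesh=inner_mesh, outer_mesh=outer_mesh,
        label_at=label_at, thickness_at=thickness_at,
        sample_outer_points=sample_outer,
        params={**layout, "gap": gap, "extent": extent})
    return intensity, labels, truth


# ---------------------------------------------------------------------------
# folded sphere

def make_folded_sphere(spec: PhantomSpec):
    r1, T, rim = spec.inner_radius, spec.thickness, spec.csf_rim
    A = spec.fold_amplitude
    n_folds = max(2, int(round(2 * np.pi * r1 / spec.fold_wavelength)))
    half = r1 + A + T + rim + spec.margin
    extent = (2 * half,) * 3
    shape, affine, axes = _grids(spec, extent)
    c = half

    def r_inner(theta, phi):
        # sin(theta)^2 tapers folds to zero at the poles
        return r1 + A * np.sin(n_folds * phi) * np.sin(theta) ** 2

    xs, ys, zs = np.meshgrid(*axes, indexing="ij", sparse=True)
    dx, dy, dz = xs - c, ys - c, zs - c
    r = np.sqrt(dx ** 2 + dy ** 2 + dz ** 2)
    with np.errstate(invalid="ignore"):
        theta = np.arccos(np.clip(np.where(r > 0, dz / np.maximum(r, 1e-12),
                                           1.0), -1, 1))
    phi = np.arctan2(dy, dx)
    wm_hi = r <= r_inner(theta, phi)

    hs = spec.spacing / spec.supersample
    # EDT gives distance to the nearest WM voxel centre; the WM *boundary*
    # lies about half a cell closer, so thresholds are offset by hs/2
    dist_out = ndimage.distance_transform_edt(~wm_hi, sampling=hs) - hs / 2.0
    labels_hi = np.full(wm_hi.shape, LABEL_BACKGROUND, dtype=np.int16)
    labels_hi[dist_out <= T + rim] = LABEL_CSF
    labels_hi[dist_out <= T] = LABEL_GM
    labels_hi[wm_hi] = LABEL_WM

    labels = LabelVolume(_majority_downsample(labels_hi, spec.supersample),
                         affine)
    intensity = synthesize_intensity(labels_hi, spec, affine)

    import trimesh
    center = np.array([c, c, c])
    base = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
    v = np.array(base.vertices)
    th = np.arccos(np.clip(v[:, 2], -1, 1))
    ph = np.arctan2(v[:, 1], v[:, 0])
    inner_v = center + v * r_inner(th, ph)[:, None]
    inner_mesh = TriangleMesh(inner_v, np.array(base.faces))
    outer_mesh = TriangleMesh(
        inner_v + T * inner_mesh.vertex_normals(), np.array(base.faces))

    prox = MeshProximity(inner_mesh)

    def label_at(points):
        p = np.atleast_2d(points)
        q = p - center
        rr = np.linalg.norm(q, axis=1)
        th = np.arccos(np.clip(np.divide(q[:, 2], np.maximum(rr, 1e-12)),
                               -1, 1))
        ph = np.arctan2(q[:, 1], q[:, 0])
        inside = rr <= r_inner(th, ph)
        d, _, _ = prox.query(p)
        out = np.full(len(p), LABEL_BACKGROUND, dtype=np.int16)
        out[(~inside) & (d <= T + rim)] = LABEL_CSF
        out[(~inside) & (d <= T)] = LABEL_GM
        out[inside] = LABEL_WM
        return out

    outer_prox = MeshProximity(outer_mesh)

    def sample_outer(n, rng):
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = center + (r1 + T) * v
        _, cp, _ = outer_prox.query(pts)
        return cp

    truth = PhantomTruth(
        kind="folded_sphere", thickness_mean=T,
        inner_mesh=inner_mesh, outer_mesh=outer_mesh,
        label_at=label_at,
        thickness_at=lambda p: np.full(len(np.atleast_2d(p)), T),
        sample_outer_points=sample_outer,
        params={"center": center, "r1": r1, "n_folds": n_folds,
                "amplitude": A})
    return intensity, labels, truth


def make_folded_phantom(spec: PhantomSpec):
    if spec.fold_amplitude >= spec.fold_wavelength:
        raise ValueError("fold_amplitude >= fold_wavelength: geometry would "
                         "self-intersect")
    if spec.kind == "folded_slab":
        return make_folded_slab(spec)
    if spec.kind == "folded_sphere":
        return make_folded_sphere(spec)
    raise ValueError("spec.kind must be folded_slab or folded_sphere")


def make_phantom(spec: PhantomSpec):
    """Dispatch on ``spec.kind``."""
    if spec.kind == "shell":
        return make_shell_phantom(spec)
    return make_folded_phantom(spec)
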