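"""Laplacian field, streamline expansion and full pial reconstruction."""

import numpy as np
import pytest
import trimesh
from scipy import ndimage

from neosurf.csf_skeleton import UnionVolume
from neosurf.mesh import TriangleMesh
from neosurf.morphometry import cortical_thickness
from neosurf.pial_surface import solve_laplace, trace_streamlines


@pytest.fixture(scope="module")
def concentric():
    """Analytic harmonic test bed: domain between r1=20 and r2=25 with the
    outer shell as the Dirichlet-1 boundary."""
    n = 56
    c = (n - 1) / 2.0
    x, y, z = np.mgrid[:n, :n, :n]
    r = np.sqrt((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2)
    r1, r2 = 20.0, 25.0
    wm = r <= r1
    union = (r > r1) & (r <= r2 + 1)
    outer = union & (r > r2)
    uv = UnionVolume(union=union, hull=outer,
                     inner_boundary=union & (r <= r1 + 1), wm=wm,
                     csf=np.zeros_like(wm), affine=np.eye(4),
                     spacing=np.ones(3))
    field = solve_laplace(uv, np.zeros_like(wm), csf_as_boundary=False)
    return {"field": field, "uv": uv, "r": r, "c": c, "r1": r1, "r2": r2}


def test_laplace_matches_radial_harmonic(concentric):
    """Potential within 0.02 of (1/r1 - 1/r)/(1/r1 - 1/r2) away from the
    blocky Dirichlet layer."""
    f = concentric["field"]
    r = concentric["r"]
    r1, r2 = concentric["r1"], concentric["r2"]
    near = ndimage.binary_dilation(
        f.fixed_one | f.fixed_zero,
        structure=ndimage.generate_binary_structure(3, 1))
    sel = f.interior & ~near
    analytic = (1 / r1 - 1 / r[sel]) / (1 / r1 - 1 / r2)
    err = np.abs(f.potential.data[sel] - analytic)
    assert err.mean() < 0.02
    assert f.residuals[-1] < 1e-5
    assert np.all((f.potential.data[f.interior] >= -1e-9)
                  & (f.potential.data[f.interior] <= 1 + 1e-9))


def test_laplace_residual_decreases(concentric):
    """Residual shrinks over 10-sweep windows and ends far below start
    (strict per-sweep monotonicity does not hold for over-relaxation)."""
    res = np.array(concentric["field"].residuals)
    assert res[-1] < 1e-5 < res[0]
    windows = [res[i:i + 10].max() for i in range(0, len(res) - 10, 10)]
    assert all(b < a for a, b in zip(windows[:-1], windows[1:]))


def test_all_boundary_domain_keeps_boundary_values():
    """A one-voxel-thick shell is all Dirichlet: the solver returns the
    boundary values untouched."""
    n = 20
    c = (n - 1) / 2.0
    x, y, z = np.mgrid[:n, :n, :n]
    r = np.sqrt((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2)
    wm = r <= 6
    union = (r > 6) & (r <= 7)
    uv = UnionVolume(union=union, hull=union,
                     inner_boundary=union, wm=wm,
                     csf=np.zeros_like(wm), affine=np.eye(4),
                     spacing=np.ones(3))
    f = solve_laplace(uv, np.zeros_like(wm), csf_as_boundary=False)
    assert np.allclose(f.potential.data[union], 1.0)
    assert np.allclose(f.potential.data[wm], 0.0)


def test_streamlines_radial_arrival(concentric):
    f = concentric["field"]
    c = concentric["c"]
    ico = trimesh.creation.icosphere(subdivisions=3, radius=20.0)
    wm_mesh = TriangleMesh(np.array(ico.vertices) + c,
                           np.array(ico.faces))
    smap, inter = trace_streamlines(f, wm_mesh)
    rr = np.linalg.norm(inter.vertices - c, axis=1)
    assert abs(rr.mean() - concentric["r2"]) < 0.5
    assert smap.flagged.sum() == 0
    # radial: arrival direction matches start direction
    d0 = wm_mesh.vertices - c
    d0 /= np.linalg.norm(d0, axis=1, keepdims=True)
    d1 = inter.vertices - c
    d1 /= np.linalg.norm(d1, axis=1, keepdims=True)
    assert np.einsum("ij,ij->i", d0, d1).min() > 0.98


def test_streamline_potential_monotone(concentric):
    f = concentric["field"]
    c = concentric["c"]
    ico = trimesh.creation.icosphere(subdivisions=1, radius=20.0)
    wm_mesh = TriangleMesh(np.array(ico.vertices) + c, np.array(ico.faces))
    smap, _ = trace_streamlines(f, wm_mesh, keep_polylines=True,
                                record_every=1)
    for pl in smap.polylines[:20]:
        pl = np.array(pl)
        vox = np.atleast_2d(f.potential.voxel_from_world(pl))
        vals = ndimage.map_coordinates(f.potential.data, vox.T, order=1)
        assert np.all(np.diff(vals) > -5e-3)


def test_vertex_on_boundary_has_zero_length_streamline(concentric):
    f = concentric["field"]
    c = concentric["c"]
    ico = trimesh.creation.icosphere(subdivisions=1, radius=25.8)
    mesh = TriangleMesh(np.array(ico.vertices) + c, np.array(ico.faces))
    smap, inter = trace_streamlines(f, mesh)
    assert np.max(smap.lengths) <= 0.5
    assert np.allclose(inter.vertices, mesh.vertices, atol=0.3)


def test_shell_pial_reconstruction(shell_recon, shell_phantom):
    """Visible-CSF shell: refined pial within 0.25 mm of r2 = 22 and never
    inside the WM surface."""
    c = shell_phantom["truth"].params["center"]
    pial = shell_recon["pial"]
    inter = shell_recon["intermediate"]
    wm = shell_recon["wm"]
    r_p = np.linalg.norm(pial.vertices - c, axis=1)
    assert abs(r_p.mean() - 22.0) <= 0.25
    assert np.array_equal(pial.faces, wm.faces)
    # outward motion, no WM crossing
    t = cortical_thickness(wm, pial).values
    r_w = np.linalg.norm(wm.vertices - c, axis=1)
    assert np.all(r_p >= r_w - 0.2)
    assert (t >= 0).all()
    # refinement improves on the intermediate surface
    err_i = np.abs(np.linalg.norm(inter.vertices - c, axis=1) - 22.0)
    err_p = np.abs(r_p - 22.0)
    assert err_p.mean() <= err_i.mean()


def test_slab_pial_enters_every_sulcus(slab_phantom, slab_recon):
    """Invisible CSF: the expanded surface penetrates >= 80% of the
    analytic sulcal depth in every sulcus."""
    truth = slab_phantom["truth"]
    spec = slab_phantom["spec"]
    p = truth.params
    v = slab_recon["intermediate"].vertices
    cortical = truth.cortical_vertex_mask(v)
    for xk in p["sulci_x"]:
        sel = (np.abs(v[:, 0] - xk) < 1.5) & cortical
        assert sel.sum() > 0
        penetration = p["z_top"] - v[sel, 2].min()
        assert penetration >= 0.8 * spec.fold_amplitude


def test_slab_pial_close_to_analytic_outer_surface(slab_phantom,
                                                   slab_recon):
    """Mean distance from analytic pial samples to the reconstruction is
    below one voxel; gradient refinement does not degrade it."""
    from neosurf.mesh import MeshProximity
    truth = slab_phantom["truth"]
    rng = np.random.default_rng(0)
    pts = truth.sample_outer_points(300, rng)
    d_p, _, _ = MeshProximity(slab_recon["pial"]).query(pts)
    d_i, _, _ = MeshProximity(slab_recon["intermediate"]).query(pts)
    assert d_p.mean() <= 1.0
    assert d_p.mean() <= d_i.mean() + 0.05


def test_pial_potential_exceeds_wm_potential(shell_recon):
    """Along each correspondence the potential is non-decreasing (outward
    motion through the field)."""
    smap = shell_recon["streamlines"]
    assert np.all(smap.arrival_potential >= -1e-6)
    assert smap.arrival_potential.mean() > 0.9
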