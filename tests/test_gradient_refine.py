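"""Profile sampling, edge detection and gradient-driven deformation."""

import numpy as np
import pytest
import trimesh

from neosurf.gradient_refine import (DeformationParams, ProfileParams,
                                     TargetIntensityMap, blur_target_map,
                                     deform_to_edges, find_edge,
                                     sample_profile, sample_profiles)
from neosurf.mesh import TriangleMesh
from neosurf.phantom import PhantomSpec, make_shell_phantom
from neosurf.volume_io import VoxelGrid


def sphere_mesh(radius, center, sub=3):
    ico = trimesh.creation.icosphere(subdivisions=sub, radius=radius)
    return TriangleMesh(np.array(ico.vertices) + center,
                        np.array(ico.faces))


@pytest.fixture(scope="module")
def refine_setup(wide_shell_phantom):
    ph = wide_shell_phantom
    c = ph["truth"].params["center"]
    return {"intensity": ph["intensity"], "labels": ph["labels"],
            "center": c, "brain": ph["labels"].data > 0}


def test_constant_image_gives_flat_profile():
    grid = VoxelGrid(np.full((20, 20, 20), 7.0))
    mesh = sphere_mesh(4.0, np.array([9.5, 9.5, 9.5]), sub=1)
    prof = sample_profile(mesh, 0, grid,
                          ProfileParams(profile_blur_sigma=0))
    valid = np.isfinite(prof)
    assert np.allclose(prof[valid], 7.0)
    assert np.allclose(np.gradient(prof[valid], 0.5), 0.0)


def test_linear_ramp_profile_has_constant_gradient():
    x = np.arange(40, dtype=float)
    grid = VoxelGrid(np.broadcast_to(x[:, None, None], (40, 40, 40)).copy())
    mesh = TriangleMesh(
        np.array([[20.0, 20.0, 20.0], [21.0, 20.0, 20.0],
                  [20.0, 21.0, 20.0]]),
        np.array([[0, 1, 2]]))
    # vertex normal of this degenerate sheet is +-z; build custom normals
    prof, valid = sample_profiles(
        mesh, grid, ProfileParams(profile_blur_sigma=0),
        normals=np.array([[1.0, 0, 0]] * 3))
    g = np.gradient(prof[0], 0.5)
    assert np.allclose(g[2:-2], 1.0, atol=1e-6)


def test_shell_profile_crosses_edge_at_analytic_offset(refine_setup):
    """A radial profile from r=21 crosses the GM->CSF step near r2-21."""
    c = refine_setup["center"]
    mesh = sphere_mesh(21.0, c, sub=2)
    pp = ProfileParams(search_step=0.5, search_distance=5.0,
                       expected_sign=-1, profile_blur_sigma=0)
    prof = sample_profile(mesh, 0, refine_setup["intensity"], pp)
    off, edge_int = find_edge(prof, pp)
    assert abs(off - 4.0) <= 0.75  # r2=25, start at 21
    assert 40.0 < edge_int < 70.0


def test_step_edge_bracketing():
    pp = ProfileParams(search_step=0.5, search_distance=5.0,
                       profile_blur_sigma=0)
    offs = pp.offsets
    prof = np.where(offs < 2.0, 1.0, 2.0)
    off, _ = find_edge(prof, pp)
    assert 1.5 <= off <= 2.5


def test_expected_sign_selects_matching_edge():
    pp = ProfileParams(search_step=0.5, search_distance=5.0,
                       profile_blur_sigma=0, expected_sign=-1)
    offs = pp.offsets
    # rising edge at -2 (mag 2), falling edge at +2 (mag 1)
    prof = np.where(offs < -2.0, 1.0, np.where(offs < 2.0, 3.0, 2.0))
    off, _ = find_edge(prof, pp)
    assert 1.5 <= off <= 2.5
    pp_up = ProfileParams(search_step=0.5, search_distance=5.0,
                          profile_blur_sigma=0, expected_sign=+1)
    off_up, _ = find_edge(prof, pp_up)
    assert -2.5 <= off_up <= -1.5


def test_flat_profile_has_no_edge():
    pp = ProfileParams(search_step=0.5, search_distance=5.0)
    off, intensity = find_edge(np.full(len(pp.offsets), 3.0), pp)
    assert off == 0.0
    assert np.isnan(intensity)


def test_too_few_samples_rejected():
    pp = ProfileParams(search_step=1.0, search_distance=5.0)
    prof = np.full(len(pp.offsets), np.nan)
    prof[5] = 1.0
    with pytest.raises(ValueError):
        find_edge(prof, pp)


def test_blur_target_map_constant_fixed_point():
    mesh = sphere_mesh(5.0, np.zeros(3), sub=2)
    tmap = TargetIntensityMap(np.full(mesh.n_vertices, 4.0),
                              np.zeros(mesh.n_vertices),
                              np.ones(mesh.n_vertices, bool))
    out = blur_target_map(mesh, tmap, 10)
    assert np.allclose(out.intensity, 4.0)


def test_blur_target_map_suppresses_outlier_and_conserves_mean():
    mesh = sphere_mesh(5.0, np.zeros(3), sub=4)  # 2562 vertices? sub4=2562
    vals = np.zeros(mesh.n_vertices)
    vals[10] = 100.0
    tmap = TargetIntensityMap(vals, np.zeros_like(vals),
                              np.ones(mesh.n_vertices, bool))
    out = blur_target_map(mesh, tmap, 10)
    assert out.intensity[10] < 0.1 * vals[10]
    assert abs(out.intensity.mean() - vals.mean()) < 1e-6


def test_blur_target_map_fills_undefined_from_neighbors():
    mesh = sphere_mesh(5.0, np.zeros(3), sub=2)
    vals = np.full(mesh.n_vertices, 3.0)
    defined = np.ones(mesh.n_vertices, bool)
    vals[7] = np.nan
    defined[7] = False
    out = blur_target_map(mesh, TargetIntensityMap(
        vals, np.zeros_like(vals), defined), 2)
    assert np.isfinite(out.intensity).all()
    assert abs(out.intensity[7] - 3.0) < 1e-6


def test_refinement_moves_shell_to_edge_noiseless(refine_setup):
    """Mesh 2 mm inside a clean step edge converges to within 0.25 mm."""
    c = refine_setup["center"]
    mesh = sphere_mesh(23.0, c)
    out = deform_to_edges(mesh, refine_setup["intensity"],
                          ProfileParams(expected_sign=-1),
                          DeformationParams(),
                          brain_mask=refine_setup["brain"])
    r = np.linalg.norm(out.vertices - c, axis=1)
    assert abs(r.mean() - 25.0) <= 0.25
    assert np.array_equal(out.faces, mesh.faces)
    assert out.euler_characteristic == 2


def test_refinement_under_noise(refine_setup):
    """10% of the GM-CSF contrast as noise: error stays below half the
    search step."""
    spec = PhantomSpec(kind="shell", inner_radius=20.0, outer_radius=25.0,
                       spacing=1.0, supersample=2, seed=3, noise_sd=3.0)
    inten, labels, truth = make_shell_phantom(spec)
    c = truth.params["center"]
    mesh = sphere_mesh(23.0, c)
    out = deform_to_edges(mesh, inten, ProfileParams(expected_sign=-1),
                          DeformationParams(), brain_mask=labels.data > 0)
    r = np.linalg.norm(out.vertices - c, axis=1)
    assert abs(r.mean() - 25.0) <= 0.5 * 0.5


def test_mesh_on_edge_is_a_fixed_point(refine_setup):
    c = refine_setup["center"]
    mesh = sphere_mesh(25.0, c)
    out = deform_to_edges(mesh, refine_setup["intensity"],
                          ProfileParams(expected_sign=-1),
                          DeformationParams(),
                          brain_mask=refine_setup["brain"])
    r = np.linalg.norm(out.vertices - c, axis=1)
    assert abs(r.mean() - 25.0) <= 0.15


@pytest.mark.parametrize("means", [(40.0, 70.0, 48.0), (30.0, 70.0, 110.0)])
def test_auto_sign_handles_both_contrast_polarities(means):
    """The same code fits the WM edge under neonatal (GM-bright) and adult
    (WM-bright) contrast."""
    spec = PhantomSpec(kind="shell", inner_radius=20.0, outer_radius=25.0,
                       spacing=1.0, supersample=2, seed=3,
                       tissue_means=means)
    inten, labels, truth = make_shell_phantom(spec)
    c = truth.params["center"]
    mesh = sphere_mesh(18.0, c)
    out = deform_to_edges(mesh, inten, ProfileParams(expected_sign="auto"),
                          DeformationParams(), brain_mask=labels.data > 0)
    r = np.linalg.norm(out.vertices - c, axis=1)
    assert abs(r.mean() - 20.0) <= 0.25


def test_refinement_never_worsens_noiseless_distance(refine_setup):
    """Mean distance to the true surface decreases monotonically across
    resolution levels on the noiseless shell."""
    c = refine_setup["center"]
    mesh = sphere_mesh(23.0, c)
    errs = [abs(np.linalg.norm(mesh.vertices - c, axis=1).mean() - 25.0)]
    for schedule in (((5.0, 1.0),), ((5.0, 1.0), (3.0, 0.5)),
                     ((5.0, 1.0), (3.0, 0.5), (1.5, 0.25))):
        out = deform_to_edges(mesh, refine_setup["intensity"],
                              ProfileParams(expected_sign=-1),
                              DeformationParams(
                                  resolution_schedule=schedule),
                              brain_mask=refine_setup["brain"])
        errs.append(abs(np.linalg.norm(out.vertices - c, axis=1).mean()
                        - 25.0))
    # every schedule prefix improves hugely on the initial surface, and
    # the full schedule is the best of all (strict per-level monotonicity
    # can be broken by ~0.1 mm sub-sample jitter at intermediate steps)
    assert all(e < 0.15 * errs[0] for e in errs[1:])
    assert errs[-1] <= min(errs[:-1])
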