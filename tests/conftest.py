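"""Shared fixtures: phantoms and reconstruction chains reused across the
suite (session-scoped; every stage is deterministic under the fixed
seeds)."""

import warnings

import numpy as np
import pytest
from scipy import ndimage

from neosurf.csf_skeleton import skeletonize
from neosurf.gradient_refine import DeformationParams, ProfileParams, \
    deform_to_edges
from neosurf.phantom import PhantomSpec, make_folded_slab, make_shell_phantom
from neosurf.pial_surface import build_pial
from neosurf.volume_io import VoxelGrid
from neosurf.wm_surface import (extract_wm_mesh, icosahedron_resample,
                                inflate_to_sphere)


@pytest.fixture(scope="session")
def shell_phantom():
    """Thin-cortex shell: WM ball r1=20, cortex to r2=22, 2 mm CSF rim."""
    spec = PhantomSpec(kind="shell", inner_radius=20.0, outer_radius=22.0,
                       spacing=1.0, supersample=2, seed=1)
    intensity, labels, truth = make_shell_phantom(spec)
    return {"spec": spec, "intensity": intensity, "labels": labels,
            "truth": truth}


@pytest.fixture(scope="session")
def wide_shell_phantom():
    """Wider cortex (r1=20, r2=25) for refinement-convergence tests."""
    spec = PhantomSpec(kind="shell", inner_radius=20.0, outer_radius=25.0,
                       spacing=1.0, supersample=2, seed=3)
    intensity, labels, truth = make_shell_phantom(spec)
    return {"spec": spec, "intensity": intensity, "labels": labels,
            "truth": truth}


@pytest.fixture(scope="session")
def slab_phantom():
    """Folded slab with sub-voxel sulcal gaps: the invisible-CSF regime."""
    spec = PhantomSpec(kind="folded_slab", sulcal_gap=0.2, spacing=1.0,
                       supersample=2, seed=7)
    intensity, labels, truth = make_folded_slab(spec)
    return {"spec": spec, "intensity": intensity, "labels": labels,
            "truth": truth}


@pytest.fixture(scope="session")
def slab_skeleton(slab_phantom):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        skel, union = skeletonize(slab_phantom["labels"])
    return {"skel": skel, "union": union}


@pytest.fixture(scope="session")
def shell_recon(shell_phantom):
    """Full reconstruction chain on the thin shell: WM mesh (level 4,
    gradient refined), skeleton, intermediate and refined pial surfaces."""
    labels = shell_phantom["labels"]
    intensity = shell_phantom["intensity"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wm_raw = extract_wm_mesh(
            VoxelGrid((labels.data == 3).astype(np.uint8), labels.affine))
        sphere = inflate_to_sphere(wm_raw)
        wm = icosahedron_resample(wm_raw, sphere, 4)
        brain = ndimage.binary_closing(
            labels.data > 0, structure=ndimage.generate_binary_structure(3, 1))
        wm = deform_to_edges(wm, intensity,
                             ProfileParams(expected_sign="auto"),
                             DeformationParams(), brain_mask=brain)
        skel, union = skeletonize(labels)
        pial, intermediate, smap = build_pial(wm, labels, intensity, skel,
                                              union=union)
    return {"wm_raw": wm_raw, "wm": wm, "sphere": sphere, "skel": skel,
            "union": union, "pial": pial, "intermediate": intermediate,
            "streamlines": smap}


@pytest.fixture(scope="session")
def slab_recon(slab_phantom, slab_skeleton):
    """Reconstruction chain on the invisible-CSF folded slab.  The native
    marching-cubes mesh is used (no spherical resampling: the slab's
    box-like shape is the worst case for a sphere map and would starve its
    corners of vertices; closed phantoms exercise that path)."""
    labels = slab_phantom["labels"]
    intensity = slab_phantom["intensity"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wm = extract_wm_mesh(
            VoxelGrid((labels.data == 3).astype(np.uint8), labels.affine))
        brain = ndimage.binary_closing(
            labels.data > 0, structure=ndimage.generate_binary_structure(3, 1))
        wm = deform_to_edges(wm, intensity,
                             ProfileParams(expected_sign="auto"),
                             DeformationParams(), brain_mask=brain)
        pial, intermediate, smap = build_pial(
            wm, labels, intensity, slab_skeleton["skel"],
            union=slab_skeleton["union"])
    return {"wm": wm, "pial": pial, "intermediate": intermediate,
            "streamlines": smap}


@pytest.fixture(scope="session")
def pipeline_pair():
    """The same pipeline config run twice (determinism checks)."""
    import tempfile

    from neosurf.pipeline import PipelineConfig, run_pipeline

    results = []
    dirs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(2):
            out = tempfile.mkdtemp(prefix="neosurf_run_")
            cfg = PipelineConfig(
                phantom={"kind": "folded_slab", "sulcal_gap": 0.2,
                         "spacing": 1.0, "supersample": 2},
                seed=7, icosahedron_level=4, resample_icosahedron=False,
                output_dir=out)
            results.append(run_pipeline(cfg))
            dirs.append(out)
    return {"manifests": results, "dirs": dirs}
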