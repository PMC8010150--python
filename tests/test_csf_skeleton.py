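"""GM+CSF skeletonization: curvature, seeding, homotopic erosion and
pruning."""

import warnings

import numpy as np
import pytest
from scipy import ndimage

from neosurf.csf_skeleton import (SkeletonVoxels, boundary_curvature,
                                  build_union, homotopic_erode,
                                  prune_skeleton, seed_catchment_basins)
from neosurf.topology import TOPO_CODES, euler_characteristic


def test_union_of_shell_phantom(shell_phantom):
    labels = shell_phantom["labels"]
    union = build_union(labels)
    c = shell_phantom["truth"].params["center"]
    ijk = np.array(np.nonzero(union.union)).T
    r = np.linalg.norm(np.atleast_2d(labels.world_from_voxel(ijk)) - c,
                       axis=1)
    assert 19.0 < r.min() and r.max() < 25.5
    inner = np.array(np.nonzero(union.inner_boundary)).T
    ri = np.linalg.norm(np.atleast_2d(labels.world_from_voxel(inner)) - c,
                        axis=1)
    assert np.all(np.abs(ri - 20.0) < 1.8)
    assert (union.hull & ~union.union).sum() == 0


def test_union_without_any_csf(slab_phantom):
    """The invisible-CSF limit: labels with no CSF code still give a valid
    union (= GM)."""
    labels = slab_phantom["labels"]
    from neosurf.volume_io import LabelVolume
    d = labels.data.copy()
    d[d == 1] = 2
    u = build_union(LabelVolume(d, labels.affine))
    assert u.union.sum() > 0
    assert not u.csf.any()


def test_hull_of_convex_mask_is_its_border():
    mask = np.zeros((24, 24, 24), bool)
    mask[4:20, 4:20, 4:20] = True
    from neosurf.volume_io import LabelVolume
    lab = np.where(mask, 2, 0).astype(np.int16)
    u = build_union(LabelVolume(lab, np.eye(4)))
    border = mask & ~ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1))
    assert np.array_equal(u.hull, border)


def test_ball_curvature_close_to_analytic():
    x, y, z = np.mgrid[:32, :32, :32]
    R = 10.0
    ball = (x - 16) ** 2 + (y - 16) ** 2 + (z - 16) ** 2 < R ** 2
    cf = boundary_curvature(ball, (1, 1, 1), 1.0)
    H = cf.H[cf.boundary]
    K = cf.K[cf.boundary]
    assert abs(H.mean() - 1.0 / R) / (1.0 / R) < 0.25
    assert abs(K.mean() - 1.0 / R ** 2) / (1.0 / R ** 2) < 0.40


def test_flat_face_curvature_negligible_vs_ball():
    slab = np.zeros((32, 32, 32), bool)
    slab[4:28, 4:28, 4:16] = True
    cf = boundary_curvature(slab, (1, 1, 1), 1.0)
    face = np.zeros_like(slab)
    face[10:22, 10:22, 15] = True
    face &= cf.boundary
    assert np.abs(cf.H[face]).max() < (1.0 / 10.0) / 5.0
    assert np.abs(cf.K[face]).max() < (1.0 / 100.0) / 5.0


def test_saddle_gaussian_curvature_negative(slab_phantom):
    """At the sulcal wall-to-fundus bend of the WM surface the Gaussian
    curvature of the keel corner is negative (saddle)."""
    labels = slab_phantom["labels"]
    truth = slab_phantom["truth"]
    wm = labels.data == 3
    cf = boundary_curvature(wm, labels.spacing, 1.0)
    p = truth.params
    ijk = np.array(np.nonzero(cf.boundary)).T
    xyz = np.atleast_2d(labels.world_from_voxel(ijk))
    # corner region: near the slit wall at the top of the keel arc
    xk = p["sulci_x"][1]
    corner = (np.abs(np.abs(xyz[:, 0] - xk) - 2.0) < 1.0) \
        & (np.abs(xyz[:, 2] - p["fundus_z"]) < 1.5) \
        & (xyz[:, 1] > p["block_y"][0] + 3) \
        & (xyz[:, 1] < p["block_y"][1] - 3)
    K = cf.K[ijk[corner, 0], ijk[corner, 1], ijk[corner, 2]]
    assert K.min() < 0


def test_shell_has_no_seeds(shell_phantom):
    union = build_union(shell_phantom["labels"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seeds = seed_catchment_basins(union)
    assert seeds.sum() == 0


def test_slab_seeds_sit_at_fundi(slab_phantom):
    labels = slab_phantom["labels"]
    truth = slab_phantom["truth"]
    union = build_union(labels)
    seeds = seed_catchment_basins(union)
    _, n = ndimage.label(seeds, structure=np.ones((3, 3, 3)))
    assert n >= labels.data.shape[0] // 56 * 3 or n >= 3
    ijk = np.array(np.nonzero(seeds)).T
    xyz = np.atleast_2d(labels.world_from_voxel(ijk))
    d = np.min(np.abs(xyz[:, 0][:, None]
                      - np.asarray(truth.params["sulci_x"])[None, :]), axis=1)
    assert d.max() <= 2.0
    assert np.all(np.abs(xyz[:, 2] - truth.params["fundus_z"]) <= 2.0)


def test_infinite_threshold_means_no_seeds(slab_phantom):
    union = build_union(slab_phantom["labels"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seeds = seed_catchment_basins(union, k_threshold=np.inf, mode="K")
    assert seeds.sum() == 0


def test_erosion_preserves_topology_throughout(slab_phantom):
    """Connected components and Euler number of the object never change
    during the homotopic erosion (audited every 200 removals)."""
    union = build_union(slab_phantom["labels"])
    seeds = seed_catchment_basins(union)
    skel = homotopic_erode(union, seeds, audit_every=200)
    audit = np.array(skel.audit)
    assert len(audit) > 3
    assert set(audit[:, 1].tolist()) == {audit[0, 1]}
    assert set(audit[:, 2].tolist()) == {audit[0, 2]}


def test_medial_sheet_accuracy_on_invisible_csf(slab_phantom, slab_skeleton):
    """>= 90% of fundus-region skeleton voxels lie within one voxel of the
    analytic inter-bank medial plane."""
    labels = slab_phantom["labels"]
    truth = slab_phantom["truth"]
    spec = slab_phantom["spec"]
    skel = slab_skeleton["skel"]
    union = slab_skeleton["union"]
    p = truth.params
    ijk = np.array(np.nonzero(skel.mask & ~union.hull)).T
    xyz = np.atleast_2d(labels.world_from_voxel(ijk))
    sulci = np.asarray(p["sulci_x"])
    in_fundus = np.zeros(len(xyz), bool)
    for xk in sulci:
        in_fundus |= (np.abs(xyz[:, 0] - xk) <= spec.fold_wavelength / 4) \
            & (xyz[:, 2] > p["fundus_z"] + 2) & (xyz[:, 2] < p["z_top"] - 2)
    d_plane = np.min(np.abs(xyz[:, 0][:, None] - sulci[None, :]), axis=1)
    assert in_fundus.sum() > 100
    assert (d_plane[in_fundus] <= spec.spacing).mean() >= 0.90
    # every sulcus holds a substantial sheet
    for xk in sulci:
        sheet = (np.abs(xyz[:, 0] - xk) <= 1.0) \
            & (xyz[:, 2] > p["fundus_z"]) & (xyz[:, 2] < p["z_top"])
        assert sheet.sum() > 50


def test_skeleton_structure_invariants(slab_phantom, slab_skeleton):
    skel = slab_skeleton["skel"]
    union = slab_skeleton["union"]
    assert not (skel.mask & ~union.union).any()          # skeleton in union
    assert not (union.hull & ~skel.mask).any()           # hull kept
    assert (skel.classes == TOPO_CODES["interior"]).sum() == 0  # thin


def test_one_voxel_sheet_is_idempotent():
    """A free-standing one-voxel plate is entirely hull (its own closing
    boundary), so erosion returns it unchanged."""
    from neosurf.volume_io import LabelVolume
    lab = np.zeros((16, 16, 16), np.int16)
    lab[3:13, 3:13, 8] = 2
    union = build_union(LabelVolume(lab, np.eye(4)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seeds = seed_catchment_basins(union)
        skel = homotopic_erode(union, seeds)
    assert np.array_equal(skel.mask, union.union)


def test_prune_removes_branches_keeps_sheets():
    sheet = np.zeros((14, 14, 14), bool)
    sheet[2:12, 2:12, 6] = True
    with_branch = sheet.copy()
    with_branch[6, 6, 7:12] = True
    pruned = prune_skeleton(SkeletonVoxels(mask=with_branch))
    assert np.array_equal(pruned.mask, sheet)
    # pure sheet unchanged
    assert np.array_equal(prune_skeleton(SkeletonVoxels(mask=sheet)).mask,
                          sheet)
    # empty deletable set is the identity
    assert np.array_equal(
        prune_skeleton(SkeletonVoxels(mask=with_branch),
                       deletable_classes=()).mask, with_branch)


def test_prune_rejects_unknown_class():
    with pytest.raises(ValueError):
        prune_skeleton(SkeletonVoxels(mask=np.ones((3, 3, 3), bool)),
                       deletable_classes={"bogus"})


def test_shell_skeleton_is_hull_only(shell_recon):
    skel = shell_recon["skel"]
    union = shell_recon["union"]
    assert not (skel.mask & ~union.hull).any()
    assert euler_characteristic(skel.mask) == \
        euler_characteristic(union.union)
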