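"""Volume and surface I/O plus the project-wide coordinate contract.

Every mesh lives in world millimetres; every voxel set in 0-based indices
referring to voxel centres.  The only bridge between the two is the NIfTI
affine carried by :class:`VoxelGrid`.  Tissue labels follow the fixed
convention {0: background, 1: CSF, 2: GM, 3: WM}.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

LABEL_BACKGROUND, LABEL_CSF, LABEL_GM, LABEL_WM = 0, 1, 2, 3
VALID_LABELS = (LABEL_BACKGROUND, LABEL_CSF, LABEL_GM, LABEL_WM)


@dataclass
class VoxelGrid:
    """3-D scalar field with a voxel-index -> world-mm affine.

    data   : (nx, ny, nz) array (intensity a.u., potential, or label codes)
    affine : 4x4 transform; ``world = affine @ (i, j, k, 1)``
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("data must be a 3-D array with positive shape")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_from_voxel(self, ijk) -> np.ndarray:
        """World-mm coordinates of voxel centre(s) ``ijk`` (0-based)."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        xyz = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return xyz[0] if xyz.shape[0] == 1 and np.asarray(ijk).ndim else xyz

    def voxel_from_world(self, xyz) -> np.ndarray:
        """Continuous voxel coordinates of world point(s) ``xyz``."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        ijk = xyz @ inv[:3, :3].T + inv[:3, 3]
        return ijk[0] if ijk.shape[0] == 1 else ijk

    def like(self, data: np.ndarray) -> "VoxelGrid":
        """New grid with the same affine."""
        return VoxelGrid(data, self.affine.copy())


class LabelVolume(VoxelGrid):
    """VoxelGrid whose data are integer tissue codes {0, 1, 2, 3}."""

    def __post_init__(self):
        super().__post_init__()
        self.data = self.data.astype(np.int16, copy=False)
        present = np.unique(self.data)
        if not np.isin(present, VALID_LABELS).all():
            raise ValueError(
                "label volume contains codes outside {0,1,2,3}: %s"
                % present[~np.isin(present, VALID_LABELS)])

    def mask(self, label: int) -> np.ndarray:
        return self.data == label


# ---------------------------------------------------------------------------
# volume I/O

def read_volume(path, labels: bool = False, remap: dict | None = None,
                reorient_ras: bool = False) -> VoxelGrid:
    """Read a NIfTI-1/2 (or MINC2, if nibabel supports it) volume.

    labels=True validates/coerces tissue codes; ``remap`` translates a
    foreign label scheme ({foreign: ours}) before validation.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    if reorient_ras:
        img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {data.shape}")
    affine = np.asarray(img.affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("volume affine is not invertible")
    if labels:
        data = np.rint(data).astype(np.int16)
        if remap:
            out = np.zeros_like(data)
            for src, dst in remap.items():
                out[data == src] = dst
            data = out
        return LabelVolume(data, affine)
    return VoxelGrid(data, affine)


def write_volume(grid: VoxelGrid, path) -> None:
    """Write to NIfTI.  Integer data round-trips bit-exactly; float data is
    stored as float32."""
    data = grid.data
    if np.issubdtype(data.dtype, np.integer) or data.dtype == bool:
        data = data.astype(np.int16)
    else:
        data = data.astype(np.float32)
    img = nib.Nifti1Image(data, grid.affine)
    img.header.set_data_dtype(data.dtype)
    nib.save(img, str(path))


def resample_isotropic(grid: VoxelGrid, target_spacing: float,
                       is_labels: bool | None = None) -> VoxelGrid:
    """Resample to isotropic voxels of ``target_spacing`` mm.

    Intensities are interpolated trilinearly, labels by nearest neighbour.
    The world extent is preserved to within one voxel.
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    if min(grid.shape) < 2:
        raise ValueError("cannot resample a single-slice volume")
    if is_labels is None:
        is_labels = isinstance(grid, LabelVolume)

    spacing = grid.spacing
    direction = grid.affine[:3, :3] / spacing  # unit columns
    new_shape = np.maximum(
        1, np.ceil(np.asarray(grid.shape) * spacing / target_spacing)
    ).astype(int)
    new_affine = np.eye(4)
    new_affine[:3, :3] = direction * target_spacing
    # keep the world position of voxel (0,0,0)'s corner fixed: voxel centres
    # shift by half the spacing difference along each axis
    shift = direction @ ((target_spacing - spacing) / 2.0)
    new_affine[:3, 3] = grid.affine[:3, 3] + shift

    # input voxel coords of each output voxel: inv(A1) @ A2
    M = np.linalg.inv(grid.affine) @ new_affine
    order = 0 if is_labels else 1
    out = ndimage.affine_transform(
        grid.data.astype(float), M[:3, :3], offset=M[:3, 3],
        output_shape=tuple(new_shape), order=order, mode="constant", cval=0.0)
    if is_labels:
        return LabelVolume(np.rint(out).astype(np.int16), new_affine)
    return VoxelGrid(out, new_affine)


def world_from_voxel(grid: VoxelGrid, ijk):
    """World-mm position of in-bounds voxel index ``ijk``."""
    arr = np.asarray(ijk)
    if np.any(arr < 0) or np.any(arr >= np.asarray(grid.shape)[-arr.shape[-1]:]):
        raise IndexError(f"voxel index {ijk} out of bounds for {grid.shape}")
    return grid.world_from_voxel(ijk)


def voxel_from_world(grid: VoxelGrid, xyz):
    return grid.voxel_from_world(xyz)


# ---------------------------------------------------------------------------
# surface I/O

def write_surface(mesh, path, scalars: np.ndarray | None = None) -> None:
    """Write a mesh as GIFTI (.gii / .surf.gii) or Wavefront OBJ (.obj).

    Per-vertex ``scalars`` go to a sibling ``.func.gii`` (GIFTI) or a plain
    text file with one value per vertex line (OBJ).
    """
    path = str(path)
    if scalars is not None:
        scalars = np.asarray(scalars, dtype=np.float32).ravel()
        if len(scalars) != mesh.n_vertices:
            raise ValueError(
                f"scalar length {len(scalars)} != vertex count {mesh.n_vertices}")
    if path.endswith(".obj"):
        lines = ["v %.8f %.8f %.8f" % tuple(v) for v in mesh.vertices]
        lines += ["f %d %d %d" % tuple(f + 1) for f in mesh.faces]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
        if scalars is not None:
            np.savetxt(path[:-4] + "_scalars.txt", scalars, fmt="%.6f")
        return
    if path.endswith(".gii"):
        darrays = [
            nib.gifti.GiftiDataArray(
                mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"),
            nib.gifti.GiftiDataArray(
                mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"),
        ]
        nib.save(nib.gifti.GiftiImage(darrays=darrays), path)
        if scalars is not None:
            base = path[:-len(".surf.gii")] if path.endswith(".surf.gii") \
                else path[:-len(".gii")]
            func = nib.gifti.GiftiImage(darrays=[
                nib.gifti.GiftiDataArray(scalars, intent="NIFTI_INTENT_SHAPE")])
            nib.save(func, base + ".func.gii")
        return
    raise ValueError(f"unsupported surface format: {path}")


def read_surface(path):
    """Read a GIFTI or OBJ surface back into a TriangleMesh."""
    from .mesh import TriangleMesh

    path = str(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such surface: {path}")
    if path.endswith(".obj"):
        verts, faces = [], []
        with open(path) as fh:
            for line in fh:
                t = line.split()
                if not t:
                    continue
                if t[0] == "v":
                    verts.append([float(x) for x in t[1:4]])
                elif t[0] == "f":
                    faces.append([int(x.split("/")[0]) - 1 for x in t[1:4]])
        return TriangleMesh(np.asarray(verts), np.asarray(faces))
    img = nib.load(path)
    verts = faces = None
    for da in img.darrays:
        if da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
            verts = da.data
        elif da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
            faces = da.data
    if verts is None or faces is None:
        raise ValueError(f"{path} lacks pointset/triangle arrays")
    return TriangleMesh(np.asarray(verts, float), np.asarray(faces, int))


def read_scalar_map(path) -> np.ndarray:
    """Read a per-vertex scalar map (.func.gii or plain text)."""
    path = str(path)
    if path.endswith(".gii"):
        img = nib.load(path)
        return np.asarray(img.darrays[0].data, dtype=float).ravel()
    return np.loadtxt(path, dtype=float).ravel()


def read_landmarks(path) -> np.ndarray:
    """Plain-text landmark file: one ``x y z`` (world mm) per line."""
    pts = np.atleast_2d(np.loadtxt(path, dtype=float))
    if pts.shape[1] != 3 or not np.isfinite(pts).all():
        raise ValueError("landmark file must contain finite 'x y z' rows")
    return pts
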