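"""Intensity-gradient surface refinement.

A reconstructed surface is pulled onto the actual tissue edge by analyzing
the 1-D intensity profile along each vertex normal: samples every
``search_step`` mm within ``+-search_distance``, Gaussian-blurred along the
ray, and searched for the maximum signed gradient.  The intensity found at
each vertex's edge is diffused across the mesh into a slowly varying
per-vertex target-intensity map; gradients are then re-scored by how well
the local intensity matches that target, which lets the edge contrast vary
over the surface (the regionally changing contrast of the neonatal T1w
cortex).  Deformation runs coarse-to-fine over a resolution schedule with a
smoothness-regularized displacement field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .mesh import TriangleMesh, smooth_vertex_values
from .volume_io import VoxelGrid


@dataclass
class ProfileParams:
    search_step: float = 0.5          # mm between samples along the normal
    search_distance: float = 5.0      # mm inward and outward
    profile_blur_sigma: float = 1.0   # in samples
    expected_sign: int | str = "auto"  # +1, -1 or 'auto' (inside->outside)

    def __post_init__(self):
        if self.search_step <= 0 or self.search_distance < self.search_step:
            raise ValueError("need search_step > 0 and "
                             "search_distance >= search_step")
        if self.expected_sign not in (+1, -1, "auto"):
            raise ValueError("expected_sign must be +1, -1 or 'auto'")

    @property
    def n_half(self) -> int:
        return int(np.floor(self.search_distance / self.search_step))

    @property
    def offsets(self) -> np.ndarray:
        k = self.n_half
        return np.arange(-k, k + 1) * self.search_step


@dataclass
class DeformationParams:
    attraction_weight: float = 1.0
    smoothness_weight: float = 0.5
    max_iterations: int = 50
    step_size: float = 0.2            # mm max move per iteration
    convergence_tol: float = 0.02     # mm mean displacement
    target_blur_iterations: int = 10
    resolution_schedule: tuple = ((5.0, 1.0), (3.0, 0.5), (1.5, 0.25))

    def __post_init__(self):
        d = [s[0] for s in self.resolution_schedule]
        if any(b >= a for a, b in zip(d[:-1], d[1:])) is False and \
                list(d) != sorted(d, reverse=True):
            raise ValueError("schedule search distances must decrease")
        if self.attraction_weight < 0 or self.smoothness_weight < 0:
            raise ValueError("weights must be >= 0")


@dataclass
class TargetIntensityMap:
    """Per-vertex edge intensity (a.u.) and edge offset (mm)."""

    intensity: np.ndarray
    offset: np.ndarray
    defined: np.ndarray


# ---------------------------------------------------------------------------
# profile sampling

def _interpolate(grid: VoxelGrid, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation at world points; NaN outside the volume."""
    vox = grid.voxel_from_world(points.reshape(-1, 3))
    vox = np.atleast_2d(vox)
    vals = ndimage.map_coordinates(grid.data.astype(float), vox.T, order=1,
                                   mode="constant", cval=np.nan)
    return vals


def sample_profiles(mesh: TriangleMesh, intensity: VoxelGrid,
                    params: ProfileParams,
                    normals: np.ndarray | None = None,
                    sample_mask: VoxelGrid | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Blurred intensity profiles along all vertex normals.

    Returns (profiles (n, 2K+1), valid mask (n, 2K+1)).  Samples outside
    the volume, or outside ``sample_mask`` (typically the brain mask), are
    invalid; profiles are Gaussian-blurred along the ray after edge-filling
    invalid samples.
    """
    if normals is None:
        normals = mesh.vertex_normals()
    offs = params.offsets
    pts = (mesh.vertices[:, None, :]
           + offs[None, :, None] * normals[:, None, :])
    raw = _interpolate(intensity, pts).reshape(len(mesh.vertices), len(offs))
    valid = np.isfinite(raw)
    if sample_mask is not None:
        inside = np.nan_to_num(
            _interpolate(sample_mask, pts)).reshape(raw.shape) > 0.5
        valid &= inside
        raw = np.where(valid, raw, np.nan)
    prof = raw.copy()
    # fill invalid samples from the nearest valid one along the ray
    if not valid.all():
        idx = np.where(valid, np.arange(prof.shape[1])[None, :], -1)
        fwd = np.maximum.accumulate(idx, axis=1)
        prof_f = np.where(fwd >= 0,
                          np.take_along_axis(raw, np.maximum(fwd, 0), axis=1),
                          np.nan)
        idxb = np.where(valid, np.arange(prof.shape[1])[None, :],
                        prof.shape[1] + 1)
        bwd = np.minimum.accumulate(idxb[:, ::-1], axis=1)[:, ::-1]
        prof_b = np.where(bwd <= prof.shape[1],
                          np.take_along_axis(
                              raw, np.minimum(bwd, prof.shape[1] - 1), axis=1),
                          np.nan)
        prof = np.where(valid, raw, np.where(np.isfinite(prof_f), prof_f,
                                             prof_b))
    if params.profile_blur_sigma > 0:
        prof = ndimage.gaussian_filter1d(
            np.nan_to_num(prof), params.profile_blur_sigma, axis=1,
            mode="nearest")
        prof[~np.isfinite(raw).any(axis=1)] = np.nan
    return prof, valid


def sample_profile(mesh: TriangleMesh, vertex: int, intensity: VoxelGrid,
                   params: ProfileParams) -> np.ndarray:
    """Single-vertex profile (NaN where out of volume)."""
    prof, valid = sample_profiles(mesh, intensity, params)
    out = prof[vertex].copy()
    out[~valid[vertex]] = np.nan
    return out


# ---------------------------------------------------------------------------
# edge finding

def _profile_gradients(profiles: np.ndarray, step: float) -> np.ndarray:
    g = np.gradient(profiles, step, axis=-1)
    return g


def find_edges(profiles: np.ndarray, valid: np.ndarray,
               params: ProfileParams,
               target_intensity: np.ndarray | None = None,
               target_bandwidth: float | None = None,
               candidate_mask: np.ndarray | None = None,
               select: str = "max") -> TargetIntensityMap:
    """Edge offset and intensity per profile.

    The edge is the sample with maximum signed gradient matching
    ``expected_sign`` ('auto': maximum magnitude), optionally re-scored by
    similarity of the sample intensity to ``target_intensity`` (Gaussian
    kernel of width ``target_bandwidth``) and restricted to
    ``candidate_mask``.  select='nearest' takes the local score maximum
    closest to the surface among competitive candidates instead of the
    global maximum.  The offset is refined by parabolic interpolation.
    Profiles whose best gradient does not exceed twice the robust noise
    floor (from pooled second differences) get offset 0 and are flagged
    undefined.
    """
    profiles = np.atleast_2d(profiles)
    valid = np.atleast_2d(valid)
    n, m = profiles.shape
    offs = params.offsets
    grad = _profile_gradients(np.nan_to_num(profiles), params.search_step)

    if params.expected_sign == "auto":
        score = np.abs(grad)
    else:
        score = grad * float(params.expected_sign)
    ok = valid.copy()
    ok[:, 0] = ok[:, -1] = False  # one-sided gradients are unreliable
    if candidate_mask is not None:
        restricted = ok & candidate_mask
        # fall back to unrestricted where the restriction empties the row
        use = restricted.any(axis=1)
        ok = np.where(use[:, None], restricted, ok)
    score = np.where(ok, score, -np.inf)

    if target_intensity is not None:
        if target_bandwidth is None or target_bandwidth <= 0:
            target_bandwidth = 1.0
        sim = np.exp(-0.5 * ((profiles - np.asarray(target_intensity)
                              [:, None]) / target_bandwidth) ** 2)
        with np.errstate(invalid="ignore"):
            score = np.where(np.isfinite(score), score * sim, -np.inf)

    rows = np.arange(n)
    # robust gradient noise floor pooled over all profiles: second
    # differences vanish on plateaus and ramps, so their median magnitude
    # isolates the noise (sd of d2 = sqrt(6) * sample noise)
    d2 = profiles[:, :-2] - 2 * profiles[:, 1:-1] + profiles[:, 2:]
    d2_ok = valid[:, :-2] & valid[:, 1:-1] & valid[:, 2:]
    pooled_d2 = np.abs(d2[d2_ok])
    sigma_i = 1.4826 * float(np.median(pooled_d2)) / np.sqrt(6.0) \
        if pooled_d2.size else 0.0
    noise = sigma_i * np.sqrt(2.0) / (2.0 * params.search_step)

    if select == "nearest":
        # candidates: local maxima of the score that exceed the noise
        # floor, have the right sign, and are competitive (>= 30% of the
        # row's best); pick the one closest to the current surface
        smax = np.full_like(score, -np.inf)
        smax[:, 1:-1] = np.where(
            (score[:, 1:-1] >= score[:, :-2])
            & (score[:, 1:-1] >= score[:, 2:]), score[:, 1:-1], -np.inf)
        eligible = np.isfinite(smax) & (score > 0) \
            & (np.abs(grad) >= 2.0 * noise) & (np.abs(grad) > 1e-12)
        with np.errstate(invalid="ignore"):
            rowmax = np.max(np.where(eligible, score, -np.inf), axis=1)
        eligible &= score >= 0.3 * np.maximum(rowmax, 0.0)[:, None]
        dist_rank = np.where(eligible, np.abs(offs)[None, :], np.inf)
        best = np.argmin(dist_rank, axis=1)
        have = eligible[rows, best]
        # fall back to the global maximum where no local max qualifies
        best_global = np.argmax(score, axis=1)
        best = np.where(have, best, best_global)
    elif select == "max":
        best = np.argmax(score, axis=1)
    else:
        raise ValueError("select must be 'max' or 'nearest'")

    best_grad = np.abs(grad[rows, best])
    defined = (np.isfinite(score[rows, best])
               & (best_grad >= 2.0 * noise) & (best_grad > 1e-12)
               & (valid.sum(axis=1) >= 3))

    # parabolic sub-sample refinement on the gradient magnitude
    delta = np.zeros(n)
    inner = (best > 0) & (best < m - 1) & defined
    g0 = np.abs(grad[rows, np.maximum(best - 1, 0)])
    g1 = best_grad
    g2 = np.abs(grad[rows, np.minimum(best + 1, m - 1)])
    denom = g0 - 2 * g1 + g2
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 0.5 * (g0 - g2) / denom
    d = np.where(np.isfinite(d) & (np.abs(d) <= 0.5), d, 0.0)
    delta[inner] = d[inner]

    offset = np.where(defined, offs[best] + delta * params.search_step, 0.0)
    # clamp into the search range
    offset = np.clip(offset, offs[0], offs[-1])
    edge_int = profiles[rows, best]
    edge_int = np.where(defined, edge_int, np.nan)
    return TargetIntensityMap(intensity=edge_int, offset=offset,
                              defined=defined)


def find_edge(profile: np.ndarray, params: ProfileParams
              ) -> tuple[float, float]:
    """(offset mm, edge intensity) for a single profile; offset 0 and NaN
    intensity when no edge exceeds the noise floor."""
    profile = np.asarray(profile, float)
    valid = np.isfinite(profile)
    if valid.sum() < 3:
        raise ValueError("profile needs at least 3 valid samples")
    res = find_edges(profile[None, :], valid[None, :], params)
    return float(res.offset[0]), float(res.intensity[0])


# ---------------------------------------------------------------------------
# target-map diffusion

def blur_target_map(mesh: TriangleMesh, tmap: TargetIntensityMap,
                    n_iterations: int = 10) -> TargetIntensityMap:
    """Surface-based diffusion of the edge-intensity map.

    Undefined vertices are first filled by repeated 1-ring means of defined
    neighbours; the complete map is then diffused with the mean-conserving
    graph-Laplacian smoother.
    """
    vals = tmap.intensity.copy()
    defined = tmap.defined.copy()
    if not defined.any():
        vals[:] = np.nanmean(vals) if np.isfinite(vals).any() else 0.0
    else:
        fill = np.where(defined, vals, np.nan)
        indptr, indices = mesh.neighbor_csr
        for _ in range(mesh.n_vertices):
            missing = ~np.isfinite(fill)
            if not missing.any():
                break
            nb_vals = np.where(np.isfinite(fill[indices]), fill[indices], 0.0)
            nb_cnt = np.add.reduceat(
                np.isfinite(fill[indices]).astype(float), indptr[:-1])
            nb_sum = np.add.reduceat(nb_vals, indptr[:-1])
            newly = missing & (nb_cnt > 0)
            fill[newly] = nb_sum[newly] / nb_cnt[newly]
        fill[~np.isfinite(fill)] = np.nanmean(fill)
        vals = fill
    sm = smooth_vertex_values(mesh, vals, n_iterations, lam=0.5)
    return TargetIntensityMap(intensity=sm, offset=tmap.offset.copy(),
                              defined=np.ones_like(defined))


# ---------------------------------------------------------------------------
# deformation

def deform_to_edges(mesh: TriangleMesh, intensity: VoxelGrid,
                    pparams: ProfileParams | None = None,
                    dparams: DeformationParams | None = None,
                    barrier: np.ndarray | None = None,
                    csf_mask: np.ndarray | None = None,
                    brain_mask: np.ndarray | None = None,
                    verbose: bool = False) -> TriangleMesh:
    """Fit a surface to the maximum-gradient tissue edge.

    Per level of the resolution schedule: find per-vertex edges, build and
    blur the target-intensity map, re-score edges toward each vertex's
    target intensity, then move vertices along their normals toward the
    edge with a smoothness-regularized displacement, clipped at
    ``step_size`` per iteration.  ``barrier``: binary grid (skeleton or
    mask) that vertices may not cross.  ``csf_mask``: binary CSF grid; when
    given, candidate edges are restricted to offsets whose outward sample
    is CSF wherever CSF is locally present.
    """
    pparams = pparams or ProfileParams()
    dparams = dparams or DeformationParams()
    work = mesh.copy()
    barrier_grid = None
    if barrier is not None:
        barrier_grid = VoxelGrid(np.asarray(barrier, float), intensity.affine)
    csf_grid = None
    if csf_mask is not None:
        csf_grid = VoxelGrid(np.asarray(csf_mask, float), intensity.affine)
    mask_grid = None
    if brain_mask is not None:
        mask_grid = VoxelGrid(np.asarray(brain_mask, float), intensity.affine)

    for (dist_mm, step_mm) in dparams.resolution_schedule:
        lp = ProfileParams(search_step=step_mm, search_distance=dist_mm,
                           profile_blur_sigma=pparams.profile_blur_sigma,
                           expected_sign=pparams.expected_sign)
        prev_mean = np.inf
        diverging = 0
        target = None
        bandwidth = None
        for it in range(dparams.max_iterations):
            normals = work.vertex_normals()
            prof, valid = sample_profiles(work, intensity, lp,
                                          normals=normals,
                                          sample_mask=mask_grid)
            cand = None
            if csf_grid is not None:
                offs = lp.offsets
                pts = (work.vertices[:, None, :]
                       + (offs[None, :, None] + lp.search_step)
                       * normals[:, None, :])
                frac = _interpolate(csf_grid, pts).reshape(prof.shape)
                cand = np.nan_to_num(frac) > 0.25
            if target is None:
                # level-start target map: the intensity at each vertex's
                # nearest suitable edge, diffused over the mesh, so the
                # admissible edge contrast varies smoothly over the
                # surface without chasing the deforming surface
                first = find_edges(prof, valid, lp, candidate_mask=cand,
                                   select="nearest")
                tmap = blur_target_map(work, first,
                                       dparams.target_blur_iterations)
                target = tmap.intensity
                pooled = prof[valid]
                # contrast scale of the local profiles (percentile spread
                # is robust to plateau-dominated sampling)
                bandwidth = max(0.25 * float(np.percentile(pooled, 95)
                                             - np.percentile(pooled, 5)),
                                1e-3) if pooled.size else 1.0
            scored = find_edges(prof, valid, lp,
                                target_intensity=target,
                                target_bandwidth=bandwidth,
                                candidate_mask=cand, select="nearest")
            offsets = np.where(scored.defined, scored.offset, 0.0)
            smoothed = smooth_vertex_values(
                work, offsets,
                n_iterations=max(1, int(round(2 * dparams.smoothness_weight
                                              / 0.5))),
                lam=0.5)
            # under-relaxation: half steps prevent half-sample
            # oscillation around the converged edge
            relax = 1.0 if it == 0 else 0.5
            move = relax * dparams.attraction_weight * np.clip(
                smoothed, -dparams.step_size, dparams.step_size)
            new_v = work.vertices + move[:, None] * normals
            if barrier_grid is not None:
                hit = np.nan_to_num(_interpolate(barrier_grid, new_v)) > 0.5
                new_v[hit] = work.vertices[hit]
                move[hit] = 0.0
            work = work.with_vertices(new_v)
            mean_move = float(np.mean(np.abs(move)))
            if verbose:
                print(f"  level {dist_mm}/{step_mm} it {it}: "
                      f"mean|d| = {mean_move:.4f}")
            if mean_move < dparams.convergence_tol:
                break
            if mean_move > prev_mean * (1 + 1e-9):
                diverging += 1
                if diverging >= 3:
                    warnings.warn(
                        f"deformation diverging at level {dist_mm} mm; "
                        "aborting level", stacklevel=2)
                    break
            else:
                diverging = 0
            prev_mean = mean_move
    return work
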