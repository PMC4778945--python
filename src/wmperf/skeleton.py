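"""Mean-FA skeletonization and perpendicular projection (the TBSS core).

The cohort mean FA map is thinned to a one-voxel-thick ridge ("skeleton")
representing tract centres: at every voxel above the FA threshold the
tract-perpendicular direction is estimated from the Hessian of the smoothed
mean FA, quantized to the nearest lattice direction, and the voxel is kept
if its FA is a local maximum along that direction (with a deterministic
centre-of-plateau tie-break for flat ridges).  Subject data are then
projected onto the skeleton by searching along the same perpendicular for
the subject's maximum FA; "non-FA" maps (CBF, variance, GM PVE, ...) are
sampled at the location of that FA maximum, never at their own maximum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .image import ImageVolume

logger = logging.getLogger(__name__)

__all__ = [
    "Skeleton",
    "mean_fa",
    "skeletonize",
    "project_to_skeleton",
    "project_many",
    "fill_skeleton",
]

# the 13 undirected lattice directions of a 3x3x3 neighbourhood
_LATTICE_DIRS = np.array(
    [
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
        (1, 1, 1), (1, -1, 1), (1, 1, -1), (1, -1, -1),
    ],
    dtype=np.int64,
)


@dataclass
class Skeleton:
    """Mean-FA ridge mask plus the per-voxel perpendicular search direction."""

    mask: ImageVolume
    fa_threshold: float
    #: (n_voxels, 3) integer indices of the skeleton voxels, sorted
    voxels: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=np.int64))
    #: (n_voxels, 3) integer lattice offset of the perpendicular direction
    search_offsets: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=np.int64))
    #: (n_voxels, 3) physical-space unit vector of the search direction
    search_dir: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    max_search_mm: float = 8.0

    @property
    def n_voxels(self) -> int:
        return self.voxels.shape[0]

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        return self.mask.voxel_size_mm

    def flat_indices(self) -> np.ndarray:
        return np.ravel_multi_index(self.voxels.T, self.mask.shape)

    def values_to_volume(self, values: np.ndarray, fill: float = 0.0) -> ImageVolume:
        """Scatter per-skeleton-voxel values back into a full volume."""
        out = np.full(self.mask.shape, fill, dtype=np.float64)
        out[tuple(self.voxels.T)] = values
        return ImageVolume(out, self.voxel_size_mm)


def mean_fa(fa_maps: list[ImageVolume]) -> ImageVolume:
    """Voxel-wise arithmetic mean FA over >= 2 subjects on a common grid."""
    if len(fa_maps) < 2:
        raise ValueError("mean_fa requires at least 2 subjects")
    first = fa_maps[0]
    for m in fa_maps[1:]:
        first.check_grid(m, "mean_fa")
    stack = np.stack([m.data for m in fa_maps], axis=0)
    return first.copy_with(stack.mean(axis=0))


def _grad_and_hessian_eigvec(fa: np.ndarray, voxel_size, sigma_voxels: float):
    """Smoothed FA gradient (per mm) and the min-curvature Hessian eigenvector."""
    sm = gaussian_filter(fa, sigma=sigma_voxels)
    spacing = list(voxel_size)
    grads = np.gradient(sm, *spacing)
    hess = np.empty(fa.shape + (3, 3))
    for i in range(3):
        gi = np.gradient(grads[i], *spacing)
        for j in range(3):
            hess[..., i, j] = gi[j]
    hess = 0.5 * (hess + np.swapaxes(hess, -1, -2))
    eigvals, eigvecs = np.linalg.eigh(hess)
    # eigh sorts ascending: column 0 is the most negative eigenvalue
    grad = np.stack(grads, axis=-1)
    return grad, eigvecs[..., :, 0]


def skeletonize(
    mean_fa_map: ImageVolume,
    fa_threshold: float = 0.3,
    sigma_voxels: float = 1.0,
    max_search_mm: float = 8.0,
    grad_tol: float = 0.005,
    tol: float = 1e-12,
) -> Skeleton:
    """Thin a mean-FA map into a one-voxel ridge skeleton.

    A supra-threshold voxel is a skeleton voxel when its FA strictly
    exceeds the values just beyond the run of FA-ties along the
    perpendicular direction, and it is the centre voxel of that tied run
    (centre-of-gravity tie-break; the lower index wins for even runs).
    """
    fa = np.asarray(mean_fa_map.data, dtype=np.float64)
    if np.any(fa < 0):
        raise ValueError("mean FA must be non-negative")
    supra = fa >= fa_threshold
    vs = np.asarray(mean_fa_map.voxel_size_mm)
    if not supra.any():
        warnings.warn("skeletonize: no voxel reaches the FA threshold; empty skeleton")
        return Skeleton(
            mask=mean_fa_map.copy_with(np.zeros_like(fa)),
            fa_threshold=fa_threshold,
            max_search_mm=max_search_mm,
        )

    grad, vecs = _grad_and_hessian_eigvec(fa, mean_fa_map.voxel_size_mm, sigma_voxels)

    # Search direction per candidate voxel: on slope voxels (FA changes by
    # more than grad_tol across one voxel) the search runs uphill along the
    # gradient, which removes e.g. the flanks of a conical tube profile; on
    # ridge/plateau voxels (negligible gradient) the perpendicular is the
    # min-curvature direction of the smoothed FA Hessian.
    phys = _LATTICE_DIRS * vs[None, :]
    phys_unit = phys / np.linalg.norm(phys, axis=1, keepdims=True)
    cand = np.argwhere(supra)
    v_at = vecs[supra]  # (N, 3)
    g_at = grad[supra]
    step_change = np.linalg.norm(g_at * vs[None, :], axis=1)  # FA per voxel step
    use_grad = step_change > grad_tol
    direction = np.where(use_grad[:, None], g_at, v_at)
    dots = np.abs(direction @ phys_unit.T)
    choice = np.argmax(dots, axis=1)
    offsets = _LATTICE_DIRS[choice]

    shape = fa.shape
    keep = np.zeros(cand.shape[0], dtype=bool)
    max_run = int(max(shape))

    def value_at(p):
        if np.all((p >= 0) & (p < shape)):
            return fa[tuple(p)]
        return -np.inf

    for n, (v, d) in enumerate(zip(cand, offsets)):
        f0 = fa[tuple(v)]
        runs = []
        beyond = []
        for sign in (+1, -1):
            steps = 0
            p = v + sign * d
            while steps < max_run:
                val = value_at(p)
                if abs(val - f0) <= tol:
                    steps += 1
                    p = p + sign * d
                else:
                    beyond.append(val)
                    break
            else:
                beyond.append(-np.inf)
            runs.append(steps)
        n_plus, n_minus = runs
        if not (f0 > beyond[0] + tol and f0 > beyond[1] + tol):
            continue
        run_len = n_plus + n_minus + 1
        centre = (run_len - 1) // 2  # centre of gravity; lower index on even ties
        keep[n] = n_minus == centre
    kept = cand[keep]
    kept_off = offsets[keep]
    order = np.lexsort((kept[:, 2], kept[:, 1], kept[:, 0]))
    kept, kept_off = kept[order], kept_off[order]
    mask = np.zeros(shape, dtype=np.float64)
    mask[tuple(kept.T)] = 1.0
    unit = (kept_off * vs[None, :]).astype(np.float64)
    norms = np.linalg.norm(unit, axis=1, keepdims=True)
    unit = np.divide(unit, norms, out=np.zeros_like(unit), where=norms > 0)
    logger.info("skeletonize: %d skeleton voxels (threshold %.2f)", kept.shape[0], fa_threshold)
    return Skeleton(
        mask=mean_fa_map.copy_with(mask),
        fa_threshold=fa_threshold,
        voxels=kept,
        search_offsets=kept_off,
        search_dir=unit,
        max_search_mm=max_search_mm,
    )


def _search_positions(skeleton: Skeleton, max_search_mm: float | None):
    """Sample positions along +/- the perpendicular, nearest first.

    Returns flat indices (N, 2*S+1) and a validity mask; invalid entries
    point at the skeleton voxel itself but are masked out.
    """
    if max_search_mm is None:
        max_search_mm = skeleton.max_search_mm
    vs = np.asarray(skeleton.voxel_size_mm)
    shape = skeleton.mask.shape
    vox = skeleton.voxels
    off = skeleton.search_offsets
    step_mm = np.linalg.norm(off * vs[None, :], axis=1)
    ratio = np.divide(
        max_search_mm, step_mm, out=np.zeros_like(step_mm), where=step_mm > 0
    )
    n_steps = np.floor(ratio).astype(int)
    s_max = int(n_steps.max(initial=0))
    seq = [0]
    for s in range(1, s_max + 1):
        seq.extend([s, -s])
    seq = np.asarray(seq, dtype=np.int64)  # (K,)
    pos = vox[:, None, :] + seq[None, :, None] * off[:, None, :]  # (N, K, 3)
    valid = np.abs(seq)[None, :] <= n_steps[:, None]
    inb = np.all((pos >= 0) & (pos < np.asarray(shape)[None, None, :]), axis=2)
    valid &= inb
    pos_clipped = np.clip(pos, 0, np.asarray(shape)[None, None, :] - 1)
    flat = np.ravel_multi_index(np.moveaxis(pos_clipped, 2, 0), shape)
    return flat, valid


def project_to_skeleton(
    subject_fa: ImageVolume,
    other_map: ImageVolume | None,
    skeleton: Skeleton,
    max_search_mm: float | None = None,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Project subject data onto the skeleton along the perpendicular search.

    For each skeleton voxel the subject's maximum FA within
    ``max_search_mm`` along the +/- perpendicular is found (nearest
    position wins ties, so an on-skeleton peak projects to itself); the FA
    projection takes that maximum, and the non-FA projection samples
    ``other_map`` at the same location.  Returns the FA values, or a
    (fa_values, other_values) pair when ``other_map`` is given.
    """
    skeleton.mask.check_grid(subject_fa, "project_to_skeleton")
    if skeleton.n_voxels == 0:
        empty = np.empty(0)
        return (empty, empty.copy()) if other_map is not None else empty
    flat, valid = _search_positions(skeleton, max_search_mm)
    fa_samp = subject_fa.data.reshape(-1)[flat]
    fa_samp = np.where(valid, fa_samp, -np.inf)
    best = np.argmax(fa_samp, axis=1)
    rows = np.arange(flat.shape[0])
    fa_proj = fa_samp[rows, best]
    if other_map is None:
        return fa_proj
    skeleton.mask.check_grid(other_map, "project_to_skeleton(other)")
    other_proj = other_map.data.reshape(-1)[flat[rows, best]]
    return fa_proj, other_proj


def project_many(
    subject_fa: ImageVolume,
    other_maps: dict[str, ImageVolume],
    skeleton: Skeleton,
    max_search_mm: float | None = None,
) -> dict[str, np.ndarray]:
    """Project FA and several companion maps using one shared FA search.

    Equivalent to repeated :func:`project_to_skeleton` calls, but the FA
    arg-max location is found once and every companion map is sampled there.
    Returns {"fa": ..., name: ...} arrays of per-skeleton-voxel values.
    """
    skeleton.mask.check_grid(subject_fa, "project_many")
    out: dict[str, np.ndarray] = {}
    if skeleton.n_voxels == 0:
        return {"fa": np.empty(0), **{k: np.empty(0) for k in other_maps}}
    flat, valid = _search_positions(skeleton, max_search_mm)
    fa_samp = subject_fa.data.reshape(-1)[flat]
    fa_samp = np.where(valid, fa_samp, -np.inf)
    best = np.argmax(fa_samp, axis=1)
    rows = np.arange(flat.shape[0])
    loc = flat[rows, best]
    out["fa"] = fa_samp[rows, best]
    for name, vol in other_maps.items():
        skeleton.mask.check_grid(vol, f"project_many({name})")
        out[name] = vol.data.reshape(-1)[loc]
    return out


def fill_skeleton(
    skeleton_values: np.ndarray,
    skeleton: Skeleton,
    radius_mm: float = 3.0,
) -> ImageVolume:
    """Thicken a per-skeleton-voxel statistic map for display.

    Every voxel within ``radius_mm`` (physical distance) of the skeleton
    receives the value of its nearest skeleton voxel — the usual
    sphere-convolution visualization of skeleton results.  ``radius_mm = 0``
    returns the values on the skeleton itself.
    """
    shape = skeleton.mask.shape
    out = np.zeros(shape, dtype=np.float64)
    if skeleton.n_voxels == 0:
        return ImageVolume(out, skeleton.voxel_size_mm)
    values = np.asarray(skeleton_values, dtype=np.float64)
    if values.shape[0] != skeleton.n_voxels:
        raise ValueError("skeleton_values length must equal the number of skeleton voxels")
    on = np.zeros(shape, dtype=bool)
    on[tuple(skeleton.voxels.T)] = True
    dist, (ix, iy, iz) = distance_transform_edt(
        ~on, sampling=skeleton.voxel_size_mm, return_indices=True
    )
    vol_values = np.zeros(shape)
    vol_values[tuple(skeleton.voxels.T)] = values
    inside = dist <= radius_mm
    out[inside] = vol_values[ix[inside], iy[inside], iz[inside]]
    return ImageVolume(out, skeleton.voxel_size_mm)
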