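"""Voxel-wise permutation GLM on skeleton data with TFCE and FWE control.

The model at every skeleton voxel v is ordinary least squares

    y_v = b0 + scalar covariates (age, sex, n_pairs, MRD)
             + voxel-dependent regressors (CBF_v, ASL variance_v, GM PVE_v)

with the projected microstructure metric (FA, MD, RD or AD) as outcome and
a t contrast on one voxel-dependent regressor (CBF).  Inference is by
Freedman-Lane permutation: the outcome is residualized against the nuisance
part of the design, residuals are permuted across subjects, the full model
is refit, and each permuted t map is TFCE-enhanced.  Uncorrected p values
compare each voxel's observed TFCE score with its own permutation
distribution; family-wise-corrected p values use the permutation
distribution of the maximum TFCE score.  Both one-sided directions are
always computed.

TFCE(v) = sum_h  e(v,h)^E * h^H * dh  over thresholds h = dh .. h(v), where
e(v,h) is the extent of the supra-threshold connected component containing
v, with connectivity restricted to skeleton voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .skeleton import Skeleton

logger = logging.getLogger(__name__)

__all__ = [
    "Design",
    "TFCEParams",
    "StatResult",
    "skeleton_adjacency",
    "fit_glm_t",
    "tfce",
    "permutation_inference",
    "threshold_and_split",
]


# --------------------------------------------------------------------------
# design
# --------------------------------------------------------------------------

@dataclass
class Design:
    """GLM design: demeaned scalar covariates plus voxel-dependent regressors.

    ``scalar_covariates`` is (n_subjects, k); ``voxelwise_regressors`` maps
    names to (n_subjects, n_voxels) matrices.  ``contrast`` names the tested
    voxel-dependent regressor, with ``contrast_sign`` +1 for a positive
    association.  All covariates are demeaned on construction (scalar
    columns globally, voxelwise regressors per voxel); an intercept is
    implicit.
    """

    scalar_covariates: np.ndarray
    voxelwise_regressors: dict[str, np.ndarray]
    contrast: str = "cbf"
    contrast_sign: int = 1

    def __post_init__(self) -> None:
        sc = np.asarray(self.scalar_covariates, dtype=np.float64)
        if sc.ndim != 2:
            raise ValueError("scalar_covariates must be (n_subjects, k)")
        self.scalar_covariates = sc - sc.mean(axis=0, keepdims=True)
        n = sc.shape[0]
        vox = {}
        n_vox = None
        for name, mat in self.voxelwise_regressors.items():
            m = np.asarray(mat, dtype=np.float64)
            if m.ndim != 2 or m.shape[0] != n:
                raise ValueError(f"voxelwise regressor {name!r} must be (n_subjects, V)")
            if n_vox is None:
                n_vox = m.shape[1]
            elif m.shape[1] != n_vox:
                raise ValueError("voxelwise regressors disagree on voxel count")
            vox[name] = m - m.mean(axis=0, keepdims=True)
        self.voxelwise_regressors = vox
        if self.contrast not in vox:
            raise KeyError(
                f"contrast regressor {self.contrast!r} not among voxelwise "
                f"regressors {sorted(vox)}"
            )
        if self.contrast_sign not in (-1, 1):
            raise ValueError("contrast_sign must be +1 or -1")

    @property
    def n_subjects(self) -> int:
        return self.scalar_covariates.shape[0]

    @property
    def n_voxels(self) -> int:
        return next(iter(self.voxelwise_regressors.values())).shape[1]

    @property
    def n_parameters(self) -> int:
        """Columns of the per-voxel design including the intercept."""
        return 1 + self.scalar_covariates.shape[1] + len(self.voxelwise_regressors)


@dataclass(frozen=True)
class TFCEParams:
    """TFCE enhancement parameters: the method's recommended defaults."""

    E: float = 0.5
    H: float = 2.0
    #: integration step; None means hmax / n_steps per enhanced map
    dh: float | None = None
    n_steps: int = 100
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.E <= 0 or self.H <= 0 or self.n_steps <= 0:
            raise ValueError("E, H and n_steps must be positive")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class StatResult:
    """Per-skeleton-voxel statistics for both contrast directions."""

    tmap: np.ndarray
    tfce_pos: np.ndarray
    tfce_neg: np.ndarray
    p_unc_pos: np.ndarray
    p_unc_neg: np.ndarray
    p_fwe_pos: np.ndarray
    p_fwe_neg: np.ndarray
    n_perm: int
    seed: int
    max_null_pos: np.ndarray | None = None
    max_null_neg: np.ndarray | None = None

    # aliases for the requested contrast direction (positive by convention)
    @property
    def tfce_map(self) -> np.ndarray:
        return self.tfce_pos

    @property
    def p_uncorrected(self) -> np.ndarray:
        return self.p_unc_pos

    @property
    def p_fwe(self) -> np.ndarray:
        return self.p_fwe_pos


# --------------------------------------------------------------------------
# skeleton adjacency + TFCE
# --------------------------------------------------------------------------

def _connectivity_offsets(connectivity: int) -> np.ndarray:
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dx, dy, dz))
    return np.asarray(offs, dtype=np.int64)


def skeleton_adjacency(skeleton: Skeleton, connectivity: int = 26) -> tuple[np.ndarray, np.ndarray]:
    """CSR adjacency (indptr, indices) among skeleton voxels."""
    vox = skeleton.voxels
    V = vox.shape[0]
    shape = skeleton.mask.shape
    flat_sorted = np.ravel_multi_index(vox.T, shape)  # voxels are lexsorted
    offs = _connectivity_offsets(connectivity)
    neighbor_lists: list[np.ndarray] = []
    counts = np.zeros(V, dtype=np.int64)
    all_src = []
    all_dst = []
    for off in offs:
        cand = vox + off[None, :]
        inb = np.all((cand >= 0) & (cand < np.asarray(shape)[None, :]), axis=1)
        if not inb.any():
            continue
        src = np.nonzero(inb)[0]
        flat_c = np.ravel_multi_index(cand[inb].T, shape)
        pos = np.searchsorted(flat_sorted, flat_c)
        pos_ok = (pos < V) & (flat_sorted[np.minimum(pos, V - 1)] == flat_c)
        all_src.append(src[pos_ok])
        all_dst.append(pos[pos_ok])
    if all_src:
        src = np.concatenate(all_src)
        dst = np.concatenate(all_dst)
        order = np.argsort(src, kind="stable")
        src, dst = src[order], dst[order]
        counts = np.bincount(src, minlength=V)
    else:
        src = np.empty(0, dtype=np.int64)
        dst = np.empty(0, dtype=np.int64)
    indptr = np.zeros(V + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    return indptr, dst.astype(np.int64)


@njit(cache=True)
def _uf_find(parent, v):  # pragma: no cover - numba
    root = v
    while parent[root] != root:
        root = parent[root]
    while parent[v] != root:
        nxt = parent[v]
        parent[v] = root
        v = nxt
    return root


@njit(cache=True)
def _tfce_kernel(values, order, indptr, indices, e_exp, h_exp, dh, n_steps):  # pragma: no cover
    V = values.shape[0]
    out = np.zeros(V)
    parent = np.full(V, -1, dtype=np.int64)
    size = np.zeros(V, dtype=np.int64)
    pos = 0
    for k in range(n_steps, 0, -1):
        h = k * dh
        while pos < V and values[order[pos]] >= h:
            v = order[pos]
            pos += 1
            parent[v] = v
            size[v] = 1
            for jj in range(indptr[v], indptr[v + 1]):
                u = indices[jj]
                if parent[u] != -1:
                    ru = _uf_find(parent, u)
                    rv = _uf_find(parent, v)
                    if ru != rv:
                        if size[ru] < size[rv]:
                            ru, rv = rv, ru
                        parent[rv] = ru
                        size[ru] += size[rv]
        inc = (h**h_exp) * dh
        for i in range(pos):
            v = order[i]
            r = _uf_find(parent, v)
            out[v] += (size[r] ** e_exp) * inc
    return out


def tfce(
    stat_values: np.ndarray,
    adjacency: tuple[np.ndarray, np.ndarray],
    params: TFCEParams = TFCEParams(),
) -> np.ndarray:
    """Threshold-free cluster enhancement of a non-negative skeleton map.

    Negative entries are clamped to zero (the opposite direction is
    enhanced separately on the negated map).  The integration step defaults
    to max(map)/n_steps, recomputed per map.
    """
    values = np.asarray(stat_values, dtype=np.float64)
    values = np.where(np.isfinite(values), values, 0.0)
    values = np.maximum(values, 0.0)
    hmax = float(values.max(initial=0.0))
    if hmax <= 0:
        return np.zeros_like(values)
    dh = params.dh if params.dh is not None else hmax / params.n_steps
    n_steps = int(np.floor(hmax / dh + 1e-12))
    if n_steps < 1:
        return np.zeros_like(values)
    order = np.argsort(-values).astype(np.int64)
    indptr, indices = adjacency
    return _tfce_kernel(
        values, order, indptr.astype(np.int64), indices.astype(np.int64),
        float(params.E), float(params.H), float(dh), n_steps,
    )


# --------------------------------------------------------------------------
# GLM and permutation inference
# --------------------------------------------------------------------------

def _prepare_partition(outcome: np.ndarray, design: Design):
    """Residualize outcome and tested regressor against the nuisance design.

    Returns the pieces of the Freedman-Lane scheme: per-voxel residual-maker
    matrices R (V, n, n), residualized tested column x_tilde, its squared
    norm, outcome residuals, and the residual degrees of freedom.
    """
    y = np.asarray(outcome, dtype=np.float64)
    n, V = y.shape[1], y.shape[0]
    # outcome arrives as (n_subjects, V); convert to voxel-major
    if y.shape[0] == design.n_subjects and y.shape[1] == design.n_voxels:
        y = y.T  # (V, n)
        n, V = design.n_subjects, design.n_voxels
    else:
        raise ValueError("outcome must be (n_subjects, n_voxels)")
    k = design.scalar_covariates.shape[1]
    nuis_names = [m for m in design.voxelwise_regressors if m != design.contrast]
    pz = 1 + k + len(nuis_names)
    p_full = pz + 1
    if n < p_full + 1:
        raise ValueError(f"need at least {p_full + 1} subjects for {p_full} parameters")
    Z = np.empty((V, n, pz))
    Z[:, :, 0] = 1.0
    Z[:, :, 1 : 1 + k] = design.scalar_covariates[None, :, :]
    for j, m in enumerate(nuis_names):
        Z[:, :, 1 + k + j] = design.voxelwise_regressors[m].T
    x = design.voxelwise_regressors[design.contrast].T  # (V, n)

    pinvZ = np.linalg.pinv(Z)  # (V, pz, n)
    R = np.eye(n)[None, :, :] - np.einsum("vnp,vpm->vnm", Z, pinvZ)
    x_t = np.einsum("vnm,vm->vn", R, x)
    xx = np.einsum("vn,vn->v", x_t, x_t)
    # a tested column (numerically) inside the nuisance span is degenerate
    xnorm2 = np.einsum("vn,vn->v", x, x)
    xx = np.where(xx <= 1e-10 * np.maximum(xnorm2, np.finfo(float).tiny), 0.0, xx)
    e = np.einsum("vnm,vm->vn", R, y)
    df = n - p_full
    return {"R": R, "x_t": x_t, "xx": xx, "e": e, "df": df, "n": n, "V": V}


def _t_from_residuals(x_t, xx, e_res, df):
    """Contrast t statistic from residualized pieces; NaN where degenerate."""
    num = np.einsum("...vn,vn->...v", e_res, x_t) if e_res.ndim == 3 else np.einsum(
        "vn,vn->v", e_res, x_t
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = num / xx
        rss = (e_res**2).sum(axis=-1) - beta**2 * xx
        rss = np.maximum(rss, 0.0)
        t = beta / np.sqrt(rss / (df * xx))
    t = np.where(xx <= 0, np.nan, t)
    return t


def fit_glm_t(outcome: np.ndarray, design: Design) -> np.ndarray:
    """Per-voxel OLS t statistic for the tested voxel-dependent regressor.

    ``outcome`` is (n_subjects, n_voxels).  A perfect fit yields +/-inf; a
    rank-deficient tested column yields NaN (logged).
    """
    prep = _prepare_partition(outcome, design)
    t = _t_from_residuals(prep["x_t"], prep["xx"], prep["e"], prep["df"])
    t = t * design.contrast_sign
    n_nan = int(np.isnan(t).sum())
    if n_nan:
        logger.info("fit_glm_t: %d voxels with rank-deficient design", n_nan)
    return t


def permutation_inference(
    outcome: np.ndarray,
    design: Design,
    skeleton: Skeleton | tuple[np.ndarray, np.ndarray],
    tfce_params: TFCEParams = TFCEParams(),
    n_perm: int = 5000,
    seed: int = 0,
) -> StatResult:
    """Freedman-Lane permutation inference with TFCE and max-statistic FWE.

    The outcome residuals (after removing the nuisance design per voxel)
    are permuted across subjects with one shared permutation per iteration,
    the full model is refit, and each permuted t map is TFCE-enhanced in
    both directions.  p values use the (1 + exceedances) / (1 + n_perm)
    estimator; family-wise p values come from the null distribution of the
    permutation-wise maximum TFCE score.  Fully seeded and reproducible.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    adjacency = (
        skeleton_adjacency(skeleton, tfce_params.connectivity)
        if isinstance(skeleton, Skeleton)
        else skeleton
    )
    prep = _prepare_partition(outcome, design)
    x_t, xx, e, R, df, n = (
        prep["x_t"], prep["xx"], prep["e"], prep["R"], prep["df"], prep["n"],
    )
    t_obs = _t_from_residuals(x_t, xx, e, df) * design.contrast_sign
    t_obs = np.where(np.isfinite(t_obs), t_obs, 0.0)
    tf_pos = tfce(t_obs, adjacency, tfce_params)
    tf_neg = tfce(-t_obs, adjacency, tfce_params)

    V = t_obs.shape[0]
    cnt_pos = np.zeros(V, dtype=np.int64)
    cnt_neg = np.zeros(V, dtype=np.int64)
    max_pos = np.empty(n_perm)
    max_neg = np.empty(n_perm)

    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    block = max(1, int(2e7 // max(1, V * n)))
    for start in range(0, n_perm, block):
        P = perms[start : start + block]  # (b, n)
        Ep = e[:, P].transpose(1, 0, 2)  # (b, V, n)
        e_res = np.einsum("vnm,bvm->bvn", R, Ep)
        t_p = _t_from_residuals(x_t, xx, e_res, df) * design.contrast_sign
        t_p = np.where(np.isfinite(t_p), t_p, 0.0)
        for b in range(t_p.shape[0]):
            tp_pos = tfce(t_p[b], adjacency, tfce_params)
            tp_neg = tfce(-t_p[b], adjacency, tfce_params)
            cnt_pos += tp_pos >= tf_pos
            cnt_neg += tp_neg >= tf_neg
            max_pos[start + b] = tp_pos.max(initial=0.0)
            max_neg[start + b] = tp_neg.max(initial=0.0)

    p_unc_pos = (1.0 + cnt_pos) / (1.0 + n_perm)
    p_unc_neg = (1.0 + cnt_neg) / (1.0 + n_perm)
    p_fwe_pos = (1.0 + (max_pos[None, :] >= tf_pos[:, None]).sum(axis=1)) / (1.0 + n_perm)
    p_fwe_neg = (1.0 + (max_neg[None, :] >= tf_neg[:, None]).sum(axis=1)) / (1.0 + n_perm)
    return StatResult(
        tmap=t_obs,
        tfce_pos=tf_pos,
        tfce_neg=tf_neg,
        p_unc_pos=p_unc_pos,
        p_unc_neg=p_unc_neg,
        p_fwe_pos=p_fwe_pos,
        p_fwe_neg=p_fwe_neg,
        n_perm=n_perm,
        seed=seed,
        max_null_pos=max_pos,
        max_null_neg=max_neg,
    )


def threshold_and_split(
    result: StatResult,
    alpha: float = 0.05,
    corrected: bool = True,
) -> dict[str, np.ndarray]:
    """Boolean significance masks per contrast direction at level alpha."""
    if corrected:
        return {
            "positive": result.p_fwe_pos < alpha,
            "negative": result.p_fwe_neg < alpha,
        }
    return {
        "positive": result.p_unc_pos < alpha,
        "negative": result.p_unc_neg < alpha,
    }
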