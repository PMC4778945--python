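"""GLM t statistics, TFCE enhancement, and permutation inference."""

import numpy as np
import pytest
from scipy import ndimage, stats as sps

from wmperf.image import ImageVolume
from wmperf.skeleton import Skeleton
from wmperf.stats import (
    Design,
    TFCEParams,
    fit_glm_t,
    permutation_inference,
    skeleton_adjacency,
    tfce,
    threshold_and_split,
)


def random_skeleton(shape=(10, 10, 4), density=0.4, seed=0):
    rng = np.random.default_rng(seed)
    mask = rng.random(shape) < density
    vox = np.argwhere(mask)
    return Skeleton(
        mask=ImageVolume(mask.astype(float)),
        fa_threshold=0.3,
        voxels=vox,
        search_offsets=np.tile([[1, 0, 0]], (len(vox), 1)),
        search_dir=np.tile([[1.0, 0, 0]], (len(vox), 1)),
    )


def tfce_bruteforce(values, skeleton, params):
    """Independent reimplementation: label components at every threshold."""
    values = np.maximum(np.where(np.isfinite(values), values, 0.0), 0.0)
    hmax = values.max(initial=0.0)
    if hmax <= 0:
        return np.zeros_like(values)
    dh = params.dh if params.dh is not None else hmax / params.n_steps
    n_steps = int(np.floor(hmax / dh + 1e-12))
    vol = np.zeros(skeleton.mask.shape)
    vol[tuple(skeleton.voxels.T)] = values
    on = skeleton.mask.data.astype(bool)
    structure = np.ones((3, 3, 3))
    out = np.zeros_like(values)
    for k in range(1, n_steps + 1):
        h = k * dh
        supra = on & (vol >= h)
        lab, n_lab = ndimage.label(supra, structure=structure)
        if n_lab == 0:
            continue
        sizes = np.bincount(lab.ravel())
        lab_at = lab[tuple(skeleton.voxels.T)]
        active = lab_at > 0
        out[active] += sizes[lab_at[active]] ** params.E * h**params.H * dh
    return out


def simple_design(n, V, seed=0, k_scalar=2):
    rng = np.random.default_rng(seed)
    return Design(
        scalar_covariates=rng.normal(size=(n, k_scalar)),
        voxelwise_regressors={"cbf": rng.normal(size=(n, V))},
        contrast="cbf",
    )


class TestFitGLM:
    def test_matches_statsmodels_on_integer_toy(self):
        import statsmodels.api as sm

        # 6 subjects, intercept + 1 scalar + tested column, integer data
        scalar = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        cbf = np.array([[2.0], [4.0], [1.0], [7.0], [5.0], [3.0]])
        y = np.array([[3.0], [5.0], [2.0], [9.0], [8.0], [4.0]])
        design = Design(scalar_covariates=scalar,
                        voxelwise_regressors={"cbf": cbf}, contrast="cbf")
        t = fit_glm_t(y, design)
        X = sm.add_constant(np.column_stack([scalar - scalar.mean(),
                                             cbf - cbf.mean()]))
        ref = sm.OLS(y[:, 0], X).fit().tvalues[-1]
        assert abs(t[0] - ref) < 1e-10

    def test_matches_statsmodels_with_voxelwise_nuisance(self, rng):
        import statsmodels.api as sm

        n, V = 15, 8
        scalar = rng.normal(size=(n, 2))
        vox = {
            "cbf": rng.normal(size=(n, V)),
            "gm_pve": rng.normal(size=(n, V)),
        }
        y = rng.normal(size=(n, V))
        design = Design(scalar_covariates=scalar, voxelwise_regressors=vox,
                        contrast="cbf")
        t = fit_glm_t(y, design)
        for v in range(V):
            X = sm.add_constant(np.column_stack([
                scalar - scalar.mean(axis=0),
                vox["gm_pve"][:, v] - vox["gm_pve"][:, v].mean(),
                vox["cbf"][:, v] - vox["cbf"][:, v].mean(),
            ]))
            ref = sm.OLS(y[:, v], X).fit().tvalues[-1]
            assert abs(t[v] - ref) < 1e-10

    def test_perfect_fit_flags_infinite(self):
        n = 10
        rng = np.random.default_rng(0)
        cbf = rng.normal(size=(n, 1))
        y = 2.0 * cbf + 1.0
        design = Design(scalar_covariates=np.empty((n, 0)),
                        voxelwise_regressors={"cbf": cbf}, contrast="cbf")
        t = fit_glm_t(y, design)
        assert np.isinf(t[0]) and t[0] > 0

    def test_null_t_distribution_is_student(self, rng):
        n, V, k = 20, 3000, 2
        design = simple_design(n, V, seed=1, k_scalar=k)
        y = rng.normal(size=(n, V))
        t = fit_glm_t(y, design)
        df = n - (k + 2)  # intercept + scalars + tested column
        stat, p = sps.kstest(t, sps.t(df).cdf)
        assert p > 0.01

    def test_rank_deficient_contrast_is_nan(self):
        n = 8
        scalar = np.arange(n, dtype=float)[:, None]
        cbf = 2.0 * scalar  # collinear with the scalar covariate
        design = Design(scalar_covariates=scalar,
                        voxelwise_regressors={"cbf": cbf}, contrast="cbf")
        t = fit_glm_t(np.random.default_rng(0).normal(size=(n, 1)), design)
        assert np.isnan(t[0])

    def test_unknown_contrast_rejected(self):
        with pytest.raises(KeyError):
            Design(scalar_covariates=np.zeros((5, 1)),
                   voxelwise_regressors={"cbf": np.zeros((5, 2))},
                   contrast="flow")


class TestTFCE:
    def test_zero_map_enhances_to_zero(self):
        sk = random_skeleton()
        adj = skeleton_adjacency(sk)
        out = tfce(np.zeros(sk.n_voxels), adj)
        assert np.all(out == 0)

    def test_isolated_unit_voxel_integrates_to_one_third(self):
        sk = Skeleton(
            mask=ImageVolume(np.eye(3)[None, :, :]),
            fa_threshold=0.3,
            voxels=np.array([[0, 0, 0]]),
            search_offsets=np.array([[1, 0, 0]]),
            search_dir=np.array([[1.0, 0, 0]]),
        )
        sk.mask.data[:] = 0
        sk.mask.data[0, 0, 0] = 1
        adj = skeleton_adjacency(sk)
        out = tfce(np.array([1.0]), adj, TFCEParams(E=0.5, H=2.0, dh=0.01))
        assert abs(out[0] - 1.0 / 3.0) / (1.0 / 3.0) < 0.02

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_component_recomputation(self, seed):
        sk = random_skeleton(seed=seed)
        adj = skeleton_adjacency(sk)
        rng = np.random.default_rng(100 + seed)
        values = np.maximum(rng.normal(size=sk.n_voxels), 0.0) * 3.0
        params = TFCEParams()
        got = tfce(values, adj, params)
        want = tfce_bruteforce(values, sk, params)
        assert np.allclose(got, want, atol=1e-9)

    def test_monotone_in_voxel_height(self, rng):
        sk = random_skeleton(seed=3)
        adj = skeleton_adjacency(sk)
        base = np.maximum(rng.normal(size=sk.n_voxels), 0.0)
        params = TFCEParams(dh=0.02)  # fixed step so the grids align
        before = tfce(base, adj, params)
        for _ in range(5):
            bumped = base.copy()
            v = rng.integers(sk.n_voxels)
            bumped[v] += rng.uniform(0.1, 1.0)
            after = tfce(bumped, adj, params)
            assert np.all(after >= before - 1e-12)

    def test_connectivity_modes_differ_on_diagonal_pair(self):
        mask = np.zeros((2, 2, 1))
        mask[0, 0, 0] = mask[1, 1, 0] = 1
        sk = Skeleton(
            mask=ImageVolume(mask), fa_threshold=0.3,
            voxels=np.array([[0, 0, 0], [1, 1, 0]]),
            search_offsets=np.tile([[1, 0, 0]], (2, 1)),
            search_dir=np.tile([[1.0, 0, 0]], (2, 1)),
        )
        vals = np.array([1.0, 1.0])
        out26 = tfce(vals, skeleton_adjacency(sk, 26))
        out6 = tfce(vals, skeleton_adjacency(sk, 6))
        assert out26[0] > out6[0]  # diagonal neighbours only connect at 26


class TestPermutationInference:
    def _nulldata(self, n, V, seed):
        rng = np.random.default_rng(seed)
        sk = random_skeleton(shape=(6, 6, 3), density=0.5, seed=seed)
        V = sk.n_voxels
        design = Design(
            scalar_covariates=rng.normal(size=(n, 2)),
            voxelwise_regressors={"cbf": rng.normal(size=(n, V))},
            contrast="cbf",
        )
        y = rng.normal(size=(n, V))
        return y, design, sk

    def test_same_seed_bit_identical(self):
        y, design, sk = self._nulldata(12, None, 4)
        a = permutation_inference(y, design, sk, n_perm=150, seed=9)
        b = permutation_inference(y, design, sk, n_perm=150, seed=9)
        assert np.array_equal(a.p_unc_pos, b.p_unc_pos)
        assert np.array_equal(a.p_fwe_pos, b.p_fwe_pos)
        assert np.array_equal(a.tmap, b.tmap)

    def test_fwe_p_dominates_uncorrected_p(self):
        y, design, sk = self._nulldata(12, None, 5)
        res = permutation_inference(y, design, sk, n_perm=200, seed=1)
        assert np.all(res.p_fwe_pos >= res.p_unc_pos - 1e-12)
        assert np.all(res.p_fwe_neg >= res.p_unc_neg - 1e-12)

    def test_null_rejection_rates_are_calibrated(self):
        hits05 = []
        hits20 = []
        for rep in range(60):
            y, design, sk = self._nulldata(12, None, 1000 + rep)
            res = permutation_inference(y, design, sk, n_perm=500, seed=rep)
            hits05.append((res.p_unc_pos < 0.05).mean())
            hits20.append((res.p_unc_pos < 0.20).mean())
        assert abs(np.mean(hits05) - 0.05) < 0.02
        assert abs(np.mean(hits20) - 0.20) < 0.04

    def test_threshold_and_split_boundaries(self):
        y, design, sk = self._nulldata(12, None, 6)
        res = permutation_inference(y, design, sk, n_perm=150, seed=2)
        empty = threshold_and_split(res, alpha=0.0)
        assert not empty["positive"].any() and not empty["negative"].any()
        res.p_fwe_pos = np.full_like(res.p_fwe_pos, 0.049)
        full = threshold_and_split(res, alpha=0.05)
        assert full["positive"].all()
        corr = threshold_and_split(res, alpha=0.3, corrected=True)
        unc = threshold_and_split(res, alpha=0.3, corrected=False)
        assert np.all(unc["negative"] | ~corr["negative"])  # corrected subset

    def test_contrast_sign_flips_directions(self):
        y, design, sk = self._nulldata(14, None, 7)
        res_pos = permutation_inference(y, design, sk, n_perm=150, seed=3)
        design_neg = Design(
            scalar_covariates=design.scalar_covariates,
            voxelwise_regressors=design.voxelwise_regressors,
            contrast="cbf",
            contrast_sign=-1,
        )
        res_neg = permutation_inference(y, design_neg, sk, n_perm=150, seed=3)
        assert np.allclose(res_pos.tmap, -res_neg.tmap)
        assert np.array_equal(res_pos.p_unc_pos, res_neg.p_unc_neg)

    def test_demeaned_invariants_of_design(self):
        design = simple_design(10, 5, seed=2)
        assert np.allclose(design.scalar_covariates.sum(axis=0), 0, atol=1e-9)
        for mat in design.voxelwise_regressors.values():
            assert np.allclose(mat.sum(axis=0), 0, atol=1e-9)
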