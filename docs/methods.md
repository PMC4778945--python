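# Methods

This note documents the models implemented in `wmperf`, the defaults and
their units, what the synthetic cohorts do and do not emulate, and the
numerical choices made where the design was genuinely open.

## 1. Perfusion quantification

The ASL series alternates control and label volumes; perfusion is carried by
the pairwise difference ΔM = control − label (positive in perfused tissue).
The mean and unbiased variance of the n_pairs differences are computed per
voxel, and the mean ΔM is calibrated to absolute CBF with the
single-compartment kinetic model

    CBF = UNIT · λ·ΔM / (2·α·M0·T1b) · 1 / (e^(−ω_s/T1b) − e^(−(τ+ω_s)/T1b)),

where ω_s = ω + s·Δt_slice is the post-labeling delay seen by slice s, and
UNIT = 100 g × 60000 ms/min converts (ml g⁻¹ ms⁻¹) to ml/100g/min.

| symbol | meaning | default | unit |
|---|---|---|---|
| λ | blood–tissue partition coefficient | 0.9 | g/ml |
| α | labeling (inversion) efficiency | 0.85 | – |
| T1b | T1 of arterial blood at 3 T | 1650 | ms |
| τ | labeling (bolus) duration | 1720 | ms |
| ω | post-labeling delay at slice 0 | 1100 | ms |
| Δt_slice | per-slice acquisition delay | 45 | ms |
| M0 | equilibrium magnetization of arterial blood | calibrated | signal units |

At the defaults the dimensionless kinetic term
1/(e^(−1100/1650) − e^(−2820/1650)) evaluates to ≈ 3.00854. Tissue T1
(1084 ms for WM) and bolus arrival time (1300 ms) are carried as metadata
for extended kinetic models; the calibration equation itself does not use
them. M0 is estimated as the mean control-image signal over a CSF mask
times a configurable CSF→blood conversion factor (default 1; the synthetic
generator's control baseline makes this exact).

Negative ΔM produces negative CBF and is deliberately **not clipped**:
clipping would bias every downstream ROI mean in low-SNR tissue. The CBF
variance map is the delta-method propagation var(CBF) = K²·var(ΔM) of the
single-difference variance (K the per-voxel linear calibration factor);
per-voxel SNR is |CBF| divided by the standard error √(var(CBF)/n_pairs),
with zero-variance voxels flagged infinite and excluded from ROI averages.

The "reliable ASL signal" test is a one-sample sign-flipping permutation
test of mean(ΔM) > 0 per voxel (one shared flip vector per permutation,
default 1000 flips), reported as the fraction of mask voxels with p < α.

Motion is summarized as the mean relative displacement (MRD): for each
consecutive volume pair, the Euclidean norm of the six motion-parameter
increments with rotations converted to millimetres on a 50 mm sphere (a
standard head-radius convention); the MRD is the temporal mean. Subjects
whose PV-corrected grey-matter CBF falls strictly below 38 ml/100g/min are
excluded before group statistics.

## 2. Tissue masks and partial-volume correction

PVE maps are resolution-matched by block-mean aggregation (integer factors
only, mass-preserving) and binarized inclusively: GM ≥ 0.4, WM ≥ 0.7, and
CSF ≥ 0.9 for the calibration mask (the CSF cut is not a literature value;
it selects near-pure CSF in the phantom). Inclusive comparison at the
printed thresholds is a deliberate reading of "thresholded at".

PV correction uses the local linear-regression formulation: within a kernel
around each voxel, observed CBF ≈ pve_gm·CBF_gm + pve_wm·CBF_wm, solved by
least squares through the normal equations (computed with constant-kernel
convolutions, so the whole map costs five convolutions and a closed-form
2×2 solve). CSF is assumed non-perfused. Voxels whose local design is
rank-deficient (relative determinant ≤ 1e-10) are NaN and counted. The
module default kernel is 5×5×1 (in-plane, matching thick perfusion slices);
the *pipeline* default is 7×7×1 because the phantom tracts are 5 voxels
thick — a 5-wide kernel sits entirely inside a tract at its centre, exactly
where skeleton voxels live, and the two-tissue design degenerates there.

Two consequences worth knowing: the pipeline's QC tissue means are computed
on the PV-corrected maps (the raw GM-mask mean is diluted toward WM values
by partial volume and would mis-rank subjects against the 38 ml/100g/min
cut), and the voxel-dependent CBF regressor fed to the GLM is the corrected
WM-compartment map (falling back to raw CBF at rank-deficient voxels).
Because the local regression pools a neighbourhood, it also reduces the
voxel-level CBF noise roughly three-fold, which is what makes voxel-wise
cross-subject statistics informative at realistic ASL noise.

## 3. Skeletonization and projection

The cohort mean FA map is thresholded at 0.3 and thinned to a one-voxel
ridge. Per supra-threshold voxel a search direction is chosen:

- **slope voxels** — where the Gaussian-smoothed (σ = 1 voxel) FA changes by
  more than `grad_tol = 0.005` across one voxel step, the direction is the
  FA gradient. This removes the flanks of ridge profiles; without it, every
  voxel of a conical tube profile is maximal along its *tangential*
  curvature direction and the whole tube would survive;
- **ridge/plateau voxels** — otherwise, the eigenvector of the most negative
  eigenvalue of the smoothed-FA Hessian (the perpendicular of a ridge).

The direction is quantized to the nearest of the 13 undirected lattice
directions (in physical space, so anisotropic voxels are handled). A voxel
is kept iff its FA strictly exceeds the values just beyond the run of exact
FA ties along ± that direction *and* it is the centre voxel of the tied run
(lower index on even runs) — a deterministic centre-of-gravity tie-break
that reduces a uniform slab to its single mid-plane.

Projection searches ± the stored perpendicular up to `max_search_mm = 8`
(nearest position first, so an on-skeleton peak maps to itself) for the
subject's maximum FA; FA takes that maximum, and every companion map (CBF,
ASL variance, GM PVE, RD/MD/AD) is sampled at the *same* location — never at
its own maximum. The search cap and pre-smoothing are configuration values;
the reference scheme's halt-at-local-minimum refinement is intentionally
replaced by the fixed half-length.

`fill_skeleton` dilates skeleton statistics into spheres (default 3 mm,
nearest skeleton voxel wins) for display only.

## 4. Permutation GLM with TFCE

Per skeleton voxel the outcome (projected FA, MD, RD or AD) is regressed on
an intercept, demeaned scalar covariates (age, sex, number of ASL pairs,
MRD) and demeaned voxel-dependent regressors (CBF — tested; ASL variance
and GM PVE — nuisance). Inference is Freedman–Lane: the outcome is
residualized against the per-voxel nuisance design, residuals are permuted
across subjects (one shared permutation per iteration), the full model is
refit, and each permuted t map is TFCE-enhanced,

    TFCE(v) = Σ_h e(v,h)^E · h^H · dh,   h = dh, 2dh, …, h(v),

with E = 0.5, H = 2, dh = h_max/100 per enhanced map, and 26-connectivity
restricted to skeleton voxels (implemented as an incremental union-find over
descending thresholds, compiled with numba; an independent
label-per-threshold reimplementation serves as the test oracle). Both
one-sided directions are always computed. p values use the
(1 + exceedances)/(1 + n_perm) estimator — voxel-wise against each voxel's
own TFCE permutation distribution, family-wise against the distribution of
the permutation-wise maximum TFCE score. Everything is driven by one seed;
identical seeds give bit-identical maps. Default n_perm = 5000
(calibration experiments in the test-suite use 500).

Numerical edge cases: a tested column numerically inside the nuisance span
(relative residual norm ≤ 1e-10) gives t = NaN (logged, treated as 0 before
TFCE); a perfect fit gives ±inf.

## 5. ROI analyses

Per-label mean ± SD extraction skips NaN voxels and reports absent labels
with volume 0. Correlations are Pearson with the exact two-sided t
transform (R−2 df); zero-variance inputs return an explicit NaN flag.
The cluster report intersects a significance mask with every label and
lists only intersections **strictly greater than** 50 voxels, with mean ±
SD of each supplied map and mean/peak t — the tract-table schema. The
CBF column summarizes whichever CBF variant was projected (by default the
PV-corrected WM map; the table header in the run directory states this).

## 6. The synthetic cohort

**Geometry.** A grid ≥ 16 voxels per axis (2 mm default) holds a central
CSF ellipsoid, a 2-voxel GM shell, diffuse WM, and n disjoint tracts —
alternating slabs (5 voxels thick; ridge = mid-plane) and tubes (radius 2–3;
ridge = axis), axis-aligned, rejection-placed with a 1-voxel separation.
PVE compositions are piecewise constant (tract 0.95/0.04/0.01 WM/GM/CSF,
diffuse WM 0.88/0.09/0.03, shell 0.15/0.80/0.05, core 0.02/0.03/0.95) and
sum to 1 by construction.

**Diffusion.** Each voxel gets axially symmetric tensor eigenvalues
(AD, RD, RD) mixed across tissues by PVE; MD and FA are then *computed*
from the eigenvalues, never drawn. WM tract baselines AD = 1.03,
RD = 0.50 μm²/ms (FA ≈ 0.424 under axial symmetry); GM eigenvalues
(1.116, 0.687) chosen to give FA 0.29 at MD 0.83; CSF isotropic at
3.0 μm²/ms. Diffuse WM is assigned FA 0.25 — *below* the skeleton
threshold — so that only the coherent tracts carry a mean-FA ridge; real WM
would skeletonize throughout, but a controlled ridge geometry is what makes
skeleton tests exact. RD rises by 0.02 μm²/ms per voxel of distance from
the tract spine, creating the FA peak the skeletonization recovers.
Gaussian voxel texture (SD 0.005 μm²/ms) is added to both eigenvalues;
negatives are clipped (logged) and RD capped at AD.

**Coupling.** Each subject carries a latent standard-normal factor u. In
coupled tracts the regional CBF is mean + ρσu + σ√(1−ρ²)ε and the regional
FA is exactly FA_base + σ_FA·u, realized by inverting the FA formula for RD
at the subject's AD. The exact inversion (rather than a linearized RD
shift) matters: the AD draw otherwise adds FA variance uncorrelated with u
and the realized cross-subject correlation falls measurably short of the
requested ρ. Null tracts and diffuse WM receive independent draws of the
same magnitudes.

**ASL forward model.** The noiseless ΔM at each voxel inverts the
calibration equation at the voxel's true CBF (PVE-weighted GM/WM perfusion
plus N(0, 1) texture, CSF non-perfused) with the slice-specific delay;
control = M0 baseline, label = control − ΔM, i.i.d. Gaussian noise added to
every volume. The noise default (SD 8 on an M0 of 1000, i.e. 0.8 % of the
control signal) was set so that the per-voxel WM CBF SNR is ≈ 3 at 100
averaged pairs — the reported operating point of the emulated protocol —
and is deliberately not tuned per experiment.

**Covariates.** Ages Uniform(20, 46); sex Bernoulli(28/43 female); pair
counts drawn from {50, 100, 150, 200} with empirical frequencies
(6, 27, 1, 5)/39; motion traces are bounded Gaussian random walks (step SD
0.02 mm / 4·10⁻⁴ rad, reflected at ±1 mm). Optionally, the first
`n_low_gm_cbf` subjects are planted with GM CBF in 25–35 ml/100g/min to
exercise the QC exclusion; ordinary subjects' GM CBF is kept ≥ 39 so the
exclusion set is known by construction.

**What the phantom does not emulate.** Registration and motion *correction*
(motion enters only as a covariate trace), curved/crossing fibers, raw DWI
synthesis and tensor fitting, MR artifacts (ghosting, distortion, T2*
decay), arrival-time heterogeneity, background suppression. Passing tests
therefore validate the analysis machinery and its statistical calibration,
not the biology of any real cohort.

## 7. Problem sizes used by the test-suite and acceptance script

Calibration experiments run a complete-null cohort (n = 20 subjects,
32×32×16 grid, 4 tracts, n_perm = 500) over 200 replicates; power
experiments run injected coupling ρ = 0.8 (n = 39 subjects, 40×40×16 grid
so the coupled slab's skeleton comfortably exceeds the 50-voxel reporting
rule, n_perm = 500) over 50 replicates. Replicate studies pin the phantom
geometry (`anatomy_seed`) and vary only the cohort seed: tract placement is
rejection-sampled and a fresh geometry per replicate would occasionally
fail to place, aborting a replicate for reasons unrelated to the statistics
under test. The acceptance script uses the same conditions at reduced
replicate counts and records each quantity's problem size in its JSON
output.

## 8. Known limitations

- The skeleton's slope/ridge split leaves slab mid-planes slightly eroded
  at their in-plane borders (the edge gradient dominates there); tube-end
  voxels are similarly attenuated by smoothing.
- The two-compartment PV correction ignores CSF perfusion (zero by
  assumption) and extrapolates from nearly collinear tissue compositions;
  its variance depends strongly on the local PVE contrast.
- Permutation p values are discrete with resolution 1/(n_perm + 1); at
  n_perm = 500 the smallest attainable p is ≈ 0.002.
- The generator's regional coupling is injected at tract level with
  homogeneous texture; no voxel-scale spatial autocorrelation is modelled,
  so TFCE's behaviour under smooth noise fields is not exercised.
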