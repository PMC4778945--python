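# wmperf

**White-matter perfusion vs. diffusion microstructure: a fully synthetic-testable
pCASL + TBSS analysis pipeline.**

White-matter (WM) health depends on its blood supply, yet WM cerebral blood
flow (CBF) is hard to measure: pseudo-continuous arterial spin labeling
(pCASL) signal in WM is weak, slow-arriving, and heavily partial-volumed.
Studies linking WM perfusion to diffusion-tensor microstructure (fractional
anisotropy FA, radial/axial/mean diffusivity RD/AD/MD) therefore combine a
long chain of delicate steps — kinetic-model CBF calibration, tissue
partial-volume handling, skeleton-based spatial statistics, permutation
inference — none of which can be validated on the original cohort, because
such cohorts are rarely shared.

`wmperf` implements that chain as a reusable library **plus a forward
simulator that generates complete synthetic cohorts with known ground
truth**, so every stage is testable end to end without any data download:

- **`wmperf.synthetic`** — digital phantoms (CSF core, GM shell, straight WM
  tracts with a partial-volume decomposition), per-subject diffusion metric
  maps built from an axially symmetric tensor (AD, RD, RD), pCASL
  control/label series obtained by inverting the CBF equation at each
  voxel's true perfusion, and covariates. A per-subject latent factor
  injects a tunable cross-subject Pearson correlation `coupling_r` between
  regional FA and CBF in designated tracts.
- **`wmperf.asl`** — control−label difference maps, CSF-based M0
  calibration, and the single-compartment quantification

  ```
  CBF = (λ·ΔM) / (2·α·M0·T1b) · 1 / (e^(−ω_s/T1b) − e^(−(τ+ω_s)/T1b))
  ```

  with λ = 0.9 g/ml, α = 0.85, T1b = 1650 ms, τ = 1720 ms, ω = 1100 ms and a
  per-slice delay increment ω_s = ω + slice·Δt; plus delta-method CBF
  variance, SNR maps, a sign-flip test for "is the ASL difference reliably
  above zero", the mean-relative-displacement motion summary, and the
  low-GM-CBF (< 38 ml/100g/min) subject exclusion.
- **`wmperf.masks`** — block-mean PVE downsampling, binary masks at the
  standard thresholds (GM ≥ 0.4, WM ≥ 0.7), and local linear-regression
  partial-volume correction of CBF.
- **`wmperf.skeleton`** — mean-FA skeletonization (threshold 0.3,
  one-voxel ridge with per-voxel perpendicular search directions) and
  projection of FA and companion maps (CBF, variance, GM PVE) onto the
  skeleton, sampling companions at the subject's FA peak.
- **`wmperf.stats`** — voxel-wise OLS with scalar covariates (age, sex,
  number of pairs, motion) and voxel-dependent regressors (CBF tested; ASL
  variance and GM PVE as nuisance), Freedman–Lane permutation inference,
  threshold-free cluster enhancement (TFCE, E = 0.5, H = 2, 26-connectivity
  restricted to the skeleton), and max-statistic family-wise error control.
- **`wmperf.roi`** — per-label means, within-subject FA–CBF correlation
  across tracts, cross-subject regional correlations, and the cluster
  report listing labels whose significant intersection exceeds 50 voxels.
- **`wmperf.pipeline` / `wmperf` CLI** — one seeded config drives
  simulate → quantify → mask → skeletonize → stats → ROI, in memory or onto
  disk with a hash manifest (identical config + seed ⇒ identical hashes).

## Worked example

Simulate a 39-subject cohort in which regional FA and CBF are coupled at
r = 0.8 in tracts 1–2 and uncoupled in tracts 3–4, then run the whole
analysis:

```python
import numpy as np
from wmperf import PipelineConfig, StatsConfig, CohortConfig, run_cohort_analysis

config = PipelineConfig(
    grid_shape=(40, 40, 16), n_tracts=4, slab_frac=0.26,
    cohort=CohortConfig(n_subjects=39, coupling_r=0.8,
                        coupled_tracts=(1, 2), null_tracts=(3, 4)),
    stats=StatsConfig(n_perm=500, outcomes={"fa": 1}),
    seed=7, anatomy_seed=1,
)
ana = run_cohort_analysis(config)

res, lab = ana.results["fa"], ana.skeleton_labels
sig = res.p_fwe_pos < 0.05
print(f"skeleton voxels:            {ana.skeleton.n_voxels}")
print(f"subjects kept after QC:     {len(ana.kept_index)} / {len(ana.subjects)}")
print(f"WM CBF (PV-corrected mean): {ana.qc.wm_cbf.mean():.1f} ml/100g/min")
print(f"GM CBF (PV-corrected mean): {ana.qc.gm_cbf.mean():.1f} ml/100g/min")
print(f"FWE-significant voxels:     {int(sig.sum())} "
      f"(coupled tracts: {int((sig & np.isin(lab, [1, 2])).sum())}, "
      f"null tracts: {int((sig & np.isin(lab, [3, 4])).sum())})")
r, p = ana.cross_subject_r["fa_cbf"]
print(f"cross-subject FA-CBF r:     {r:.2f} (p = {p:.2g})")
print(ana.reports["fa"][["label", "location", "volume_voxels",
                         "cbf_mean", "fa_mean", "mean_t"]])
```

This prints:

```
skeleton voxels:            300
subjects kept after QC:     39 / 39
WM CBF (PV-corrected mean): 19.6 ml/100g/min
GM CBF (PV-corrected mean): 48.4 ml/100g/min
FWE-significant voxels:     138 (coupled tracts: 138, null tracts: 0)
cross-subject FA-CBF r:     0.79 (p = 3.2e-09)
   label  location  volume_voxels   cbf_mean   fa_mean    mean_t
0      1  tract_01            132  19.937944  0.401772  5.021668
```

Reading this: the quantification recovers the simulated tissue perfusion
levels (WM ≈ 19.7, GM ≈ 48.1 ml/100g/min); the permutation GLM finds
TFCE-FWE-significant positive FA–CBF association *only* inside the tracts
where coupling was injected; the recovered cross-subject correlation (0.79)
matches the injected 0.8; and the cluster report lists only the coupled
slab, whose significant intersection (132 voxels) clears the > 50-voxel
reporting rule — the uncoupled tracts are clean.

The same run from a shell:

```bash
wmperf run-all --config demo.yaml --out run_dir   # writes manifest.json + TSV reports
```

## Limitations

The simulator produces straight, axis-aligned tracts in a shared grid: no
registration, no curved or crossing fibers, no MR artifacts. Passing tests
demonstrate the correctness and calibration of the *analysis machinery*,
not the physiology of any real cohort. See `docs/methods.md` for the model,
parameter defaults, and numerical choices.
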