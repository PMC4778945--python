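"""End-to-end orchestration: simulate -> quantify -> mask -> skeleton -> stats -> ROI.

The in-memory chain (:func:`run_cohort_analysis`) executes every stage on a
synthetic cohort under one seeded configuration and returns all intermediate
products; :func:`run_pipeline` additionally persists every artifact (NIfTI
volumes, TSV tables, YAML config) into a run directory with a JSON manifest
of file hashes, so that identical config + seed reproduce identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .asl import (
    ASLKineticParams,
    calibrate_m0,
    cbf_variance,
    mean_relative_displacement,
    pairwise_differences,
    qc_exclude_low_gm_cbf,
    quantify_cbf,
    significant_signal,
    snr_map,
)
from .image import ImageVolume
from .masks import binarize_masks, pv_correct_cbf
from .roi import (
    cluster_report,
    cross_subject_region_correlation,
    report_to_frame,
    within_subject_tract_correlation,
)
from .skeleton import Skeleton, fill_skeleton, mean_fa, project_many, skeletonize
from .stats import Design, StatResult, TFCEParams, permutation_inference, threshold_and_split
from .synthetic import (
    CohortConfig,
    PhantomAnatomy,
    SubjectGroundTruth,
    build_true_cbf,
    covariate_table,
    make_asl_timeseries,
    make_cohort,
    make_diffusion_maps,
    make_phantom_anatomy,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StatsConfig",
    "PipelineConfig",
    "CohortAnalysis",
    "PipelineError",
    "run_cohort_analysis",
    "run_pipeline",
]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending context."""


@dataclass
class StatsConfig:
    """Permutation-GLM settings for the skeleton statistics stage."""

    n_perm: int = 5000
    alpha: float = 0.05
    tfce: TFCEParams = field(default_factory=TFCEParams)
    #: outcome metrics and the hypothesized association sign with CBF
    outcomes: dict[str, int] = field(default_factory=lambda: {"fa": 1, "rd": -1})
    max_search_mm: float = 8.0
    #: permutations for the per-subject raw-signal significance test
    sig_n_perm: int = 200


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end run, aggregated and serializable."""

    grid_shape: tuple[int, int, int] = (32, 32, 16)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_tracts: int = 4
    slab_frac: float = 0.20
    kinetic: ASLKineticParams = field(default_factory=ASLKineticParams)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    gm_threshold: float = 0.4
    wm_threshold: float = 0.7
    csf_threshold: float = 0.9
    fa_threshold: float = 0.3
    gm_cbf_exclude: float = 38.0
    #: use the PV-corrected WM CBF map (not the raw mixture CBF) as the
    #: voxel-dependent regressor, as in the emulated analysis
    pv_correct: bool = True
    #: PV-correction kernel; 7 in-plane voxels so the local design still
    #: spans a tissue boundary at the centre of a 5-voxel-thick tract
    pv_kernel: tuple[int, int, int] = (7, 7, 1)
    compute_sig_masks: bool = False
    seed: int = 0
    #: pin the phantom geometry across replicate cohorts (None: derive from seed)
    anatomy_seed: int | None = None

    # ------------------------------------------------------------ serialization
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "kinetic" in d and isinstance(d["kinetic"], dict):
            d["kinetic"] = ASLKineticParams(**d["kinetic"])
        if "cohort" in d and isinstance(d["cohort"], dict):
            c = dict(d["cohort"])
            for key in ("coupled_tracts", "null_tracts", "n_pairs_choices",
                        "n_pairs_weights", "age_range"):
                if key in c and c[key] is not None:
                    c[key] = tuple(c[key])
            d["cohort"] = CohortConfig(**c)
        if "stats" in d and isinstance(d["stats"], dict):
            s = dict(d["stats"])
            if "tfce" in s and isinstance(s["tfce"], dict):
                s["tfce"] = TFCEParams(**s["tfce"])
            d["stats"] = StatsConfig(**s)
        for key in ("grid_shape", "voxel_size_mm", "pv_kernel"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"config file not found: {p}")
        return cls.from_dict(yaml.safe_load(p.read_text()))


#: stage order of the pipeline; partial runs stop after the named stage
STAGES = ("simulate", "quantify", "masks", "skeleton", "stats", "roi")


@dataclass
class CohortAnalysis:
    """Everything the in-memory pipeline produces (up to the requested stage)."""

    config: PipelineConfig
    anatomy: PhantomAnatomy
    subjects: list[SubjectGroundTruth]
    truth: pd.DataFrame
    covariates: pd.DataFrame          # all simulated subjects
    qc: pd.DataFrame | None = None    # per-subject QC summary with excluded flag
    kept_index: list[int] = field(default_factory=list)
    masks: object | None = None
    skeleton: Skeleton | None = None
    skeleton_labels: np.ndarray | None = None
    skeleton_data: dict[str, np.ndarray] = field(default_factory=dict)
    results: dict[str, StatResult] = field(default_factory=dict)
    reports: dict[str, pd.DataFrame] = field(default_factory=dict)
    within_subject_r: pd.DataFrame | None = None
    cross_subject_r: dict[str, tuple[float, float]] = field(default_factory=dict)
    perfusion: list[dict] = field(default_factory=list)


def _derive_seeds(seed: int, n: int) -> list[int]:
    """Stable per-stage integer seeds (< 2^31) from one top-level seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def quantify_subject(
    anatomy: PhantomAnatomy,
    subject: SubjectGroundTruth,
    kinetic: ASLKineticParams,
    cohort: CohortConfig,
    csf_mask: np.ndarray,
    compute_sig: bool = False,
    sig_n_perm: int = 200,
    sig_mask_roi: np.ndarray | None = None,
) -> dict:
    """Forward-simulate one subject's ASL series and quantify it to CBF."""
    ts = make_asl_timeseries(anatomy, subject, kinetic, cohort)
    delta_m, delta_m_var, n_pairs = pairwise_differences(ts)
    mean_control = ImageVolume(ts.volumes[..., 0::2].mean(axis=3), ts.voxel_size_mm)
    m0_blood = calibrate_m0(mean_control, csf_mask, 1.0 / cohort.control_scale)
    slice_map = ts.slice_index_map()
    params = replace(kinetic, slice_time_increment_ms=cohort.slice_time_increment_ms)
    cbf = quantify_cbf(delta_m, m0_blood, params, slice_map)
    cbf_var = cbf_variance(delta_m_var, n_pairs, m0_blood, params, slice_map)
    snr = snr_map(cbf, cbf_var, n_pairs)
    out = {
        "ts": ts,
        "delta_m": delta_m,
        "delta_m_var": delta_m_var,
        "m0_blood": m0_blood,
        "cbf": cbf,
        "cbf_var": cbf_var,
        "snr": snr,
        "n_pairs": n_pairs,
        "mrd": mean_relative_displacement(ts.motion_trace),
    }
    if compute_sig:
        roi = sig_mask_roi if sig_mask_roi is not None else np.ones(anatomy.grid_shape, bool)
        sig_mask, frac = significant_signal(
            ts, roi, alpha=0.05, n_perm=sig_n_perm, seed=subject.seed
        )
        out["sig_mask"] = sig_mask
        out["sig_fraction"] = frac
    return out


def run_cohort_analysis(
    config: PipelineConfig,
    keep_timeseries: bool = False,
    upto: str = "roi",
) -> CohortAnalysis:
    """Execute the analysis chain in memory on a synthetic cohort.

    ``upto`` names the last stage to run (one of ``STAGES``); later fields
    of the returned :class:`CohortAnalysis` stay empty.
    """
    if upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}; choose from {STAGES}")
    upto_i = STAGES.index(upto)
    seeds = _derive_seeds(config.seed, 3)
    try:
        anatomy = make_phantom_anatomy(
            config.grid_shape, config.voxel_size_mm, config.n_tracts,
            seed=seeds[0] if config.anatomy_seed is None else config.anatomy_seed,
            slab_frac=config.slab_frac,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage simulate/anatomy failed: {exc}") from exc

    cohort = replace(config.cohort, seed=seeds[1])
    try:
        subjects, truth = make_cohort(anatomy, cohort)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage simulate/cohort failed: {exc}") from exc
    covariates = covariate_table(subjects)
    ana = CohortAnalysis(
        config=config, anatomy=anatomy, subjects=subjects, truth=truth,
        covariates=covariates,
    )
    if upto_i < 1:
        return ana

    masks = binarize_masks(
        anatomy.pve_gm, anatomy.pve_wm, anatomy.pve_csf,
        config.gm_threshold, config.wm_threshold, config.csf_threshold,
    )
    gm_mask = masks.gm_mask.data.astype(bool)
    wm_mask = masks.wm_mask.data.astype(bool)
    csf_mask = masks.csf_mask.data.astype(bool)

    # ---- quantification + QC -------------------------------------------------
    perfusion: list[dict] = []
    qc_rows = []
    for subj in subjects:
        try:
            make_diffusion_maps(anatomy, subj, cohort)
            build_true_cbf(anatomy, subj, cohort)
            q = quantify_subject(
                anatomy, subj, config.kinetic, cohort, csf_mask,
                compute_sig=config.compute_sig_masks,
                sig_n_perm=config.stats.sig_n_perm,
                sig_mask_roi=wm_mask | gm_mask,
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(
                f"stage quantify failed for {subj.subject_id}: {exc}"
            ) from exc
        if not keep_timeseries:
            q.pop("ts")
        # QC tissue means on PV-corrected CBF: the raw GM-mask mean is
        # diluted by the WM partial volume and would mis-rank subjects
        cbf_gm_vol, cbf_wm_vol = pv_correct_cbf(
            q["cbf"], anatomy.pve_gm, anatomy.pve_wm, config.pv_kernel
        )
        q["cbf_gm"], q["cbf_wm"] = cbf_gm_vol, cbf_wm_vol
        perfusion.append(q)
        with np.errstate(invalid="ignore"):
            qc_rows.append(
                {
                    "subject_id": subj.subject_id,
                    "gm_cbf": float(np.nanmean(cbf_gm_vol.data[gm_mask])),
                    "wm_cbf": float(np.nanmean(cbf_wm_vol.data[wm_mask])),
                    "mrd": q["mrd"],
                }
            )
    qc = pd.DataFrame(qc_rows)
    kept_ids, excluded_ids = qc_exclude_low_gm_cbf(
        dict(zip(qc["subject_id"], qc["gm_cbf"])), config.gm_cbf_exclude
    )
    qc["excluded"] = qc["subject_id"].isin(excluded_ids)
    kept_index = [i for i, s in enumerate(subjects) if s.subject_id in set(kept_ids)]
    if len(kept_index) < 3:
        raise PipelineError("stage qc failed: fewer than 3 subjects survive exclusion")
    ana.perfusion = perfusion
    ana.qc = qc
    ana.kept_index = kept_index
    ana.masks = masks
    if upto_i < 3:
        return ana

    # ---- skeletonization + projection ---------------------------------------
    try:
        fa_maps = [make_fa_lookup(subjects[i]) for i in kept_index]
        mfa = mean_fa(fa_maps)
        skel = skeletonize(
            mfa, config.fa_threshold, max_search_mm=config.stats.max_search_mm
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage skeleton failed: {exc}") from exc
    if skel.n_voxels == 0:
        raise PipelineError("stage skeleton failed: empty skeleton")
    skeleton_labels = anatomy.tract_labels.data.astype(int)[tuple(skel.voxels.T)]

    names = ["rd", "md", "ad", "cbf", "cbf_var", "gm_pve"]
    data: dict[str, list[np.ndarray]] = {"fa": []} | {n: [] for n in names}
    n_nan_filled = 0
    for row, i in enumerate(kept_index):
        subj = subjects[i]
        q = perfusion[i]
        if config.pv_correct:
            corrected = q["cbf_wm"].data
            raw = q["cbf"].data
            bad = np.isnan(corrected)
            n_nan_filled += int(bad.sum())
            cbf_map = q["cbf"].copy_with(np.where(bad, raw, corrected))
        else:
            cbf_map = q["cbf"]
        others = {
            "rd": subj.true_rd,
            "md": ImageVolume(
                (subj.true_ad.data + 2 * subj.true_rd.data) / 3.0, anatomy.voxel_size_mm
            ),
            "ad": subj.true_ad,
            "cbf": cbf_map,
            "cbf_var": q["cbf_var"],
            "gm_pve": anatomy.pve_gm,
        }
        proj = project_many(make_fa_lookup(subj), others, skel)
        for nm, vals in proj.items():
            data[nm].append(vals)
    if n_nan_filled:
        logger.info(
            "skeleton projection: %d rank-deficient PV-corrected voxels fell "
            "back to uncorrected CBF", n_nan_filled,
        )
    skeleton_data = {nm: np.stack(v) for nm, v in data.items()}
    ana.skeleton = skel
    ana.skeleton_labels = skeleton_labels
    ana.skeleton_data = skeleton_data
    if upto_i < 4:
        return ana

    # ---- permutation GLM ------------------------------------------------------
    cov_kept = covariates.iloc[kept_index]
    qc_kept = qc.iloc[kept_index]
    scalar = np.column_stack(
        [
            cov_kept["age"].to_numpy(float),
            (cov_kept["sex"] == "F").to_numpy(float),
            cov_kept["n_pairs"].to_numpy(float),
            qc_kept["mrd"].to_numpy(float),
        ]
    )
    results: dict[str, StatResult] = {}
    reports: dict[str, pd.DataFrame] = {}
    stat_seed = seeds[2]
    for outcome, sign in config.stats.outcomes.items():
        design = Design(
            scalar_covariates=scalar,
            voxelwise_regressors={
                "cbf": skeleton_data["cbf"],
                "cbf_var": skeleton_data["cbf_var"],
                "gm_pve": skeleton_data["gm_pve"],
            },
            contrast="cbf",
            contrast_sign=sign,
        )
        try:
            res = permutation_inference(
                skeleton_data[outcome], design, skel, config.stats.tfce,
                n_perm=config.stats.n_perm, seed=stat_seed,
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage stats failed for outcome {outcome}: {exc}") from exc
        results[outcome] = res
        sig = threshold_and_split(res, config.stats.alpha, corrected=True)["positive"]
        sig_vol = skel.values_to_volume(sig.astype(float)).data.astype(bool)
        mean_maps = {
            "cbf": skel.values_to_volume(skeleton_data["cbf"].mean(axis=0)),
            outcome: skel.values_to_volume(skeleton_data[outcome].mean(axis=0)),
        }
        rep = cluster_report(
            sig_vol,
            anatomy.tract_labels,
            mean_maps,
            skel.values_to_volume(res.tmap),
            label_names={i + 1: n for i, n in enumerate(anatomy.label_names)},
        )
        reports[outcome] = report_to_frame(rep)
    ana.results = results
    ana.reports = reports
    if upto_i < 5:
        return ana

    # ---- ROI correlations -----------------------------------------------------
    ws_rows = []
    labels_present = sorted(set(skeleton_labels) - {0})
    for row, i in enumerate(kept_index):
        fa_m = [skeleton_data["fa"][row][skeleton_labels == l].mean() for l in labels_present]
        cbf_m = [skeleton_data["cbf"][row][skeleton_labels == l].mean() for l in labels_present]
        if len(labels_present) >= 3:
            r, p = within_subject_tract_correlation(np.array(fa_m), np.array(cbf_m))
        else:
            r, p = np.nan, np.nan
        ws_rows.append({"subject_id": subjects[i].subject_id, "r": r, "p": p})
    within_subject_r = pd.DataFrame(ws_rows)

    cross: dict[str, tuple[float, float]] = {}
    sig_pos = threshold_and_split(results[next(iter(results))], config.stats.alpha)["positive"]
    region = sig_pos if sig_pos.sum() >= 1 else np.ones(skel.n_voxels, bool)
    fa_subj = skeleton_data["fa"][:, region].mean(axis=1)
    cbf_subj = skeleton_data["cbf"][:, region].mean(axis=1)
    if len(kept_index) >= 3:
        cross["fa_cbf"] = cross_subject_region_correlation(fa_subj, cbf_subj)
        for metric in ("rd", "md", "ad"):
            vals = skeleton_data[metric][:, region].mean(axis=1)
            cross[f"fa_{metric}"] = cross_subject_region_correlation(fa_subj, vals)

    ana.within_subject_r = within_subject_r
    ana.cross_subject_r = cross
    return ana


def make_fa_lookup(subject: SubjectGroundTruth) -> ImageVolume:
    """Subject FA map computed from the stored eigenvalue maps."""
    from .synthetic import fa_from_axial_radial

    if subject.true_ad is None or subject.true_rd is None:
        raise PipelineError(f"diffusion maps missing for {subject.subject_id}")
    return subject.true_ad.copy_with(
        fa_from_axial_radial(subject.true_ad.data, subject.true_rd.data)
    )


# --------------------------------------------------------------------------
# disk-run wrapper with manifest
# --------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir, upto: str = "roi") -> Path:
    """Run the analysis up to a stage and persist artifacts plus a manifest.

    Identical config + seed produce identical manifest hashes.  Returns the
    path to ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ana = run_cohort_analysis(config, upto=upto)
    files: list[tuple[str, Path]] = []

    config.to_yaml(out / "config.yaml")
    files.append(("config", out / "config.yaml"))

    anat_dir = out / "anatomy"
    ana.anatomy.save(anat_dir)
    for f in sorted(anat_dir.iterdir()):
        files.append(("simulate", f))

    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    ana.truth.to_csv(truth_dir / "ground_truth.tsv", sep="\t", index=False)
    ana.covariates.to_csv(truth_dir / "covariates.tsv", sep="\t", index=False)
    files += [("simulate", truth_dir / "ground_truth.tsv"),
              ("simulate", truth_dir / "covariates.tsv")]

    if ana.qc is None:
        return _write_manifest(out, config, files)

    if ana.masks is not None:
        mask_dir = out / "masks"
        mask_dir.mkdir(exist_ok=True)
        for name, vol in (
            ("gm_mask", ana.masks.gm_mask),
            ("wm_mask", ana.masks.wm_mask),
            ("csf_mask", ana.masks.csf_mask),
        ):
            vol.save(mask_dir / f"{name}.nii.gz")
            files.append(("masks", mask_dir / f"{name}.nii.gz"))

    perf_dir = out / "perfusion"
    for subj, q in zip(ana.subjects, ana.perfusion):
        sdir = perf_dir / subj.subject_id
        sdir.mkdir(parents=True, exist_ok=True)
        for name in ("cbf", "cbf_var", "snr"):
            q[name].save(sdir / f"{name}.nii.gz")
            files.append(("quantify", sdir / f"{name}.nii.gz"))
        if subj.true_ad is not None and subj.true_rd is not None:
            fa_vol = make_fa_lookup(subj)
            md_vol = subj.true_ad.copy_with(
                (subj.true_ad.data + 2 * subj.true_rd.data) / 3.0
            )
            for name, vol in (("fa", fa_vol), ("md", md_vol),
                              ("ad", subj.true_ad), ("rd", subj.true_rd)):
                vol.save(sdir / f"{name}.nii.gz")
                files.append(("simulate", sdir / f"{name}.nii.gz"))
        if "sig_mask" in q:
            q["sig_mask"].save(sdir / "sig_mask.nii.gz")
            files.append(("quantify", sdir / "sig_mask.nii.gz"))
        if subj.motion_trace is not None:
            np.savetxt(sdir / "motion.txt", subj.motion_trace, fmt="%.8f")
            files.append(("quantify", sdir / "motion.txt"))
    qc_path = out / "qc_summary.tsv"
    ana.qc.to_csv(qc_path, sep="\t", index=False)
    files.append(("qc", qc_path))

    if ana.skeleton is None:
        return _write_manifest(out, config, files)

    skel_dir = out / "skeleton"
    skel_dir.mkdir(exist_ok=True)
    ana.skeleton.mask.save(skel_dir / "skeleton_mask.nii.gz")
    files.append(("skeleton", skel_dir / "skeleton_mask.nii.gz"))
    dir_vol = np.zeros(ana.skeleton.mask.shape + (3,))
    dir_vol[tuple(ana.skeleton.voxels.T)] = ana.skeleton.search_dir
    import nibabel as nib

    affine = np.diag(list(ana.skeleton.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(dir_vol, affine), str(skel_dir / "search_dir.nii.gz"))
    files.append(("skeleton", skel_dir / "search_dir.nii.gz"))
    vox_df = pd.DataFrame(ana.skeleton.voxels, columns=["i", "j", "k"])
    vox_df["tract_label"] = ana.skeleton_labels
    vox_df.to_csv(skel_dir / "skeleton_voxels.tsv", sep="\t", index=False)
    files.append(("skeleton", skel_dir / "skeleton_voxels.tsv"))
    import gzip

    for name, mat in ana.skeleton_data.items():
        p = skel_dir / f"data_{name}.tsv.gz"
        text = pd.DataFrame(mat).to_csv(sep="\t", index=False, float_format="%.10g")
        # mtime=0 keeps the gzip byte stream reproducible across reruns
        with gzip.GzipFile(p, "wb", mtime=0) as fh:
            fh.write(text.encode())
        files.append(("skeleton", p))

    if not ana.results:
        return _write_manifest(out, config, files)

    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    for outcome, res in ana.results.items():
        for stem, vals in (
            ("tstat", res.tmap),
            ("tfce_pos", res.tfce_pos),
            ("p_fwe_pos", res.p_fwe_pos),
            ("p_unc_pos", res.p_unc_pos),
            ("p_fwe_neg", res.p_fwe_neg),
        ):
            p = stats_dir / f"{outcome}_{stem}.nii.gz"
            ana.skeleton.values_to_volume(vals).save(p)
            files.append(("stats", p))
        filled = fill_skeleton(1.0 - res.p_fwe_pos, ana.skeleton, radius_mm=3.0)
        p = stats_dir / f"{outcome}_display_fill.nii.gz"
        filled.save(p)
        files.append(("stats", p))

    roi_dir = out / "roi"
    roi_dir.mkdir(exist_ok=True)
    for outcome, rep in ana.reports.items():
        p = roi_dir / f"cluster_report_{outcome}.tsv"
        rep.to_csv(p, sep="\t", index=False)
        files.append(("roi", p))
    if ana.within_subject_r is not None:
        ana.within_subject_r.to_csv(roi_dir / "within_subject_r.tsv", sep="\t", index=False)
        files.append(("roi", roi_dir / "within_subject_r.tsv"))
        cross_df = pd.DataFrame(
            [{"pair": k, "r": v[0], "p": v[1]} for k, v in ana.cross_subject_r.items()]
        )
        cross_df.to_csv(roi_dir / "cross_subject_r.tsv", sep="\t", index=False)
        files.append(("roi", roi_dir / "cross_subject_r.tsv"))
    return _write_manifest(out, config, files)


def _write_manifest(out: Path, config: PipelineConfig, files) -> Path:
    manifest = {
        "seed": config.seed,
        "n_subjects": config.cohort.n_subjects,
        "files": [
            {"path": str(p.relative_to(out)), "stage": stage, "sha256": _sha256(p)}
            for stage, p in files
        ],
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path
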