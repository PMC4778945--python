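"""Synthetic cohorts with known ground truth for the full perfusion pipeline.

Everything the analysis consumes is forward-modelled here: a digital phantom
anatomy (CSF core, GM shell, straight white-matter "tracts" of differing
orientation with a partial-volume decomposition), per-subject diffusion
metric maps built from an axially symmetric tensor (AD, RD, RD), pCASL
control/label time series obtained by algebraically inverting the CBF
calibration equation at each voxel's true perfusion, and a covariate table.

The statistical structure is controlled: a standard-normal latent factor per
subject drives both the regional fractional anisotropy (through radial
diffusivity) and the regional CBF of designated "coupled" tracts, so that the
expected cross-subject Pearson correlation between regional FA and CBF
equals ``coupling_r`` by construction; "null" tracts receive independent
draws.  Default levels follow a healthy young-adult cohort at 3 T: WM/GM CBF
19.7 / 48.1 ml/100g/min (between-subject SD 2.7 / 8.9), WM AD 1.03 and RD
0.50 um^2/ms (FA 0.42 under axial symmetry), GM eigenvalues chosen to give
FA 0.29 at MD 0.83.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .asl import ASLKineticParams, ASLTimeSeries, UNIT_SCALE, kinetic_factor
from .image import ImageVolume

logger = logging.getLogger(__name__)

__all__ = [
    "PhantomAnatomy",
    "PhantomPlacementError",
    "SubjectGroundTruth",
    "CohortConfig",
    "make_phantom_anatomy",
    "make_cohort",
    "make_diffusion_maps",
    "build_true_cbf",
    "make_asl_timeseries",
    "fa_from_axial_radial",
    "md_from_axial_radial",
    "covariate_table",
]

# free-water diffusivity used for the CSF compartment, um^2/ms
_AD_CSF = 3.0
_RD_CSF = 3.0
# GM axially-symmetric eigenvalues giving FA ~= 0.29 at MD ~= 0.83 um^2/ms
_AD_GM = 1.116
_RD_GM = 0.687


class PhantomPlacementError(RuntimeError):
    """The requested number of disjoint tracts does not fit the grid."""


# --------------------------------------------------------------------------
# tensor-metric helpers (axially symmetric tensor with eigenvalues AD, RD, RD)
# --------------------------------------------------------------------------

def md_from_axial_radial(ad, rd):
    """Mean diffusivity of an axially symmetric tensor: (AD + 2 RD) / 3."""
    return (np.asarray(ad) + 2.0 * np.asarray(rd)) / 3.0


def fa_from_axial_radial(ad, rd):
    """Fractional anisotropy of eigenvalues (AD, RD, RD).

    FA = (AD - RD) / sqrt(AD^2 + 2 RD^2) for AD >= RD; 0 where the tensor
    vanishes.
    """
    ad = np.asarray(ad, dtype=np.float64)
    rd = np.asarray(rd, dtype=np.float64)
    denom = np.sqrt(ad**2 + 2.0 * rd**2)
    out = np.zeros(np.broadcast_shapes(ad.shape, rd.shape))
    with np.errstate(divide="ignore", invalid="ignore"):
        np.divide(ad - rd, denom, out=out, where=denom > 0)
    return out


def rd_for_target_fa(ad: float, fa: float) -> float:
    """The RD giving fractional anisotropy ``fa`` at axial diffusivity ``ad``.

    Exact inversion of FA = (AD - RD)/sqrt(AD^2 + 2 RD^2); valid for
    0 <= fa < 1/sqrt(2) (the axially symmetric prolate regime).
    """
    if not (0.0 <= fa < 1.0 / np.sqrt(2.0)):
        raise ValueError(f"target FA {fa} outside the prolate range [0, 1/sqrt(2))")
    if fa == 0.0:
        return float(ad)
    return float(ad * (1.0 - fa * np.sqrt(3.0 - 2.0 * fa**2)) / (1.0 - 2.0 * fa**2))


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class PhantomAnatomy:
    """Digital head phantom: PVE decomposition plus labelled WM tracts."""

    grid_shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    pve_gm: ImageVolume
    pve_wm: ImageVolume
    pve_csf: ImageVolume
    tract_labels: ImageVolume
    label_names: list[str]
    #: per-voxel distance (voxels) to the spine of its tract; +inf outside
    spine_distance: ImageVolume | None = None
    #: per-tract principal orientation axis (0/1/2) and kind ("tube"/"slab")
    tract_axes: list[int] = field(default_factory=list)
    tract_kinds: list[str] = field(default_factory=list)

    @property
    def n_tracts(self) -> int:
        return len(self.label_names)

    def validate(self, atol: float = 1e-9) -> None:
        total = self.pve_gm.data + self.pve_wm.data + self.pve_csf.data
        if not np.allclose(total, 1.0, atol=atol):
            raise AssertionError("PVE fractions do not sum to 1 everywhere")
        labels = self.tract_labels.data.astype(int)
        present = np.unique(labels)
        expected = np.arange(0, self.n_tracts + 1)
        if not np.array_equal(present, expected):
            raise AssertionError(f"tract labels {present} are not contiguous 0..{self.n_tracts}")
        if np.any(self.pve_wm.data[labels > 0] < 0.7):
            raise AssertionError("a labelled tract voxel has pve_wm < 0.7")

    def save(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.pve_gm.save(out / "pve_gm.nii.gz")
        self.pve_wm.save(out / "pve_wm.nii.gz")
        self.pve_csf.save(out / "pve_csf.nii.gz")
        self.tract_labels.save(out / "tract_labels.nii.gz")
        pd.DataFrame(
            {"label": np.arange(1, self.n_tracts + 1), "name": self.label_names}
        ).to_csv(out / "label_names.tsv", sep="\t", index=False)


@dataclass
class SubjectGroundTruth:
    """One simulated subject: covariates, latent factor, regional truths."""

    subject_id: str
    age: float
    sex: str  # "F" or "M"
    n_pairs: int
    latent_u: float
    #: diffuse (non-tract) WM and GM CBF, ml/100g/min
    wm_cbf: float
    gm_cbf: float
    #: global WM eigenvalue baselines, um^2/ms
    ad_wm: float
    rd_wm: float
    #: per-tract regional truths, keyed by tract label
    tract_cbf: dict[int, float] = field(default_factory=dict)
    tract_rd_shift: dict[int, float] = field(default_factory=dict)
    motion_trace: np.ndarray | None = None
    #: voxelwise ground-truth perfusion, built on demand
    true_cbf: ImageVolume | None = None
    true_ad: ImageVolume | None = None
    true_rd: ImageVolume | None = None
    seed: int = 0


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults encode the emulated study: 43 subjects (28 women), ages 20-46,
    control/label pair counts 50/100/150/200 with empirical frequencies
    6/27/1/5, reference WM and GM CBF and diffusion-metric levels, and additive
    Gaussian ASL noise whose default (8 signal units on an M0 of 1000)
    yields a per-voxel WM CBF SNR of about 3 at 100 averaged pairs.
    """

    n_subjects: int = 43
    coupling_r: float = 0.0
    coupled_tracts: tuple[int, ...] = ()
    null_tracts: tuple[int, ...] = ()
    mean_cbf_wm: float = 19.7
    mean_cbf_gm: float = 48.1
    sd_cbf_between: float = 2.7
    sd_cbf_gm_between: float = 8.9
    mean_ad_wm: float = 1.03
    mean_rd_wm: float = 0.50
    sd_ad_between: float = 0.03
    sd_fa_between: float = 0.02
    #: FA of diffuse (non-tract) WM — below the skeleton threshold so that
    #: only the coherent tracts carry a mean-FA ridge
    fa_diffuse_wm: float = 0.25
    noise_sd_asl: float = 8.0
    cbf_texture_sd: float = 1.0
    dti_texture_sd: float = 0.005
    #: deterministic RD rise per voxel of distance from the tract spine,
    #: um^2/ms; creates the FA ridge the skeletonization recovers
    rd_edge_rise: float = 0.02
    slice_time_increment_ms: float = 45.0
    m0_blood: float = 1000.0
    control_scale: float = 1.0
    n_pairs_choices: tuple[int, ...] = (50, 100, 150, 200)
    n_pairs_weights: tuple[float, ...] = (6.0, 27.0, 1.0, 5.0)
    age_range: tuple[float, float] = (20.0, 46.0)
    p_female: float = 28.0 / 43.0
    motion_step_sd_mm: float = 0.02
    motion_step_sd_rad: float = 4e-4
    motion_bound_mm: float = 1.0
    #: number of planted low-GM-CBF subjects (for QC-exclusion testing)
    n_low_gm_cbf: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (-1.0 <= self.coupling_r <= 1.0):
            raise ValueError("coupling_r must lie in [-1, 1]")
        if set(self.coupled_tracts) & set(self.null_tracts):
            raise ValueError("coupled_tracts and null_tracts must be disjoint")
        for name in (
            "sd_cbf_between",
            "sd_cbf_gm_between",
            "sd_ad_between",
            "sd_fa_between",
            "noise_sd_asl",
            "cbf_texture_sd",
            "dti_texture_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.m0_blood <= 0:
            raise ValueError("m0_blood must be positive")


# --------------------------------------------------------------------------
# phantom anatomy
# --------------------------------------------------------------------------

def make_phantom_anatomy(
    grid_shape: tuple[int, int, int],
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
    n_tracts: int = 4,
    seed: int = 0,
    max_attempts: int = 500,
    slab_frac: float = 0.20,
) -> PhantomAnatomy:
    """Build a phantom with a CSF core, a GM shell and disjoint WM tracts.

    Tracts alternate between slabs (a thick plate whose FA ridge is a
    mid-plane) and tubes (whose ridge is the axis line), cycling through the
    three grid axes.  Placement is rejection-sampled; if ``n_tracts``
    disjoint tracts cannot be placed, a :class:`PhantomPlacementError` is
    raised.  Fully deterministic for a fixed seed.
    """
    shape = tuple(int(s) for s in grid_shape)
    if len(shape) != 3 or any(s < 16 for s in shape):
        raise ValueError(f"grid_shape must be 3 axes of >= 16 voxels, got {shape}")
    if n_tracts < 2:
        raise ValueError("n_tracts must be >= 2")
    rng = np.random.default_rng(seed)
    nx, ny, nz = shape
    idx = np.indices(shape)

    # CSF core: central ellipsoid with semi-axes ~ 1/10 of each dimension
    center = (np.array(shape) - 1) / 2.0
    semi = np.maximum(np.array(shape) / 10.0, 1.5)
    csf_core = (((idx[0] - center[0]) / semi[0]) ** 2
                + ((idx[1] - center[1]) / semi[1]) ** 2
                + ((idx[2] - center[2]) / semi[2]) ** 2) <= 1.0

    # GM shell: outermost 2 voxels on every face
    shell = np.zeros(shape, dtype=bool)
    for ax, n in enumerate(shape):
        coord = idx[ax]
        shell |= (coord < 2) | (coord >= n - 2)
    shell &= ~csf_core

    # region where tracts may live: away from shell, core and a 1-voxel buffer
    margin = 3
    interior = np.ones(shape, dtype=bool)
    for ax, n in enumerate(shape):
        coord = idx[ax]
        interior &= (coord >= margin) & (coord < n - margin)
    from scipy.ndimage import binary_dilation

    forbidden = binary_dilation(csf_core, iterations=1)
    allowed = interior & ~forbidden

    labels = np.zeros(shape, dtype=np.int32)
    spine = np.full(shape, np.inf)
    occupied = np.zeros(shape, dtype=bool)
    tract_axes: list[int] = []
    tract_kinds: list[str] = []

    for t in range(n_tracts):
        kind = "slab" if t % 2 == 0 else "tube"
        placed = False
        for _ in range(max_attempts):
            axis = int(rng.integers(0, 3))
            others = [a for a in range(3) if a != axis]
            if kind == "slab":
                half = 2  # thickness 5 voxels
                lo = margin + half
                hi = shape[axis] - margin - half
                if hi <= lo:
                    continue
                c = int(rng.integers(lo, hi))
                # in-plane half-extent ~ slab_frac of each in-plane axis
                ext = {}
                ok = True
                for a in others:
                    e = max(3, int(round(slab_frac * shape[a])))
                    lo_a = margin
                    hi_a = shape[a] - margin - 2 * e
                    if hi_a < lo_a:
                        ok = False
                        break
                    s = int(rng.integers(lo_a, hi_a + 1))
                    ext[a] = (s, s + 2 * e + 1)
                if not ok:
                    continue
                region = np.abs(idx[axis] - c) <= half
                for a, (s, e) in ext.items():
                    region &= (idx[a] >= s) & (idx[a] < e)
                dist = np.abs(idx[axis] - c).astype(float)
            else:
                radius = int(rng.integers(2, 4))
                cs = []
                ok = True
                for a in others:
                    lo_a = margin + radius
                    hi_a = shape[a] - margin - radius
                    if hi_a <= lo_a:
                        ok = False
                        break
                    cs.append(int(rng.integers(lo_a, hi_a)))
                if not ok:
                    continue
                length = max(8, int(round(0.5 * shape[axis])))
                if shape[axis] - 2 * margin <= length:
                    start = margin
                    length = shape[axis] - 2 * margin
                else:
                    start = int(rng.integers(margin, shape[axis] - margin - length + 1))
                r2 = sum((idx[a] - c) ** 2 for a, c in zip(others, cs))
                region = r2 <= radius**2
                region &= (idx[axis] >= start) & (idx[axis] < start + length)
                dist = np.sqrt(r2.astype(float))

            if not region.any():
                continue
            if not allowed[region].all():
                continue
            grown = binary_dilation(region, iterations=1)
            if (occupied & grown).any():
                continue
            labels[region] = t + 1
            spine[region] = dist[region]
            occupied |= grown
            tract_axes.append(axis)
            tract_kinds.append(kind)
            placed = True
            break
        if not placed:
            raise PhantomPlacementError(
                f"could not place tract {t + 1}/{n_tracts} on grid {shape} "
                f"after {max_attempts} attempts"
            )

    # PVE composition; sums to 1 by construction
    pve_gm = np.full(shape, 0.09)
    pve_wm = np.full(shape, 0.88)
    pve_csf = np.full(shape, 0.03)
    pve_gm[shell], pve_wm[shell], pve_csf[shell] = 0.80, 0.15, 0.05
    pve_gm[csf_core], pve_wm[csf_core], pve_csf[csf_core] = 0.03, 0.02, 0.95
    tract_mask = labels > 0
    pve_gm[tract_mask], pve_wm[tract_mask], pve_csf[tract_mask] = 0.04, 0.95, 0.01

    vs = tuple(float(v) for v in voxel_size_mm)
    anat = PhantomAnatomy(
        grid_shape=shape,
        voxel_size_mm=vs,
        pve_gm=ImageVolume(pve_gm, vs),
        pve_wm=ImageVolume(pve_wm, vs),
        pve_csf=ImageVolume(pve_csf, vs),
        tract_labels=ImageVolume(labels.astype(np.float64), vs),
        label_names=[f"tract_{i + 1:02d}" for i in range(n_tracts)],
        spine_distance=ImageVolume(spine, vs),
        tract_axes=tract_axes,
        tract_kinds=tract_kinds,
    )
    anat.validate()
    return anat


# --------------------------------------------------------------------------
# cohort draws
# --------------------------------------------------------------------------

def make_cohort(
    anatomy: PhantomAnatomy,
    cohort: CohortConfig,
) -> tuple[list[SubjectGroundTruth], pd.DataFrame]:
    """Draw a cohort of subjects with controlled FA-CBF coupling.

    In coupled tracts, regional CBF is mean + rho*sigma*u + sigma*
    sqrt(1-rho^2)*eps with the same latent u shifting regional FA (through
    RD), so the expected cross-subject correlation of regional FA and CBF
    equals ``coupling_r``.  Null tracts get independent draws.  Returns the
    subject list and a tidy ground-truth table (one row per subject x tract)
    for test use.
    """
    if cohort.n_subjects < 3:
        raise ValueError("n_subjects must be >= 3 (correlations undefined below)")
    known = set(range(1, anatomy.n_tracts + 1))
    for lbl in list(cohort.coupled_tracts) + list(cohort.null_tracts):
        if lbl not in known:
            raise ValueError(f"tract label {lbl} not present in anatomy")
    rho = cohort.coupling_r
    ss = np.random.SeedSequence(cohort.seed)
    subject_seeds = ss.spawn(cohort.n_subjects)
    rng = np.random.default_rng(ss.spawn(1)[0])

    weights = np.asarray(cohort.n_pairs_weights, dtype=float)
    weights = weights / weights.sum()
    low_ids = set(range(cohort.n_low_gm_cbf))

    subjects: list[SubjectGroundTruth] = []
    rows = []
    for i in range(cohort.n_subjects):
        srng = np.random.default_rng(subject_seeds[i])
        u = float(srng.standard_normal())
        age = float(srng.uniform(*cohort.age_range))
        sex = "F" if srng.random() < cohort.p_female else "M"
        n_pairs = int(srng.choice(cohort.n_pairs_choices, p=weights))
        wm_cbf = cohort.mean_cbf_wm + cohort.sd_cbf_between * float(srng.standard_normal())
        if i in low_ids:
            gm_cbf = float(srng.uniform(25.0, 35.0))  # below the 38 QC threshold
        else:
            gm_cbf = cohort.mean_cbf_gm + cohort.sd_cbf_gm_between * float(
                srng.standard_normal()
            )
            gm_cbf = max(gm_cbf, 39.0)  # non-planted subjects stay above QC
        ad_wm = cohort.mean_ad_wm + cohort.sd_ad_between * float(srng.standard_normal())
        fa_bg = cohort.fa_diffuse_wm + cohort.sd_fa_between * float(srng.standard_normal())
        rd_diffuse = rd_for_target_fa(ad_wm, max(fa_bg, 0.0))

        # Regional FA is made *exactly* linear in the shared factor by
        # inverting the FA formula at the subject's AD, so the AD draw does
        # not dilute the injected FA-CBF correlation.
        fa_base = float(fa_from_axial_radial(cohort.mean_ad_wm, cohort.mean_rd_wm))
        tract_cbf: dict[int, float] = {}
        tract_rd_shift: dict[int, float] = {}
        for lbl in range(1, anatomy.n_tracts + 1):
            eps = float(srng.standard_normal())
            if lbl in cohort.coupled_tracts:
                cbf_t = cohort.mean_cbf_wm + cohort.sd_cbf_between * (
                    rho * u + np.sqrt(max(0.0, 1.0 - rho**2)) * eps
                )
                fa_t = fa_base + cohort.sd_fa_between * u
            else:
                cbf_t = cohort.mean_cbf_wm + cohort.sd_cbf_between * eps
                fa_t = fa_base + cohort.sd_fa_between * float(srng.standard_normal())
            rd_shift = rd_for_target_fa(ad_wm, fa_t) - cohort.mean_rd_wm
            tract_cbf[lbl] = float(cbf_t)
            tract_rd_shift[lbl] = float(rd_shift)

        # bounded random walk for the 6 motion parameters
        steps = srng.normal(
            scale=[cohort.motion_step_sd_mm] * 3 + [cohort.motion_step_sd_rad] * 3,
            size=(2 * n_pairs, 6),
        )
        steps[0] = 0.0
        trace = np.cumsum(steps, axis=0)
        b = cohort.motion_bound_mm
        trace[:, :3] = np.clip(trace[:, :3], -b, b)

        subj_seed = int(subject_seeds[i].generate_state(1)[0] % (2**31))
        subj = SubjectGroundTruth(
            subject_id=f"sub-{i + 1:03d}",
            age=age,
            sex=sex,
            n_pairs=n_pairs,
            latent_u=u,
            wm_cbf=wm_cbf,
            gm_cbf=gm_cbf,
            ad_wm=ad_wm,
            rd_wm=rd_diffuse,
            tract_cbf=tract_cbf,
            tract_rd_shift=tract_rd_shift,
            motion_trace=trace,
            seed=subj_seed,
        )
        subjects.append(subj)
        for lbl in range(1, anatomy.n_tracts + 1):
            rd_t = cohort.mean_rd_wm + tract_rd_shift[lbl]
            rows.append(
                {
                    "subject_id": subj.subject_id,
                    "label": lbl,
                    "latent_u": u,
                    "true_cbf": tract_cbf[lbl],
                    "true_fa": float(fa_from_axial_radial(ad_wm, rd_t)),
                    "coupled": lbl in cohort.coupled_tracts,
                }
            )
    return subjects, pd.DataFrame(rows)


def covariate_table(subjects: list[SubjectGroundTruth]) -> pd.DataFrame:
    """Covariate TSV schema: subject_id, age, sex, n_pairs, mrd."""
    from .asl import mean_relative_displacement

    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "age": [s.age for s in subjects],
            "sex": [s.sex for s in subjects],
            "n_pairs": [s.n_pairs for s in subjects],
            "mrd": [
                mean_relative_displacement(s.motion_trace)
                if s.motion_trace is not None
                else 0.0
                for s in subjects
            ],
        }
    )


# --------------------------------------------------------------------------
# per-subject maps
# --------------------------------------------------------------------------

def _tissue_eigen_fields(
    anatomy: PhantomAnatomy,
    subject: SubjectGroundTruth,
    cohort: CohortConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free per-voxel AD and RD for one subject (PVE-mixed)."""
    labels = anatomy.tract_labels.data.astype(int)
    ad_wm_local = np.full(anatomy.grid_shape, subject.ad_wm)
    rd_wm_local = np.full(anatomy.grid_shape, subject.rd_wm)
    spine = anatomy.spine_distance.data if anatomy.spine_distance is not None else None
    for lbl, rd_shift in subject.tract_rd_shift.items():
        m = labels == lbl
        rd_wm_local[m] = cohort.mean_rd_wm + rd_shift
        if spine is not None:
            rd_wm_local[m] += cohort.rd_edge_rise * spine[m]
    gm, wm, csf = anatomy.pve_gm.data, anatomy.pve_wm.data, anatomy.pve_csf.data
    ad = wm * ad_wm_local + gm * _AD_GM + csf * _AD_CSF
    rd = wm * rd_wm_local + gm * _RD_GM + csf * _RD_CSF
    return ad, rd


def make_diffusion_maps(
    anatomy: PhantomAnatomy,
    subject: SubjectGroundTruth,
    cohort: CohortConfig,
    seed: int | None = None,
) -> dict[str, ImageVolume]:
    """Subject FA/MD/AD/RD maps from axially symmetric tensor eigenvalues.

    AD and RD are drawn per tissue and tract (the subject's latent factor
    shifts FA in coupled tracts via RD), Gaussian voxel texture is added,
    negative eigenvalues are clipped to zero (logged), and MD and FA are
    *computed* from (AD, RD, RD) — never drawn independently.
    """
    ad, rd = _tissue_eigen_fields(anatomy, subject, cohort)
    rng = np.random.default_rng(subject.seed if seed is None else seed)
    if cohort.dti_texture_sd > 0:
        ad = ad + rng.normal(scale=cohort.dti_texture_sd, size=ad.shape)
        rd = rd + rng.normal(scale=cohort.dti_texture_sd, size=rd.shape)
    n_neg = int((ad < 0).sum() + (rd < 0).sum())
    if n_neg:
        logger.info("make_diffusion_maps: clipped %d negative eigenvalues", n_neg)
    ad = np.maximum(ad, 0.0)
    rd = np.clip(rd, 0.0, ad)  # axial symmetry requires AD >= RD >= 0
    vs = anatomy.voxel_size_mm
    maps = {
        "ad": ImageVolume(ad, vs),
        "rd": ImageVolume(rd, vs),
        "md": ImageVolume(md_from_axial_radial(ad, rd), vs),
        "fa": ImageVolume(fa_from_axial_radial(ad, rd), vs),
    }
    subject.true_ad, subject.true_rd = maps["ad"], maps["rd"]
    return maps


def build_true_cbf(
    anatomy: PhantomAnatomy,
    subject: SubjectGroundTruth,
    cohort: CohortConfig,
    seed: int | None = None,
) -> ImageVolume:
    """Voxelwise ground-truth perfusion: PVE-weighted GM/WM CBF + texture.

    CSF contributes zero perfusion.  Gaussian voxel texture of SD
    ``cbf_texture_sd`` is superimposed and the result clipped at zero.
    """
    labels = anatomy.tract_labels.data.astype(int)
    cbf_wm_local = np.full(anatomy.grid_shape, subject.wm_cbf)
    for lbl, cbf_t in subject.tract_cbf.items():
        cbf_wm_local[labels == lbl] = cbf_t
    cbf = anatomy.pve_wm.data * cbf_wm_local + anatomy.pve_gm.data * subject.gm_cbf
    rng = np.random.default_rng(
        (subject.seed + 0x5EED) % (2**31) if seed is None else seed
    )
    if cohort.cbf_texture_sd > 0:
        cbf = cbf + rng.normal(scale=cohort.cbf_texture_sd, size=cbf.shape)
    cbf = np.maximum(cbf, 0.0)
    vol = ImageVolume(cbf, anatomy.voxel_size_mm)
    subject.true_cbf = vol
    return vol


def make_asl_timeseries(
    anatomy: PhantomAnatomy,
    subject: SubjectGroundTruth,
    params: ASLKineticParams,
    cohort: CohortConfig,
    seed: int | None = None,
) -> ASLTimeSeries:
    """Forward-model a pCASL control/label series from true perfusion.

    The noiseless ΔM at each voxel inverts the CBF calibration equation at
    that voxel's true CBF with the slice-specific post-labeling delay
    (slices along axis 2).  Control volumes are the M0-proportional
    baseline, label = control − ΔM, and i.i.d. Gaussian noise of SD
    ``noise_sd_asl`` is added to every volume.  Volume order alternates
    control, label, control, label, ...
    """
    if cohort.m0_blood <= 0:
        raise ValueError("m0_blood must be positive")
    if subject.true_cbf is None:
        build_true_cbf(anatomy, subject, cohort)
    cbf = subject.true_cbf.data
    slice_axis = 2
    shape = anatomy.grid_shape
    idx = np.arange(shape[slice_axis])
    slice_map = np.broadcast_to(idx[None, None, :], shape)
    params = replace(params, slice_time_increment_ms=cohort.slice_time_increment_ms)
    kin = kinetic_factor(params, slice_map)
    # invert CBF = UNIT_SCALE * lambda * dM / (2 alpha M0 T1b) * kin
    dm = (
        cbf
        * (2.0 * params.alpha * cohort.m0_blood * params.t1_blood_ms)
        / (UNIT_SCALE * params.lambda_bt)
        / kin
    )
    baseline = cohort.control_scale * cohort.m0_blood
    n_vol = 2 * subject.n_pairs
    rng = np.random.default_rng(
        (subject.seed + 0xA51) % (2**31) if seed is None else seed
    )
    volumes = np.empty(shape + (n_vol,), dtype=np.float64)
    volumes[..., 0::2] = baseline
    volumes[..., 1::2] = (baseline - dm)[..., None]
    if cohort.noise_sd_asl > 0:
        volumes += rng.normal(scale=cohort.noise_sd_asl, size=volumes.shape)
    trace = subject.motion_trace
    if trace is None or trace.shape[0] != n_vol:
        trace = np.zeros((n_vol, 6))
    return ASLTimeSeries(
        volumes=volumes,
        voxel_size_mm=anatomy.voxel_size_mm,
        slice_axis=slice_axis,
        motion_trace=trace,
    )
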