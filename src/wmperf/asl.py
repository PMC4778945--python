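"""pCASL perfusion quantification and subject-level QC.

Implements the single-compartment kinetic calibration of control-minus-label
difference images into cerebral blood flow in absolute units (ml/100g/min),

    CBF = (lambda * dM) / (2 * alpha * M0 * T1b)
          * 1 / (exp(-w_s/T1b) - exp(-(tau + w_s)/T1b)) * UNIT_SCALE

where ``w_s`` is the post-labeling delay seen by slice *s* (the nominal PLD
plus a per-slice acquisition-delay increment), ``tau`` the labeling duration
and ``T1b`` the longitudinal relaxation time of arterial blood.  The module
also provides a delta-method CBF variance map, per-voxel and ROI SNR, a
sign-flipping one-sample test for "is the ASL difference signal reliably
above zero", the mean-relative-displacement motion summary, and the
low-GM-CBF subject exclusion rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .image import ImageVolume

logger = logging.getLogger(__name__)

__all__ = [
    "ASLKineticParams",
    "ASLTimeSeries",
    "PerfusionResult",
    "pairwise_differences",
    "calibrate_m0",
    "kinetic_factor",
    "cbf_scale",
    "quantify_cbf",
    "cbf_variance",
    "snr_map",
    "roi_snr",
    "significant_signal",
    "mean_relative_displacement",
    "qc_exclude_low_gm_cbf",
]

#: converts lambda[ml/g] * dM/M0 / T1b[ms] into ml / 100 g / min
UNIT_SCALE = 100.0 * 60000.0


@dataclass(frozen=True)
class ASLKineticParams:
    """All symbols of the CBF calibration equation plus tissue metadata.

    Defaults are the acquisition/quantification constants of a 3 T pCASL
    protocol: blood-tissue partition coefficient λ = 0.9 g/ml, inversion
    efficiency α = 0.85, T1 of arterial blood 1650 ms, labeling duration
    τ = 1720 ms, post-labeling delay ω = 1100 ms at the first slice.
    ``t1_wm_ms`` (1084 ms) and ``bat_ms`` (1300 ms) are carried as metadata
    for extended kinetic models; the calibration equation itself does not
    use them.  ``slice_time_increment_ms`` is the per-slice readout delay
    added to ω; it is acquisition software dependent and must be configured.
    """

    lambda_bt: float = 0.9
    alpha: float = 0.85
    t1_blood_ms: float = 1650.0
    tau_ms: float = 1720.0
    omega_ms: float = 1100.0
    slice_time_increment_ms: float = 45.0
    t1_wm_ms: float = 1084.0
    bat_ms: float = 1300.0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.lambda_bt <= 0:
            raise ValueError("lambda_bt must be positive")
        for name in ("t1_blood_ms", "tau_ms", "omega_ms", "t1_wm_ms", "bat_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.slice_time_increment_ms < 0:
            raise ValueError("slice_time_increment_ms must be non-negative")


@dataclass
class ASLTimeSeries:
    """Alternating control/label 4-D series with slice and motion metadata.

    ``volumes`` is (x, y, z, 2*n_pairs), time-ordered as control, label,
    control, label, ...  ``motion_trace`` holds one 6-vector per volume:
    three translations (mm) and three rotations (rad).
    """

    volumes: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    slice_axis: int = 2
    motion_trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=np.float64)
        if self.volumes.ndim != 4:
            raise ValueError("ASLTimeSeries requires a 4-D array")
        if self.volumes.shape[3] % 2 != 0 or self.volumes.shape[3] < 2:
            raise ValueError("number of volumes must be an even count >= 2")
        if self.slice_axis not in (0, 1, 2):
            raise ValueError("slice_axis must be 0, 1 or 2")
        if self.motion_trace is not None:
            self.motion_trace = np.asarray(self.motion_trace, dtype=np.float64)
            if self.motion_trace.shape != (self.volumes.shape[3], 6):
                raise ValueError("motion_trace must be (n_volumes, 6)")

    @property
    def n_pairs(self) -> int:
        return self.volumes.shape[3] // 2

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.volumes.shape[:3]

    def slice_index_map(self) -> np.ndarray:
        """Integer volume giving each voxel's slice index along slice_axis."""
        shape = self.grid_shape
        idx = np.arange(shape[self.slice_axis])
        expand = [None, None, None]
        expand[self.slice_axis] = slice(None)
        return np.broadcast_to(idx[tuple(expand)], shape).copy()


@dataclass
class PerfusionResult:
    """Per-subject perfusion maps: ΔM, CBF, variance, SNR, significance."""

    delta_m: ImageVolume
    delta_m_var: ImageVolume
    cbf: ImageVolume
    cbf_var: ImageVolume
    snr: ImageVolume
    sig_mask: ImageVolume | None = None
    n_pairs: int = 0


# --------------------------------------------------------------------------
# difference maps and calibration
# --------------------------------------------------------------------------

def pairwise_differences(ts: ASLTimeSeries) -> tuple[ImageVolume, ImageVolume, int]:
    """Mean and unbiased variance of the control−label pairwise differences.

    The sign convention is control − label, positive in perfused tissue.
    """
    n = ts.n_pairs
    control = ts.volumes[..., 0::2]
    label = ts.volumes[..., 1::2]
    diffs = control - label
    mean = diffs.mean(axis=3)
    if n < 2:
        raise ValueError("variance of pairwise differences requires n_pairs >= 2")
    var = diffs.var(axis=3, ddof=1)
    vox = ts.voxel_size_mm
    return ImageVolume(mean, vox), ImageVolume(var, vox), n


def calibrate_m0(
    m0_csf_map: ImageVolume,
    csf_mask: ImageVolume | np.ndarray,
    conversion_factor: float = 1.0,
) -> float:
    """Equilibrium magnetization of arterial blood from the CSF signal.

    M0_blood = mean(M0 over CSF mask) * conversion_factor.  The CSF→blood
    conversion (relative proton density / T2* weighting) is a single
    configurable factor; with synthetic data the generator's stored M0 is
    recovered at the default factor of 1.
    """
    mask = np.asarray(csf_mask.data if isinstance(csf_mask, ImageVolume) else csf_mask)
    mask = mask.astype(bool)
    if mask.sum() == 0:
        raise ValueError("CSF mask is empty; cannot calibrate M0")
    m0 = float(np.mean(np.asarray(m0_csf_map.data)[mask])) * float(conversion_factor)
    if m0 <= 0:
        raise ValueError(f"calibrated M0_blood must be positive, got {m0}")
    return m0


# --------------------------------------------------------------------------
# quantification
# --------------------------------------------------------------------------

def kinetic_factor(params: ASLKineticParams, slice_index=0) -> np.ndarray | float:
    """The dimensionless kinetic term 1 / (e^{-w/T1b} - e^{-(tau+w)/T1b}).

    ``slice_index`` may be a scalar or an integer map; the effective
    post-labeling delay is w_s = omega + slice_index * slice_time_increment.
    Strictly positive and increasing in w for all positive durations.
    """
    t1b = params.t1_blood_ms
    w = params.omega_ms + np.asarray(slice_index, dtype=np.float64) * params.slice_time_increment_ms
    denom = np.exp(-w / t1b) - np.exp(-(params.tau_ms + w) / t1b)
    if np.any(denom <= 0):
        raise ValueError("degenerate kinetic denominator; check tau/omega/T1b")
    out = 1.0 / denom
    return float(out) if out.ndim == 0 else out


def cbf_scale(params: ASLKineticParams, m0_blood: float, slice_index=0):
    """Per-voxel linear factor K with CBF = K * dM, in (ml/100g/min) per signal unit."""
    if m0_blood <= 0:
        raise ValueError("m0_blood must be positive")
    base = UNIT_SCALE * params.lambda_bt / (2.0 * params.alpha * m0_blood * params.t1_blood_ms)
    return base * kinetic_factor(params, slice_index)


def quantify_cbf(
    delta_m: ImageVolume,
    m0_blood: float,
    params: ASLKineticParams,
    slice_index_map: np.ndarray | None = None,
    slice_axis: int = 2,
) -> ImageVolume:
    """Calibrate a mean ΔM map into CBF in ml/100g/min.

    Negative ΔM yields negative CBF: values are deliberately not clipped, so
    that downstream ROI means remain unbiased under noise.
    """
    if slice_index_map is None:
        shape = delta_m.shape
        idx = np.arange(shape[slice_axis])
        expand = [None, None, None]
        expand[slice_axis] = slice(None)
        slice_index_map = np.broadcast_to(idx[tuple(expand)], shape)
    scale = cbf_scale(params, m0_blood, slice_index_map)
    return delta_m.copy_with(scale * delta_m.data)


def cbf_variance(
    delta_m_var: ImageVolume,
    n_pairs: int,
    m0_blood: float,
    params: ASLKineticParams,
    slice_index_map: np.ndarray | None = None,
    slice_axis: int = 2,
) -> ImageVolume:
    """Delta-method variance map: var(CBF) = K^2 var(dM).

    ``delta_m_var`` is the variance of a *single* pairwise difference (as
    produced by :func:`pairwise_differences`); the returned map keeps that
    convention — the SNR computation divides by sqrt(n_pairs) separately.
    """
    if np.any(delta_m_var.data < 0):
        raise ValueError("delta_m_var contains negative values")
    if slice_index_map is None:
        shape = delta_m_var.shape
        idx = np.arange(shape[slice_axis])
        expand = [None, None, None]
        expand[slice_axis] = slice(None)
        slice_index_map = np.broadcast_to(idx[tuple(expand)], shape)
    scale = cbf_scale(params, m0_blood, slice_index_map)
    return delta_m_var.copy_with(scale**2 * delta_m_var.data)


def snr_map(cbf: ImageVolume, cbf_var: ImageVolume, n_pairs: int) -> ImageVolume:
    """Per-voxel SNR: |CBF| / (sqrt(var CBF) / sqrt(n_pairs)).

    The noise level is the standard error of the mean CBF over the averaged
    pairs.  Voxels with zero variance but non-zero CBF become +inf (flagged
    and excluded from ROI averages); 0/0 voxels are defined as 0.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    cbf.check_grid(cbf_var, "snr_map")
    noise = np.sqrt(cbf_var.data) / np.sqrt(n_pairs)
    signal = np.abs(cbf.data)
    out = np.zeros_like(signal, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        np.divide(signal, noise, out=out, where=noise > 0)
    inf_voxels = (noise == 0) & (signal > 0)
    if inf_voxels.any():
        logger.info("snr_map: %d voxels with zero variance flagged infinite", inf_voxels.sum())
        out[inf_voxels] = np.inf
    return cbf.copy_with(out)


def roi_snr(snr: ImageVolume, mask: ImageVolume | np.ndarray) -> float:
    """SNR averaged over all voxels of a mask, excluding infinite flags."""
    m = np.asarray(mask.data if isinstance(mask, ImageVolume) else mask).astype(bool)
    if m.sum() == 0:
        raise ValueError("roi_snr: empty mask")
    vals = np.asarray(snr.data)[m]
    finite = np.isfinite(vals)
    if not finite.all():
        logger.info("roi_snr: excluding %d non-finite voxels", (~finite).sum())
    if finite.sum() == 0:
        raise ValueError("roi_snr: no finite SNR voxels in mask")
    return float(vals[finite].mean())


# --------------------------------------------------------------------------
# significance of the raw ASL difference signal
# --------------------------------------------------------------------------

def significant_signal(
    ts: ASLTimeSeries,
    mask: ImageVolume | np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = 0,
) -> tuple[ImageVolume, float]:
    """Voxels whose control−label difference is significantly above zero.

    A non-parametric one-sample test: the n_pairs differences at each voxel
    are sign-flipped ``n_perm`` times (one shared flip vector per
    permutation across voxels), the one-sided p value compares the observed
    t statistic with its sign-flip null, and the reported fraction is the
    share of mask voxels with p < alpha.
    """
    m = np.asarray(mask.data if isinstance(mask, ImageVolume) else mask).astype(bool)
    if m.sum() == 0:
        raise ValueError("significant_signal: empty mask")
    n = ts.n_pairs
    if n < 5:
        raise ValueError("significant_signal requires n_pairs >= 5")
    control = ts.volumes[..., 0::2]
    label = ts.volumes[..., 1::2]
    diffs = (control - label)[m]  # (V, n)
    V = diffs.shape[0]

    def tstat(mean, var):
        # var == 0: mean/0 -> signed inf is the right limit; 0/0 -> 0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / np.sqrt(var / n)
        return np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)

    sum_sq = (diffs**2).sum(axis=1)
    mean_obs = diffs.mean(axis=1)
    var_obs = (sum_sq - n * mean_obs**2) / (n - 1)
    t_obs = tstat(mean_obs, np.maximum(var_obs, 0.0))

    rng = np.random.default_rng(seed)
    count = np.zeros(V, dtype=np.int64)
    block = max(1, min(n_perm, 64))
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        flips = rng.choice([-1.0, 1.0], size=(b, n))
        mean_p = flips @ diffs.T / n  # (b, V)
        var_p = (sum_sq[None, :] - n * mean_p**2) / (n - 1)
        t_p = tstat(mean_p, np.maximum(var_p, 0.0))
        count += (t_p >= t_obs[None, :]).sum(axis=0)
        done += b
    p = (1.0 + count) / (1.0 + n_perm)
    sig_flat = p < alpha
    sig = np.zeros(ts.grid_shape, dtype=bool)
    sig[m] = sig_flat
    fraction = float(sig_flat.sum()) / float(m.sum())
    return ImageVolume(sig.astype(np.float64), ts.voxel_size_mm), fraction


# --------------------------------------------------------------------------
# QC metrics
# --------------------------------------------------------------------------

def mean_relative_displacement(motion_trace: np.ndarray, rotation_radius_mm: float = 50.0) -> float:
    """Mean relative displacement (mm) of a 6-parameter motion trace.

    Each consecutive volume pair contributes the Euclidean norm of the
    relative displacement vector (three translation increments in mm and
    three rotation increments converted to mm on a sphere of
    ``rotation_radius_mm``); the MRD is the temporal mean of this relative
    displacement time course.  50 mm is the conventional head radius.
    """
    trace = np.asarray(motion_trace, dtype=np.float64)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise ValueError("motion_trace must be (n_volumes, 6)")
    if trace.shape[0] < 2:
        raise ValueError("motion trace must have at least 2 time points")
    d = np.diff(trace, axis=0)
    d[:, 3:] *= rotation_radius_mm
    disp = np.sqrt((d**2).sum(axis=1))
    return float(disp.mean())


def qc_exclude_low_gm_cbf(
    subject_gm_cbf_means: dict[str, float],
    threshold: float = 38.0,
) -> tuple[list[str], list[str]]:
    """Split subjects into kept/excluded by grey-matter mean CBF.

    Subjects with GM-mean CBF strictly below ``threshold`` (default
    38 ml/100g/min) are excluded; a value exactly at threshold is kept.
    """
    kept, excluded = [], []
    for sid, v in subject_gm_cbf_means.items():
        (excluded if v < threshold else kept).append(sid)
    if excluded:
        logger.info("qc_exclude_low_gm_cbf: excluded %s (GM CBF < %g)", excluded, threshold)
    return kept, excluded
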