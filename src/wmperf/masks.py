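"""Partial-volume map handling: resolution matching, binary masks, PV correction.

Partial-volume estimates (PVE) come from a high-resolution structural
segmentation; the perfusion grid is coarser.  ``downsample_pve`` aggregates
by block means (mass-preserving), ``binarize_masks`` applies the standard
inclusive thresholds (GM 0.4, WM 0.7), and ``pv_correct_cbf`` separates the
GM and WM perfusion contributions with the local linear-regression method:
within a small kernel around each voxel, observed CBF is modelled as
pve_gm * cbf_gm + pve_wm * cbf_wm and solved by least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate

from .image import ImageVolume

logger = logging.getLogger(__name__)

__all__ = ["TissueMaskSet", "downsample_pve", "binarize_masks", "pv_correct_cbf"]


@dataclass
class TissueMaskSet:
    """Binary tissue masks together with the PVE thresholds that made them."""

    gm_mask: ImageVolume
    wm_mask: ImageVolume
    csf_mask: ImageVolume
    gm_threshold: float = 0.4
    wm_threshold: float = 0.7
    csf_threshold: float = 0.9


def downsample_pve(pve_highres: ImageVolume, target_shape: tuple[int, int, int]) -> ImageVolume:
    """Block-mean aggregation of a PVE map onto a coarser grid.

    Each source axis must be an integer multiple of the target axis (the
    phantoms are built to guarantee this).  Fractions stay in [0, 1] and
    total tissue mass (sum x voxel volume) is conserved.
    """
    src = np.asarray(pve_highres.data)
    target_shape = tuple(int(t) for t in target_shape)
    factors = []
    for s, t in zip(src.shape, target_shape):
        if t <= 0 or s % t != 0:
            raise ValueError(
                f"source shape {src.shape} is not an integer multiple of target "
                f"{target_shape}; regenerate the phantom on a compatible grid"
            )
        factors.append(s // t)
    fx, fy, fz = factors
    blocks = src.reshape(
        target_shape[0], fx, target_shape[1], fy, target_shape[2], fz
    )
    out = blocks.mean(axis=(1, 3, 5))
    new_vox = tuple(v * f for v, f in zip(pve_highres.voxel_size_mm, factors))
    return ImageVolume(out, new_vox)


def binarize_masks(
    pve_gm: ImageVolume,
    pve_wm: ImageVolume,
    pve_csf: ImageVolume,
    gm_thr: float = 0.4,
    wm_thr: float = 0.7,
    csf_thr: float = 0.9,
) -> TissueMaskSet:
    """Threshold PVE maps into binary masks; comparisons are inclusive (>=)."""
    pve_gm.check_grid(pve_wm, "binarize_masks")
    pve_gm.check_grid(pve_csf, "binarize_masks")
    vs = pve_gm.voxel_size_mm
    return TissueMaskSet(
        gm_mask=ImageVolume((pve_gm.data >= gm_thr).astype(np.float64), vs),
        wm_mask=ImageVolume((pve_wm.data >= wm_thr).astype(np.float64), vs),
        csf_mask=ImageVolume((pve_csf.data >= csf_thr).astype(np.float64), vs),
        gm_threshold=gm_thr,
        wm_threshold=wm_thr,
        csf_threshold=csf_thr,
    )


def pv_correct_cbf(
    cbf: ImageVolume,
    pve_gm: ImageVolume,
    pve_wm: ImageVolume,
    kernel_voxels: tuple[int, int, int] = (5, 5, 1),
) -> tuple[ImageVolume, ImageVolume]:
    """Regression-based partial-volume correction of a CBF map.

    For every voxel, solves CBF ~= pve_gm * cbf_gm + pve_wm * cbf_wm by
    ordinary least squares over the kernel neighbourhood (default in-plane
    5 x 5, reflecting thick perfusion slices).  The CSF compartment is
    assumed non-perfused and is not modelled.  Voxels whose local design is
    rank-deficient (e.g. locally proportional PVE maps) are returned as NaN
    and counted in the log.
    """
    cbf.check_grid(pve_gm, "pv_correct_cbf")
    cbf.check_grid(pve_wm, "pv_correct_cbf")
    k = tuple(int(v) for v in kernel_voxels)
    if any(v < 1 or v % 2 == 0 for v in k):
        raise ValueError("kernel_voxels must be odd and >= 1 per axis")
    if any(kv > s for kv, s in zip(k, cbf.shape)):
        raise ValueError(f"kernel {k} larger than image {cbf.shape}")

    g, w, c = pve_gm.data, pve_wm.data, cbf.data
    kernel = np.ones(k)

    def ksum(x):
        # zero padding outside the image == truncating the neighbourhood
        return correlate(x, kernel, mode="constant", cval=0.0)

    s_gg = ksum(g * g)
    s_gw = ksum(g * w)
    s_ww = ksum(w * w)
    s_gc = ksum(g * c)
    s_wc = ksum(w * c)

    det = s_gg * s_ww - s_gw**2
    scale = np.maximum(s_gg * s_ww, np.finfo(float).tiny)
    singular = det <= 1e-10 * scale
    n_bad = int(singular.sum())
    if n_bad:
        logger.info("pv_correct_cbf: %d voxels with rank-deficient local design", n_bad)
    safe_det = np.where(singular, 1.0, det)
    cbf_gm = (s_ww * s_gc - s_gw * s_wc) / safe_det
    cbf_wm = (s_gg * s_wc - s_gw * s_gc) / safe_det
    cbf_gm[singular] = np.nan
    cbf_wm[singular] = np.nan
    return cbf.copy_with(cbf_gm), cbf.copy_with(cbf_wm)
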