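"""Atlas-label summaries: regional means, tract correlations, cluster reports.

Mirrors the tract-level analyses of the perfusion-microstructure study:
per-label mean +/- SD extraction, the within-subject Pearson correlation of
FA and CBF across tracts, the cross-subject correlation of regional means,
and the tabular report of significant clusters per label (only
intersections strictly larger than a minimum voxel count are listed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .image import ImageVolume

logger = logging.getLogger(__name__)

__all__ = [
    "RegionSummary",
    "roi_means",
    "within_subject_tract_correlation",
    "cross_subject_region_correlation",
    "cluster_report",
    "report_to_frame",
]


@dataclass
class RegionSummary:
    """One row of the cluster report: a label's extent and map summaries."""

    label: int
    name: str
    volume_voxels: int
    means: dict[str, tuple[float, float]]  # metric -> (mean, sd)
    mean_t: float
    peak_t: float


def _as_array(vol) -> np.ndarray:
    return np.asarray(vol.data if isinstance(vol, ImageVolume) else vol)


def roi_means(
    map_vol: ImageVolume,
    labels: ImageVolume,
    label_ids: list[int] | None = None,
) -> pd.DataFrame:
    """Mean and SD of a map per atlas label, skipping undefined (NaN) voxels.

    Labels absent from the volume are reported with volume 0 and NaN mean.
    Rows are sorted by label id.
    """
    map_vol.check_grid(labels, "roi_means")
    lab = _as_array(labels).astype(int)
    data = _as_array(map_vol).astype(float)
    if label_ids is None:
        label_ids = sorted(int(v) for v in np.unique(lab) if v != 0)
    if len(label_ids) == 0:
        raise ValueError("roi_means: no labels requested or present")
    rows = []
    for lbl in sorted(label_ids):
        m = lab == lbl
        vals = data[m]
        vals = vals[~np.isnan(vals)]
        rows.append(
            {
                "label": lbl,
                "n_voxels": int(vals.size),
                "mean": float(vals.mean()) if vals.size else np.nan,
                "sd": float(vals.std(ddof=0)) if vals.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the exact two-sided t-transform p (n-2 df).

    Zero-variance input yields (nan, nan) — an explicit undefined flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("correlation requires at least 3 defined pairs")
    tol_x = 1e-12 * max(1.0, float(np.abs(x).max()))
    tol_y = 1e-12 * max(1.0, float(np.abs(y).max()))
    if np.std(x) <= tol_x or np.std(y) <= tol_y:
        logger.info("correlation undefined: zero-variance input")
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return r, float(p)


def within_subject_tract_correlation(
    fa_means: np.ndarray,
    cbf_means: np.ndarray,
) -> tuple[float, float]:
    """Pearson correlation of FA vs CBF across tracts within one subject.

    Also applicable to subject-averaged regional means.  Requires >= 3
    regions with defined means; p is the exact two-sided t transform with
    R-2 degrees of freedom.
    """
    fa = np.asarray(fa_means, dtype=float)
    cbf = np.asarray(cbf_means, dtype=float)
    if fa.shape != cbf.shape:
        raise ValueError("fa_means and cbf_means must align")
    defined = ~(np.isnan(fa) | np.isnan(cbf))
    if defined.sum() < 3:
        raise ValueError("need >= 3 regions with defined means")
    return _pearson_with_p(fa, cbf)


def cross_subject_region_correlation(
    metric_means: np.ndarray,
    cbf_means: np.ndarray,
) -> tuple[float, float]:
    """Pearson correlation across subjects of two regional mean vectors."""
    a = np.asarray(metric_means, dtype=float)
    b = np.asarray(cbf_means, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need aligned vectors over >= 3 subjects")
    return _pearson_with_p(a, b)


def cluster_report(
    sig_mask: np.ndarray | ImageVolume,
    labels: ImageVolume,
    maps: dict[str, ImageVolume],
    tmap: ImageVolume | np.ndarray,
    label_names: dict[int, str] | None = None,
    min_voxels: int = 50,
) -> list[RegionSummary]:
    """Per-label summary of a significant mask (the tabular-report schema).

    The significant mask is intersected with every atlas label; only labels
    whose intersection is strictly larger than ``min_voxels`` are reported.
    Each surviving row lists the intersection volume, mean +/- SD of each
    supplied map within it, and the mean and peak t value.  Rows sort by
    label id.
    """
    sig = _as_array(sig_mask).astype(bool)
    lab = _as_array(labels).astype(int)
    t = _as_array(tmap).astype(float)
    if sig.shape != lab.shape:
        raise ValueError("sig_mask and labels must share a grid")
    out: list[RegionSummary] = []
    for lbl in sorted(int(v) for v in np.unique(lab) if v != 0):
        inter = sig & (lab == lbl)
        n = int(inter.sum())
        if n <= min_voxels:
            continue
        means = {}
        for name, vol in maps.items():
            vals = _as_array(vol).astype(float)[inter]
            vals = vals[~np.isnan(vals)]
            means[name] = (
                (float(vals.mean()), float(vals.std(ddof=0))) if vals.size else (np.nan, np.nan)
            )
        tv = t[inter]
        tv = tv[np.isfinite(tv)]
        out.append(
            RegionSummary(
                label=lbl,
                name=(label_names or {}).get(lbl, f"label_{lbl}"),
                volume_voxels=n,
                means=means,
                mean_t=float(tv.mean()) if tv.size else np.nan,
                peak_t=float(np.abs(tv).max()) if tv.size else np.nan,
            )
        )
    return out


def report_to_frame(report: list[RegionSummary]) -> pd.DataFrame:
    """Flatten a cluster report into the TSV table schema."""
    rows = []
    for r in report:
        row = {
            "label": r.label,
            "location": r.name,
            "volume_voxels": r.volume_voxels,
            "mean_t": r.mean_t,
            "peak_t": r.peak_t,
        }
        for metric, (m, s) in r.means.items():
            row[f"{metric}_mean"] = m
            row[f"{metric}_sd"] = s
        rows.append(row)
    return pd.DataFrame(rows)
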