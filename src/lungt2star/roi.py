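"""Per-lung summary statistics: mean/SD/median T2*, volume, histograms,
and the paired right-vs-left comparison.

'both' lungs means the pooled union of right and left voxels, so the combined
mean is the voxel-count-weighted mean of the per-lung means (exactly), and the
voxel histogram of 'both' is the sum of the per-lung histograms.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .images import LungMask, T2StarMap, grids_match

ROIS = ("right", "left", "both")


@dataclass
class RoiSummary:
    roi: str
    n_voxels: int
    mean_t2star: float
    sd_t2star: float
    median_t2star: float
    volume_ml: float
    undefined_stats: bool = False


@dataclass
class Histogram:
    roi: str
    bin_edges: np.ndarray
    counts: np.ndarray


@dataclass
class PairedComparison:
    n_pairs: int
    mean_difference: float
    statistic: float
    p_value: float
    degenerate: bool = False


def _select(t2map: T2StarMap, mask: LungMask, roi: str, quality=None) -> np.ndarray:
    if not grids_match(t2map.affine, mask.affine, t2map.shape, mask.shape):
        raise ValueError("T2* map and lung mask are not on the same grid")
    sel = mask.roi_selector(roi)
    if quality is not None:
        quality = np.asarray(quality, bool)
        if quality.shape != sel.shape:
            raise ValueError("quality mask grid does not match")
        sel = sel & quality
    return sel


def summarize_roi(
    t2map: T2StarMap, mask: LungMask, roi: str, quality: np.ndarray | None = None
) -> RoiSummary:
    """Summary statistics of T2* over one ROI; empty ROIs are flagged, not raised.

    SD is the descriptive (population, ddof=0) standard deviation of the voxel
    values.  Volume uses the mask voxel count times the voxel volume.
    """
    sel = _select(t2map, mask, roi, quality)
    values = t2map.t2star[sel]
    n = int(sel.sum())
    volume_ml = n * mask.voxel_volume_mm3 / 1000.0
    if n == 0:
        return RoiSummary(roi, 0, np.nan, np.nan, np.nan, 0.0, undefined_stats=True)
    return RoiSummary(
        roi=roi,
        n_voxels=n,
        mean_t2star=float(np.mean(values)),
        sd_t2star=float(np.std(values)),
        median_t2star=float(np.median(values)),
        volume_ml=volume_ml,
    )


def roi_histogram(
    t2map: T2StarMap,
    mask: LungMask,
    roi: str,
    bins: int = 50,
    value_range: tuple | None = None,
    quality: np.ndarray | None = None,
) -> Histogram:
    """Voxel histogram of T2* over one ROI; counts sum to the ROI voxel count."""
    if int(bins) < 1:
        raise ValueError("bins must be >= 1")
    sel = _select(t2map, mask, roi, quality)
    values = t2map.t2star[sel]
    if values.size == 0:
        edges = np.histogram_bin_edges(
            np.array([0.0, 1.0]), bins=bins, range=value_range
        )
        return Histogram(roi, edges, np.zeros(int(bins), dtype=int))
    counts, edges = np.histogram(values, bins=int(bins), range=value_range)
    return Histogram(roi, edges, counts)


def rois_wide(metrics_long: pd.DataFrame, values: list[str] | None = None) -> pd.DataFrame:
    """Pivot a long per-scan/per-roi metrics table to one row per scan.

    Columns become ``<metric>_<roi>``; scan-level columns (subject_id,
    ga_weeks) are carried through.
    """
    values = values or [
        c
        for c in metrics_long.columns
        if c not in ("scan_id", "subject_id", "ga_weeks", "roi")
    ]
    wide = metrics_long.pivot(index="scan_id", columns="roi", values=values)
    wide.columns = [f"{m}_{roi}" for m, roi in wide.columns]
    keys = metrics_long.drop_duplicates("scan_id").set_index("scan_id")[
        [c for c in ("subject_id", "ga_weeks") if c in metrics_long.columns]
    ]
    return keys.join(wide).reset_index()


def compare_lungs(cohort: pd.DataFrame, metric: str) -> PairedComparison:
    """Paired two-sided t-test of right minus left for ``metric``.

    Expects columns ``<metric>_right`` and ``<metric>_left`` paired by row
    (one row per scan_id). Zero-variance differences are handled
    deterministically and flagged as degenerate.
    """
    cols = (f"{metric}_right", f"{metric}_left")
    for c in cols:
        if c not in cohort.columns:
            raise ValueError(f"missing per-lung column {c!r}")
    pairs = cohort[list(cols)].dropna()
    if len(pairs) < 2:
        raise ValueError(f"need >= 2 complete right/left pairs, got {len(pairs)}")
    diff = pairs[cols[0]].to_numpy(float) - pairs[cols[1]].to_numpy(float)
    mean_diff = float(diff.mean())
    if np.std(diff) == 0.0:
        if mean_diff == 0.0:
            return PairedComparison(len(diff), 0.0, 0.0, 1.0, degenerate=True)
        stat = np.inf if mean_diff > 0 else -np.inf
        return PairedComparison(len(diff), mean_diff, stat, 0.0, degenerate=True)
    res = stats.ttest_rel(pairs[cols[0]], pairs[cols[1]])
    return PairedComparison(len(diff), mean_diff, float(res.statistic), float(res.pvalue))
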