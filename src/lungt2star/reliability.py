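"""Observer reliability: two-way absolute-agreement intraclass correlation.

Implements the single-measures ICC(A,1) (default) and average-measures
ICC(A,k) from two-way ANOVA mean squares, with 95% confidence intervals from
the McGraw & Wong F-based construction.  Absolute agreement penalises
systematic offsets between observers, unlike consistency-type ICCs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str  # 'ICC(A,1)' or 'ICC(A,k)'
    n_targets: int
    k_raters: int
    n_dropped: int = 0
    degenerate: bool = False
    metric: str = ""


def _anova_mean_squares(x: np.ndarray):
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_absolute_agreement(
    matrix, average: bool = False, alpha: float = 0.05, metric: str = ""
) -> ICCResult:
    """ICC(A,1) (or ICC(A,k) with ``average=True``) of a targets x raters matrix.

    Rows with missing values are dropped (complete-case) and counted in
    ``n_dropped``.  Zero between-target variance yields a flagged degenerate
    result rather than an exception.
    """
    x = np.asarray(matrix, float)
    if x.ndim != 2:
        raise ValueError("ratings matrix must be 2-D (targets x raters)")
    complete = np.isfinite(x).all(axis=1)
    n_dropped = int((~complete).sum())
    x = x[complete]
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 targets and >= 2 raters, got {n} x {k}")

    msr, msc, mse = _anova_mean_squares(x)
    model = "ICC(A,k)" if average else "ICC(A,1)"
    degenerate = np.var(x.mean(axis=1)) <= 1e-30

    if average:
        denom = msr + (msc - mse) / n
    else:
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return ICCResult(np.nan, np.nan, np.nan, model, n, k, n_dropped, True, metric)
    icc1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)  # single measures
    icc = (msr - mse) / denom

    # McGraw & Wong F-based interval for the agreement ICCs
    if mse == 0.0 and msc == 0.0:
        lo = hi = icc
    else:
        a = k * icc1 / (n * (1.0 - icc1)) if icc1 < 1.0 else np.inf
        b = 1.0 + k * icc1 * (n - 1) / (n * (1.0 - icc1)) if icc1 < 1.0 else np.inf
        denom_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        if np.isinf(a) or np.isinf(b) or denom_v <= 0 or not np.isfinite(denom_v):
            lo = hi = icc
        else:
            v = (a * msc + b * mse) ** 2 / denom_v
            f1 = f_dist.ppf(1 - alpha / 2, n - 1, v)
            f2 = f_dist.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
            if average:  # Spearman-Brown step up to the k-rater interval
                lo = k * lo / (1 + (k - 1) * lo)
                hi = k * hi / (1 + (k - 1) * hi)
    lo, hi = float(min(lo, icc)), float(max(hi, icc))
    return ICCResult(float(icc), lo, hi, model, n, k, n_dropped, bool(degenerate), metric)


def agreement_report(
    cohort_a: pd.DataFrame,
    cohort_b: pd.DataFrame,
    metrics,
    average: bool = False,
) -> pd.DataFrame:
    """One ICC row per metric over scans shared by two observers' tables.

    Tables are matched on ``scan_id``; unmatched scans are counted per metric
    in the ``n_unmatched`` column.
    """
    if "scan_id" not in cohort_a.columns or "scan_id" not in cohort_b.columns:
        raise ValueError("both tables need a scan_id column")
    merged = cohort_a.merge(cohort_b, on="scan_id", suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("no overlapping scan_ids between the two tables")
    n_unmatched = len(set(cohort_a.scan_id).symmetric_difference(cohort_b.scan_id))
    rows = []
    for metric in metrics:
        mat = merged[[f"{metric}_a", f"{metric}_b"]].to_numpy(float)
        res = icc_absolute_agreement(mat, average=average, metric=metric)
        rows.append(
            {
                "metric": metric,
                "icc": res.icc,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "model": res.model,
                "n_targets": res.n_targets,
                "k_raters": res.k_raters,
                "n_dropped": res.n_dropped,
                "n_unmatched": n_unmatched,
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame(rows)
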