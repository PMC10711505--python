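"""Gestational-age trend and normative modelling with z-scores and centiles.

A normative model here is a pair of linear functions of gestational age:
``mean(GA) = mean_slope * GA + mean_intercept`` and
``SD(GA) = sd_slope * GA + sd_intercept``.  An observation converts to
``z = (observed - mean(GA)) / SD(GA)`` and to a centile via the exact standard
normal CDF.  :func:`published_model` packages the published reference
coefficients for mean lung T2* (ms).

Trend fitting is OLS of the metric on GA; serial scans of the same subject can
be handled with cluster-robust (CR1) standard errors over subject id, which
changes inference only, never the point estimates.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from sklearn.base import BaseEstimator, RegressorMixin

PUBLISHED_MEAN = (1.488884, 21.997645)  # ms/week, ms
PUBLISHED_SD = (1.488884, -18.451005)  # ms/week, ms
PUBLISHED_GA_DOMAIN = (20.6, 38.3)  # weeks; study range, SD > 0 throughout


@dataclass
class ZScoreResult:
    z: float
    centile: float  # percent, 100 * Phi(z)


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    se_slope: float
    n_scans: int
    n_subjects: int
    cluster_robust: bool = False


@dataclass
class SdTrendFit:
    sd_slope: float
    sd_intercept: float
    negative_sd_warning: bool = False


@dataclass
class NormativeModel:
    """Linear mean/SD reference for a metric over a gestational-age domain."""

    mean_slope: float
    mean_intercept: float
    sd_slope: float
    sd_intercept: float
    ga_domain: tuple = PUBLISHED_GA_DOMAIN
    metric: str = "t2star_both_ms"
    provenance: str = ""

    def __post_init__(self):
        lo, hi = self.ga_domain
        if not lo < hi:
            raise ValueError("ga_domain must be an increasing (min, max) pair")
        if min(self.sd(lo), self.sd(hi)) <= 0:
            raise ValueError("SD function must be positive over the whole ga_domain")

    def _check_domain(self, ga):
        ga = np.asarray(ga, float)
        lo, hi = self.ga_domain
        if np.any(ga < lo) or np.any(ga > hi):
            raise ValueError(f"gestational age outside model domain [{lo}, {hi}] weeks")
        return ga

    def mean(self, ga):
        return self.mean_slope * np.asarray(ga, float) + self.mean_intercept

    def sd(self, ga):
        return self.sd_slope * np.asarray(ga, float) + self.sd_intercept

    def zscore(self, observed, ga_weeks) -> ZScoreResult:
        ga = self._check_domain(ga_weeks)
        z = (np.asarray(observed, float) - self.mean(ga)) / self.sd(ga)
        centile = 100.0 * norm.cdf(z)
        if z.ndim == 0:
            return ZScoreResult(float(z), float(centile))
        return ZScoreResult(z, centile)

    def reference_band(self, ga_grid, centiles=(3, 10, 50, 90, 97)) -> pd.DataFrame:
        """Table of (ga, centile, value) with value = mean(ga) + Phi^-1(c/100) SD(ga)."""
        ga = self._check_domain(ga_grid)
        centiles = np.asarray(centiles, float)
        if np.any(centiles <= 0) or np.any(centiles >= 100):
            raise ValueError("centiles must lie strictly inside (0, 100)")
        rows = []
        for c in centiles:
            q = norm.ppf(c / 100.0)
            rows.append(
                pd.DataFrame(
                    {"ga_weeks": ga, "centile": c, "value": self.mean(ga) + q * self.sd(ga)}
                )
            )
        return pd.concat(rows, ignore_index=True)

    def to_json(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "NormativeModel":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        d["ga_domain"] = tuple(d["ga_domain"])
        return cls(**d)


def published_model() -> NormativeModel:
    """The published normative reference for mean lung T2* (ms) vs GA (weeks)."""
    return NormativeModel(
        mean_slope=PUBLISHED_MEAN[0],
        mean_intercept=PUBLISHED_MEAN[1],
        sd_slope=PUBLISHED_SD[0],
        sd_intercept=PUBLISHED_SD[1],
        ga_domain=PUBLISHED_GA_DOMAIN,
        metric="t2star_both_ms",
        provenance="published reference coefficients",
    )


def zscore(observed, ga_weeks, model: NormativeModel) -> ZScoreResult:
    return model.zscore(observed, ga_weeks)


def reference_band(model: NormativeModel, ga_grid, centiles=(3, 10, 50, 90, 97)) -> pd.DataFrame:
    return model.reference_band(ga_grid, centiles)


class GATrendRegressor(BaseEstimator, RegressorMixin):
    """OLS of a metric on gestational age with optional cluster-robust SEs.

    X is (n, 1) gestational ages; ``groups`` (subject ids) passed to ``fit``
    switches the slope SE and p-value to cluster-robust (CR1) inference over
    subjects while leaving point estimates untouched.
    """

    def __init__(self, cluster_robust: bool = False):
        self.cluster_robust = cluster_robust

    def fit(self, X, y, groups=None):
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or X.shape[1] != 1:
            raise ValueError("X must be a single column of gestational ages")
        y = np.asarray(y, float)
        keep = np.isfinite(X[:, 0]) & np.isfinite(y)
        X, y = X[keep], y[keep]
        if groups is not None:
            groups = np.asarray(groups)[keep]
        if X.shape[0] < 3:
            raise ValueError(f"need >= 3 scans with metric and GA, got {X.shape[0]}")
        if np.ptp(X[:, 0]) == 0:
            raise ValueError("gestational age is constant; trend design is singular")
        design = sm.add_constant(X[:, 0])
        model = sm.OLS(y, design)
        if self.cluster_robust:
            if groups is None:
                raise ValueError("cluster_robust=True requires groups (subject ids)")
            res = model.fit(cov_type="cluster", cov_kwds={"groups": groups})
        else:
            res = model.fit()
        self.intercept_ = float(res.params[0])
        self.slope_ = float(res.params[1])
        self.se_slope_ = float(res.bse[1])
        self.p_value_ = float(res.pvalues[1])
        self.r_squared_ = float(res.rsquared)
        self.conf_int_slope_ = tuple(np.asarray(res.conf_int())[1])
        self.n_scans_ = int(X.shape[0])
        self.n_subjects_ = int(len(np.unique(groups))) if groups is not None else int(X.shape[0])
        self.results_ = res
        return self

    def predict(self, X):
        X = np.asarray(X, float)
        if X.ndim == 2:
            X = X[:, 0]
        return self.intercept_ + self.slope_ * X


def fit_trend(
    cohort: pd.DataFrame, metric: str, cluster_by_subject: bool = False
) -> RegressionFit:
    """Linear GA trend of ``metric`` over the cohort table."""
    reg = GATrendRegressor(cluster_robust=cluster_by_subject)
    groups = cohort["subject_id"].to_numpy() if "subject_id" in cohort.columns else None
    if cluster_by_subject and groups is None:
        raise ValueError("cluster_by_subject requires a subject_id column")
    reg.fit(cohort[["ga_weeks"]].to_numpy(), cohort[metric].to_numpy(), groups=groups)
    return RegressionFit(
        slope=reg.slope_,
        intercept=reg.intercept_,
        r_squared=reg.r_squared_,
        p_value=reg.p_value_,
        se_slope=reg.se_slope_,
        n_scans=reg.n_scans_,
        n_subjects=reg.n_subjects_,
        cluster_robust=cluster_by_subject,
    )


def binned_sd_fit(ga, values) -> tuple[float, float]:
    """OLS of per-GA-bin sample SDs (ddof=1) on bin GA; bins are the unique GAs.

    Returns (sd_slope, sd_intercept). Intended for designed cohorts with a
    fixed GA grid and many scans per grid point.
    """
    df = pd.DataFrame({"ga": np.asarray(ga, float), "v": np.asarray(values, float)})
    per_bin = df.groupby("ga")["v"].agg(["std", "count"])
    per_bin = per_bin[per_bin["count"] >= 2]
    if len(per_bin) < 3:
        raise ValueError("need >= 3 GA bins with >= 2 scans each")
    x = per_bin.index.to_numpy(float)
    res = sm.OLS(per_bin["std"].to_numpy(), sm.add_constant(x)).fit()
    return float(res.params[1]), float(res.params[0])


def fit_sd_trend(
    cohort: pd.DataFrame,
    metric: str,
    mean_fit: RegressionFit,
    method: str = "residual",
) -> SdTrendFit:
    """Linear SD-vs-GA function of ``metric``.

    'residual' (default): absolute residuals from the mean fit, scaled by
    sqrt(pi/2) (since E|N(0, s)| = s sqrt(2/pi)), regressed on GA.
    'binned': per-GA-bin sample SDs regressed on GA (see binned_sd_fit).
    """
    ga = cohort["ga_weeks"].to_numpy(float)
    y = cohort[metric].to_numpy(float)
    keep = np.isfinite(ga) & np.isfinite(y)
    ga, y = ga[keep], y[keep]
    if method == "residual":
        resid = y - (mean_fit.intercept + mean_fit.slope * ga)
        scaled = np.abs(resid) * np.sqrt(np.pi / 2.0)
        res = sm.OLS(scaled, sm.add_constant(ga)).fit()
        sd_slope, sd_intercept = float(res.params[1]), float(res.params[0])
    elif method == "binned":
        sd_slope, sd_intercept = binned_sd_fit(ga, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    lo, hi = float(ga.min()), float(ga.max())
    neg = min(sd_slope * lo + sd_intercept, sd_slope * hi + sd_intercept) <= 0
    if neg:
        warnings.warn("fitted SD function is non-positive somewhere on the cohort GA range")
    return SdTrendFit(sd_slope, sd_intercept, negative_sd_warning=bool(neg))


class NormativeRegressor(BaseEstimator):
    """Fit a full normative model (mean and SD trends) from (GA, metric) data.

    Estimator-style wrapper around :func:`fit_trend` and :func:`fit_sd_trend`;
    fitted attributes mirror the coefficient names and ``to_model()`` yields a
    :class:`NormativeModel` restricted to the observed GA range.
    """

    def __init__(self, cluster_robust: bool = False, sd_method: str = "residual",
                 metric: str = "metric"):
        self.cluster_robust = cluster_robust
        self.sd_method = sd_method
        self.metric = metric

    def fit(self, X, y, groups=None):
        X = np.asarray(X, float)
        ga = X[:, 0] if X.ndim == 2 else X
        frame = pd.DataFrame({"ga_weeks": ga, self.metric: np.asarray(y, float)})
        if groups is not None:
            frame["subject_id"] = np.asarray(groups)
        mean_fit = fit_trend(frame, self.metric, cluster_by_subject=self.cluster_robust)
        sd_fit = fit_sd_trend(frame, self.metric, mean_fit, method=self.sd_method)
        self.mean_slope_ = mean_fit.slope
        self.mean_intercept_ = mean_fit.intercept
        self.sd_slope_ = sd_fit.sd_slope
        self.sd_intercept_ = sd_fit.sd_intercept
        self.mean_fit_ = mean_fit
        self.sd_fit_ = sd_fit
        self.ga_domain_ = (float(np.nanmin(ga)), float(np.nanmax(ga)))
        return self

    def predict(self, X):
        X = np.asarray(X, float)
        ga = X[:, 0] if X.ndim == 2 else X
        return self.mean_intercept_ + self.mean_slope_ * ga

    def to_model(self) -> NormativeModel:
        return NormativeModel(
            mean_slope=self.mean_slope_,
            mean_intercept=self.mean_intercept_,
            sd_slope=self.sd_slope_,
            sd_intercept=self.sd_intercept_,
            ga_domain=self.ga_domain_,
            metric=self.metric,
            provenance="fitted from cohort",
        )
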