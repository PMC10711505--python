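"""Synthetic cohort tables: gestational ages and normative-model metric draws.

A cohort table has one row per scan (subject_id, scan_id, ga_weeks, metric).
Gestational ages follow a truncated normal on the study range; a configurable
fraction of subjects receives a second scan 2-8 weeks later (clipped to the
range), sharing the subject id.

Because truncation shrinks the standard deviation and repeat scans shift the
mean upward, drawing GA from a truncated Normal(ga_mean, ga_sd) literally would
not reproduce the target scan-level summary.  By default the generator
therefore calibrates the latent (mu, sigma) of the truncated normal — by
deterministic quadrature over the scan-level mixture (first scans + clipped
repeat scans) and a least-squares root-find — so that the scan-level GA
distribution has exactly the requested mean and SD.  Set
``calibrate_ga=False`` to use the literal latent parameters instead.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

COHORT_COLUMNS = ("subject_id", "scan_id", "ga_weeks")

# Published normative coefficients for mean lung T2* (ms) vs GA (weeks); the
# default metric-generating process of the simulated cohort.
_PUB_MEAN = (1.488884, 21.997645)
_PUB_SD = (1.488884, -18.451005)


@dataclass
class CohortSpec:
    """Design of a simulated cohort.

    ga_mean / ga_sd are the *target scan-level* sample moments (see module
    docstring); ga_min / ga_max bound every scan's gestational age.  The
    metric is drawn per scan from Normal(mean(GA), SD(GA)) with linear
    coefficient functions of GA.
    """

    n_subjects: int = 77
    ga_mean: float = 29.9
    ga_sd: float = 4.3
    ga_min: float = 20.6
    ga_max: float = 38.3
    mean_slope: float = _PUB_MEAN[0]
    mean_intercept: float = _PUB_MEAN[1]
    sd_slope: float = _PUB_SD[0]
    sd_intercept: float = _PUB_SD[1]
    repeat_scan_fraction: float = 0.115
    metric_name: str = "t2star_both_ms"
    calibrate_ga: bool = True
    seed: int | None = None

    def __post_init__(self):
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        if not self.ga_min < self.ga_max:
            raise ValueError("ga_min must be < ga_max")
        if not 0.0 <= self.repeat_scan_fraction <= 1.0:
            raise ValueError("repeat_scan_fraction must lie in [0, 1]")
        if self.ga_sd <= 0:
            raise ValueError("ga_sd must be > 0")
        # linear SD function: positivity over the range is decided at the ends
        for ga in (self.ga_min, self.ga_max):
            if self.metric_sd(ga) <= 0:
                raise ValueError(
                    f"normative SD is non-positive at GA {ga}; the metric-generating "
                    "process is undefined on part of the GA range"
                )

    def metric_mean(self, ga):
        return self.mean_slope * np.asarray(ga, float) + self.mean_intercept

    def metric_sd(self, ga):
        return self.sd_slope * np.asarray(ga, float) + self.sd_intercept


def _scan_ga_moments(mu: float, sigma: float, spec: CohortSpec) -> tuple[float, float]:
    """Mean and SD of the scan-level GA mixture under latent TN(mu, sigma)."""
    a, b = spec.ga_min, spec.ga_max
    g = np.linspace(a, b, 801)
    pdf = stats.truncnorm.pdf(g, (a - mu) / sigma, (b - mu) / sigma, loc=mu, scale=sigma)
    wg = pdf / pdf.sum()
    m1 = float(wg @ g)
    m2 = float(wg @ (g * g))
    f = spec.repeat_scan_fraction
    if f > 0:
        d = np.linspace(2.0, 8.0, 161)
        h = np.clip(g[:, None] + d[None, :], a, b)
        h1 = float(wg @ h.mean(axis=1))
        h2 = float(wg @ (h**2).mean(axis=1))
        w2 = f / (1.0 + f)
        m1, m2 = (1 - w2) * m1 + w2 * h1, (1 - w2) * m2 + w2 * h2
    var = max(m2 - m1 * m1, 0.0)
    return m1, float(np.sqrt(var))


def latent_ga_params(spec: CohortSpec) -> tuple[float, float]:
    """Latent (mu, sigma) of the truncated normal used to draw first-scan GAs."""
    if not spec.calibrate_ga:
        return spec.ga_mean, spec.ga_sd

    def resid(x):
        m, s = _scan_ga_moments(x[0], np.exp(x[1]), spec)
        return [m - spec.ga_mean, s - spec.ga_sd]

    sol = optimize.least_squares(
        resid,
        x0=[spec.ga_mean, np.log(spec.ga_sd * 1.3)],
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if np.max(np.abs(sol.fun)) > 1e-3:
        raise ValueError(
            "could not calibrate the truncated-normal GA distribution to the "
            f"requested moments (residual {sol.fun}); the target SD may be "
            "unattainable on the given GA range"
        )
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def simulate_cohort(spec: CohortSpec | None = None, seed: int | None = None) -> pd.DataFrame:
    """Draw a cohort table; one row per scan, repeat scans share subject_id."""
    spec = spec or CohortSpec()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    columns = list(COHORT_COLUMNS) + [spec.metric_name]
    if spec.n_subjects == 0:
        return pd.DataFrame({c: pd.Series(dtype=(object if c.endswith("_id") else float))
                             for c in columns})

    mu, sigma = latent_ga_params(spec)
    a, b = spec.ga_min, spec.ga_max
    alpha, beta = (a - mu) / sigma, (b - mu) / sigma
    n = spec.n_subjects
    ga_first = stats.truncnorm.rvs(alpha, beta, loc=mu, scale=sigma, size=n, random_state=rng)

    n_repeat = int(round(spec.repeat_scan_fraction * n))
    repeat_idx = rng.choice(n, size=n_repeat, replace=False) if n_repeat else np.array([], int)

    subject_ids, scan_ids, ga = [], [], []
    for i in range(n):
        sid = f"S{i + 1:05d}"
        subject_ids.append(sid)
        scan_ids.append(f"{sid}_1")
        ga.append(ga_first[i])
    for i in sorted(repeat_idx):
        delta = rng.uniform(2.0, 8.0)
        subject_ids.append(f"S{i + 1:05d}")
        scan_ids.append(f"S{i + 1:05d}_2")
        ga.append(float(np.clip(ga_first[i] + delta, a, b)))

    ga = np.asarray(ga, float)
    metric = rng.normal(spec.metric_mean(ga), spec.metric_sd(ga))
    return pd.DataFrame(
        {
            "subject_id": subject_ids,
            "scan_id": scan_ids,
            "ga_weeks": ga,
            spec.metric_name: metric,
        }
    )


def simulate_designed_metric(
    ga_values: np.ndarray,
    seed: int | None = None,
    mean_slope: float = _PUB_MEAN[0],
    mean_intercept: float = _PUB_MEAN[1],
    sd_slope: float = _PUB_SD[0],
    sd_intercept: float = _PUB_SD[1],
    metric_name: str = "t2star_both_ms",
) -> pd.DataFrame:
    """Cohort table at fixed, user-designed GA values (e.g. 200 per integer GA).

    Used for parameter-recovery studies of the normative SD function, where a
    balanced GA design is wanted rather than a realistic GA distribution.
    """
    ga = np.asarray(ga_values, float)
    rng = np.random.default_rng(seed)
    sd = sd_slope * ga + sd_intercept
    if np.any(sd <= 0):
        raise ValueError("normative SD non-positive at some requested GA")
    metric = rng.normal(mean_slope * ga + mean_intercept, sd)
    ids = [f"D{i + 1:06d}" for i in range(ga.size)]
    return pd.DataFrame(
        {
            "subject_id": ids,
            "scan_id": [f"{s}_1" for s in ids],
            "ga_weeks": ga,
            metric_name: metric,
        }
    )
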