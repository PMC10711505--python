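"""Voxelwise mono-exponential T2* estimation from multi-echo magnitude data.

Two fitters are provided:

* log-linear — ordinary least squares of ln(S) on TE; closed form and fast,
  but biased when the Rician noise floor lifts late-echo magnitudes;
* NLLS — bounded nonlinear least squares of ``S0 * exp(-TE/T2*)`` in the
  linear signal domain, initialised from the log-linear solution (the field
  standard and the default).

T2* estimates are clamped to [t2_min, t2_max] with the clamp recorded in a
per-voxel status flag; voxels with fewer than three positive samples fail
without raising, so whole-map fits always complete.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, TransformerMixin

from .images import FitStatus, MultiEchoImage, T2StarMap, grids_match

DEFAULT_T2_BOUNDS = (1.0, 500.0)  # ms; values outside are non-physiological at 3 T
_TINY = 1e-300


@dataclass
class FitResult:
    """Single-voxel decay-fit outcome."""

    s0: float
    t2star_ms: float
    r_squared: float
    status: FitStatus

    @property
    def failed(self) -> bool:
        return self.status == FitStatus.FAILED


def _loglinear_batch(signals: np.ndarray, echo_times: np.ndarray, t2_min: float, t2_max: float):
    """Vectorised log-linear fit over rows of ``signals`` (n_voxels, n_echoes).

    Returns (s0, t2star, r_squared, status) arrays. Nonpositive samples are
    dropped per voxel; < 3 remaining echoes marks the voxel failed.
    """
    S = np.asarray(signals, float)
    te = np.asarray(echo_times, float)
    if S.ndim != 2 or S.shape[1] != te.size:
        raise ValueError("signals must be (n_voxels, n_echoes) matching echo_times")
    pos = S > 0
    npos = pos.sum(axis=1)
    valid = npos >= 3

    w = pos.astype(float)
    sw = np.maximum(npos, 1)
    logS = np.where(pos, np.log(np.where(pos, S, 1.0)), 0.0)
    mx = (w * te).sum(axis=1) / sw
    my = (w * logS).sum(axis=1) / sw
    dx = (te[None, :] - mx[:, None]) * w
    dy = (logS - my[:, None]) * w
    sxx = (dx * dx).sum(axis=1)
    sxy = (dx * dy).sum(axis=1)
    syy = (dy * dy).sum(axis=1)
    slope = sxy / np.maximum(sxx, _TINY)
    intercept = my - slope * mx
    ss_res = np.maximum(syy - slope * sxy, 0.0)
    r2 = np.where(syy > 0, 1.0 - ss_res / np.where(syy > 0, syy, 1.0), 1.0)
    r2 = np.clip(r2, 0.0, 1.0)

    s0 = np.exp(intercept)
    with np.errstate(divide="ignore"):
        t2 = np.where(slope < 0, -1.0 / np.minimum(slope, -_TINY), np.inf)
    status = np.full(S.shape[0], FitStatus.OK, dtype=np.uint8)
    status[t2 < t2_min] = FitStatus.CLAMPED_LOW
    status[t2 > t2_max] = FitStatus.CLAMPED_HIGH  # includes rising / flat signal
    t2 = np.clip(t2, t2_min, t2_max)

    status[~valid] = FitStatus.FAILED
    s0[~valid] = np.nan
    t2[~valid] = np.nan
    r2[~valid] = np.nan
    return s0, t2, r2, status


def fit_loglinear(
    signal,
    echo_times,
    t2_min: float = DEFAULT_T2_BOUNDS[0],
    t2_max: float = DEFAULT_T2_BOUNDS[1],
) -> FitResult:
    """Log-linear OLS fit of one voxel's decay; see module docstring."""
    s0, t2, r2, status = _loglinear_batch(
        np.asarray(signal, float)[None, :], echo_times, t2_min, t2_max
    )
    return FitResult(float(s0[0]), float(t2[0]), float(r2[0]), FitStatus(int(status[0])))


def _linear_r2(signal, model) -> float:
    resid = signal - model
    ss_res = float(resid @ resid)
    dev = signal - signal.mean()
    ss_tot = float(dev @ dev)
    if ss_tot <= 0:
        return 1.0 if ss_res <= 1e-12 * max(1.0, float(signal.max()) ** 2) else 0.0
    return float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))


def fit_nlls(
    signal,
    echo_times,
    init: FitResult | None = None,
    t2_min: float = DEFAULT_T2_BOUNDS[0],
    t2_max: float = DEFAULT_T2_BOUNDS[1],
) -> FitResult:
    """Bounded NLLS fit of one voxel's decay in the linear signal domain."""
    signal = np.asarray(signal, float)
    te = np.asarray(echo_times, float)
    if init is None:
        init = fit_loglinear(signal, te, t2_min=t2_min, t2_max=t2_max)
    if init.failed:
        return FitResult(np.nan, np.nan, np.nan, FitStatus.FAILED)

    x0 = np.array(
        [max(init.s0, 1e-9), float(np.clip(init.t2star_ms, t2_min, t2_max))]
    )

    def resid(p):
        return p[0] * np.exp(-te / p[1]) - signal

    def jac(p):
        e = np.exp(-te / p[1])
        return np.column_stack([e, p[0] * e * te / p[1] ** 2])

    res = least_squares(
        resid, x0, jac=jac, bounds=([1e-12, t2_min], [np.inf, t2_max]), method="trf"
    )
    if res.success:
        s0_hat, t2_hat = float(res.x[0]), float(res.x[1])
    else:  # fall back on the initialiser
        warnings.warn("NLLS did not converge; falling back to the log-linear initialiser")
        s0_hat, t2_hat = float(x0[0]), float(x0[1])

    tol = 1e-8 * (t2_max - t2_min)
    if t2_hat >= t2_max - tol:
        status = FitStatus.CLAMPED_HIGH
    elif t2_hat <= t2_min + tol:
        status = FitStatus.CLAMPED_LOW
    else:
        status = FitStatus.OK
    r2 = _linear_r2(signal, s0_hat * np.exp(-te / t2_hat))
    return FitResult(s0_hat, t2_hat, r2, status)


class T2StarFitter(BaseEstimator, TransformerMixin):
    """Per-sample mono-exponential decay fitter with a transformer interface.

    Rows of X are decay curves sampled at ``echo_times``; ``transform``
    returns an (n_samples, 4) array with columns (s0, t2star_ms, r_squared,
    status code), status codes per :class:`~lungt2star.images.FitStatus`.

    Parameters
    ----------
    echo_times : sequence of float
        Echo times, strictly increasing. Units are free; T2* is returned in
        the same units, so the clamp bounds must use those units too.
    method : {'nlls', 'loglinear'}
    t2_min, t2_max : float
        Clamp bounds for T2*.
    """

    def __init__(
        self,
        echo_times=None,
        method: str = "nlls",
        t2_min: float = DEFAULT_T2_BOUNDS[0],
        t2_max: float = DEFAULT_T2_BOUNDS[1],
    ):
        self.echo_times = echo_times
        self.method = method
        self.t2_min = t2_min
        self.t2_max = t2_max

    def fit(self, X, y=None):
        if self.method not in ("nlls", "loglinear"):
            raise ValueError(f"unknown method {self.method!r}")
        te = np.asarray(self.echo_times, float)
        if te.ndim != 1 or te.size < 3 or np.any(np.diff(te) <= 0) or np.any(te <= 0):
            raise ValueError("echo_times must be >= 3 strictly increasing positive values")
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != te.size:
            raise ValueError("X must be (n_samples, n_echoes) matching echo_times")
        self.echo_times_ = te
        self.n_features_in_ = te.size
        return self

    def transform(self, X) -> np.ndarray:
        te = self.echo_times_
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != te.size:
            raise ValueError("X must be (n_samples, n_echoes) matching echo_times")
        s0, t2, r2, status = _loglinear_batch(X, te, self.t2_min, self.t2_max)
        if self.method == "nlls":
            for i in range(X.shape[0]):
                if status[i] == FitStatus.FAILED:
                    continue
                init = FitResult(s0[i], t2[i], r2[i], FitStatus(int(status[i])))
                fr = fit_nlls(X[i], te, init=init, t2_min=self.t2_min, t2_max=self.t2_max)
                s0[i], t2[i], r2[i], status[i] = fr.s0, fr.t2star_ms, fr.r_squared, fr.status
        return np.column_stack([s0, t2, r2, status.astype(float)])


def fit_map(
    image: MultiEchoImage,
    mask: np.ndarray | None = None,
    method: str = "nlls",
    t2_min: float = DEFAULT_T2_BOUNDS[0],
    t2_max: float = DEFAULT_T2_BOUNDS[1],
) -> T2StarMap:
    """Fit every voxel inside ``mask`` (whole grid if None); others are failed."""
    shape = image.shape
    if mask is None:
        sel = np.ones(shape, dtype=bool)
    else:
        mask = np.asarray(mask)
        if mask.shape != shape:
            raise ValueError(f"mask grid {mask.shape} does not match image grid {shape}")
        sel = mask.astype(bool)

    t2_vol = np.full(shape, np.nan)
    s0_vol = np.full(shape, np.nan)
    r2_vol = np.full(shape, np.nan)
    status_vol = np.full(shape, FitStatus.FAILED, dtype=np.uint8)

    n = int(sel.sum())
    if n:
        fitter = T2StarFitter(
            echo_times=image.echo_times, method=method, t2_min=t2_min, t2_max=t2_max
        ).fit(image.data[sel].reshape(n, -1))
        out = fitter.transform(image.data[sel].reshape(n, -1))
        s0_vol[sel] = out[:, 0]
        t2_vol[sel] = out[:, 1]
        r2_vol[sel] = out[:, 2]
        status_vol[sel] = out[:, 3].astype(np.uint8)

    return T2StarMap(
        t2star=t2_vol,
        s0=s0_vol,
        r_squared=r2_vol,
        status=status_vol,
        voxel_size=image.voxel_size,
        affine=image.affine,
        meta={"method": method, "t2_min": t2_min, "t2_max": t2_max},
    )


def quality_mask(
    t2map: T2StarMap,
    r2_min: float = 0.0,
    statuses_allowed=(FitStatus.OK,),
) -> np.ndarray:
    """Boolean volume of voxels with allowed status and r_squared >= r2_min."""
    if r2_min < 0:
        raise ValueError("r2_min must be >= 0")
    # r2_min > 1 is permitted and simply yields an empty mask
    allowed = np.isin(t2map.status, [int(s) for s in statuses_allowed])
    with np.errstate(invalid="ignore"):
        good_r2 = t2map.r_squared >= r2_min
    return allowed & good_r2
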