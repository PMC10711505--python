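"""Digital thorax phantom and multi-echo gradient-echo signal simulation.

The phantom is deliberately simple geometry with an analytic volume oracle:
two lung ellipsoids (left analytically 0.85x the right, matching the smaller
left lung seen in vivo) plus a spherical heart inside a cylindrical body.
Total analytic lung volume grows linearly with gestational age so that
volumetry, growth modelling and lacunarity all have known ground truth.

Signals follow the mono-exponential gradient-echo decay
``S(TE) = S0 * exp(-TE / T2*)`` with optional Rician noise, the noise family
of magnitude MR images.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .images import LungMask, MultiEchoImage, default_affine, LEFT_LUNG, RIGHT_LUNG

#: Echo times (ms) of the multi-echo gradient-echo EPI protocol the simulator mimics.
DEFAULT_ECHO_TIMES = (13.8, 70.4, 127.0, 183.6, 240.2)

#: Phantom label conventions (the lung labels coincide with LungMask labels).
BACKGROUND = 0
BODY = 3
HEART = 4

# Published linear reference for mean lung T2* (ms) as a function of GA (weeks);
# used as the default lung tissue value so end-to-end phantom runs land on the
# normative curve.  See lungt2star.normative.published_model().
_MEAN_SLOPE = 1.488884
_MEAN_INTERCEPT = 21.997645


@dataclass
class AcquisitionParams:
    """Multi-echo GRE acquisition metadata.

    flip_angle is metadata only — its signal effect is folded into S0.
    """

    echo_times: tuple = DEFAULT_ECHO_TIMES
    repetition_time: float = 3000.0  # ms (TR = 3 s)
    flip_angle: float = 90.0  # degrees
    voxel_size: tuple = (3.0, 3.0, 3.0)  # mm

    def __post_init__(self):
        te = np.asarray(self.echo_times, dtype=float)
        if te.size < 1 or np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValueError("echo_times must be positive and strictly increasing")
        self.echo_times = tuple(te)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size entries must be positive")
        if self.repetition_time <= 0:
            raise ValueError("repetition_time must be positive")


@dataclass
class TissueParams:
    """Signal parameters of one phantom tissue class."""

    label: int
    name: str
    s0: float
    t2star_ms: float
    heterogeneity_sd: float = 0.0  # fractional SD of a multiplicative T2* texture

    def __post_init__(self):
        if self.s0 <= 0:
            raise ValueError(f"tissue {self.name!r}: s0 must be > 0")
        if self.t2star_ms <= 0:
            raise ValueError(f"tissue {self.name!r}: t2star_ms must be > 0")
        if self.heterogeneity_sd < 0:
            raise ValueError(f"tissue {self.name!r}: heterogeneity_sd must be >= 0")


def default_tissues(ga_weeks: float, lung_heterogeneity_sd: float = 0.0) -> list[TissueParams]:
    """Default tissue set; lung T2* sits on the normative mean curve at ``ga_weeks``."""
    lung_t2 = _MEAN_SLOPE * ga_weeks + _MEAN_INTERCEPT
    return [
        TissueParams(RIGHT_LUNG, "right_lung", 1000.0, lung_t2, lung_heterogeneity_sd),
        TissueParams(LEFT_LUNG, "left_lung", 1000.0, lung_t2, lung_heterogeneity_sd),
        TissueParams(BODY, "body", 900.0, 40.0),
        TissueParams(HEART, "heart", 1100.0, 150.0),
    ]


def total_lung_volume_ml(ga_weeks: float) -> float:
    """Analytic total (right+left) lung volume in mL, linear in gestational age.

    4 mL/week from a 16-week intercept keeps >= 500 lung voxels at 3 mm
    resolution from 21 weeks onwards while staying in the range reported for
    fetal lungs over the late second and third trimesters.
    """
    return 4.0 * (ga_weeks - 16.0)


#: Left lung analytic volume as a fraction of the right.
LEFT_RIGHT_VOLUME_RATIO = 0.85

# Ellipsoid semi-axis proportions (x: lateral, y: anteroposterior, z: craniocaudal).
_LUNG_AXIS_PROPORTIONS = np.array([0.55, 0.65, 1.0])


def lung_semi_axes_mm(volume_mm3: float) -> np.ndarray:
    """Semi-axes (mm) of a lung ellipsoid of the given analytic volume."""
    p = _LUNG_AXIS_PROPORTIONS
    scale = (3.0 * volume_mm3 / (4.0 * np.pi * np.prod(p))) ** (1.0 / 3.0)
    return scale * p


@dataclass
class Phantom:
    """Label map plus ground-truth S0/T2* volumes on one grid."""

    label_map: np.ndarray
    truth_s0: np.ndarray
    truth_t2star: np.ndarray
    voxel_size: tuple
    ga_weeks: float
    affine: np.ndarray = None
    analytic_volumes_ml: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.affine is None:
            self.affine = default_affine(self.voxel_size)
        self.affine = np.asarray(self.affine, float)
        fg = self.label_map != BACKGROUND
        if np.any(self.truth_s0[fg] <= 0) or np.any(self.truth_t2star[fg] <= 0):
            raise ValueError("truth maps must be positive inside the body")

    @property
    def shape(self):
        return self.label_map.shape

    def lung_mask(self) -> LungMask:
        labels = np.where(
            np.isin(self.label_map, (RIGHT_LUNG, LEFT_LUNG)), self.label_map, 0
        ).astype(np.int16)
        return LungMask(labels, self.voxel_size, self.affine)

    def digitized_volume_ml(self, label: int) -> float:
        return float(np.sum(self.label_map == label)) * float(np.prod(self.voxel_size)) / 1000.0


def make_phantom(
    ga_weeks: float,
    grid_shape: tuple = (64, 64, 64),
    acquisition: AcquisitionParams | None = None,
    tissues: list[TissueParams] | None = None,
    seed: int | None = None,
) -> Phantom:
    """Build a thorax phantom for gestational age ``ga_weeks``.

    Geometry: body cylinder (z axis) containing a spherical heart and two lung
    ellipsoids; lungs are rasterised last so their digitised volume tracks the
    analytic ellipsoid volume.
    """
    if not 18.0 <= ga_weeks <= 40.0:
        raise ValueError(f"ga_weeks={ga_weeks} outside supported range [18, 40]")
    acquisition = acquisition or AcquisitionParams()
    tissues = tissues if tissues is not None else default_tissues(ga_weeks)
    by_label = {t.label: t for t in tissues}

    vx = np.asarray(acquisition.voxel_size, float)
    shape = tuple(int(s) for s in grid_shape)
    # voxel-centre coordinates in mm, origin at the grid centre
    coords = [
        (np.arange(n) - (n - 1) / 2.0) * v for n, v in zip(shape, vx)
    ]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    half_extent = np.array([(n - 1) / 2.0 * v for n, v in zip(shape, vx)])

    total_ml = total_lung_volume_ml(ga_weeks)
    right_mm3 = total_ml * 1000.0 / (1.0 + LEFT_RIGHT_VOLUME_RATIO)
    left_mm3 = LEFT_RIGHT_VOLUME_RATIO * right_mm3
    axes_r = lung_semi_axes_mm(right_mm3)
    axes_l = lung_semi_axes_mm(left_mm3)
    offset_r = axes_r[0] + 9.0
    offset_l = axes_l[0] + 9.0
    centers = {
        RIGHT_LUNG: (np.array([-offset_r, 0.0, 0.0]), axes_r),
        LEFT_LUNG: (np.array([offset_l, 0.0, 0.0]), axes_l),
    }
    for label, (c, ax) in centers.items():
        if np.any(np.abs(c) + ax > half_extent + 1e-9):
            raise ValueError(
                f"grid {shape} too small at GA {ga_weeks}: lung label {label} "
                f"(centre {c} mm, semi-axes {ax} mm) exceeds half-extent {half_extent} mm"
            )

    label_map = np.zeros(shape, dtype=np.int16)
    body_radius = min(60.0, 0.95 * min(half_extent[0], half_extent[1]))
    body_half_height = 0.9 * half_extent[2]
    label_map[(X**2 + Y**2 <= body_radius**2) & (np.abs(Z) <= body_half_height)] = BODY
    heart_center = np.array([0.0, 12.0, -8.0])
    heart_radius = 14.0
    inside_heart = (
        (X - heart_center[0]) ** 2
        + (Y - heart_center[1]) ** 2
        + (Z - heart_center[2]) ** 2
    ) <= heart_radius**2
    label_map[inside_heart] = HEART
    for label, (c, ax) in centers.items():
        inside = (
            ((X - c[0]) / ax[0]) ** 2
            + ((Y - c[1]) / ax[1]) ** 2
            + ((Z - c[2]) / ax[2]) ** 2
        ) <= 1.0
        label_map[inside] = label

    present = set(np.unique(label_map)) - {BACKGROUND}
    missing = sorted(present - set(by_label))
    if missing:
        raise ValueError(f"no TissueParams supplied for phantom labels {missing}")

    rng = np.random.default_rng(seed)
    truth_s0 = np.zeros(shape, dtype=float)
    truth_t2star = np.full(shape, np.inf)  # background: zero signal at any TE
    for label in sorted(present):
        t = by_label[label]
        sel = label_map == label
        truth_s0[sel] = t.s0
        t2 = np.full(int(sel.sum()), t.t2star_ms)
        if t.heterogeneity_sd > 0:
            # multiplicative lognormal texture with mean exactly 1
            sd_ln = np.sqrt(np.log1p(t.heterogeneity_sd**2))
            t2 = t2 * np.exp(rng.normal(0.0, sd_ln, size=t2.size) - sd_ln**2 / 2.0)
        truth_t2star[sel] = t2

    return Phantom(
        label_map=label_map,
        truth_s0=truth_s0,
        truth_t2star=truth_t2star,
        voxel_size=tuple(vx),
        ga_weeks=float(ga_weeks),
        analytic_volumes_ml={
            "right": right_mm3 / 1000.0,
            "left": left_mm3 / 1000.0,
            "total": total_ml,
        },
    )


NOISE_MODELS = ("rician", "gaussian", "none")


def simulate_multiecho(
    phantom: Phantom,
    acquisition: AcquisitionParams | None = None,
    snr: float | None = None,
    noise_model: str = "none",
    seed: int | None = None,
) -> MultiEchoImage:
    """Simulate a multi-echo magnitude image from a phantom.

    SNR is defined as S0(lung) / sigma, with sigma the per-channel Gaussian
    noise standard deviation.  Rician noise is applied to the magnitude; the
    'gaussian' option adds real-channel noise and clips at zero to preserve
    the magnitude-image invariant.
    """
    acquisition = acquisition or AcquisitionParams()
    if noise_model not in NOISE_MODELS:
        raise ValueError(f"unknown noise_model {noise_model!r}; expected one of {NOISE_MODELS}")
    if noise_model != "none" and (snr is None or snr <= 0):
        raise ValueError("snr must be > 0 when noise is enabled")

    te = np.asarray(acquisition.echo_times, float)
    with np.errstate(divide="ignore"):
        decay = np.exp(-te[None, None, None, :] / phantom.truth_t2star[..., None])
    signal = phantom.truth_s0[..., None] * decay

    sigma = 0.0
    if noise_model != "none":
        lungs = np.isin(phantom.label_map, (RIGHT_LUNG, LEFT_LUNG))
        ref_s0 = float(phantom.truth_s0[lungs].mean()) if lungs.any() else float(
            phantom.truth_s0.max()
        )
        sigma = ref_s0 / snr
        rng = np.random.default_rng(seed)
        if noise_model == "rician":
            re = signal + rng.normal(0.0, sigma, signal.shape)
            im = rng.normal(0.0, sigma, signal.shape)
            signal = np.hypot(re, im)
        else:  # gaussian
            signal = np.clip(signal + rng.normal(0.0, sigma, signal.shape), 0.0, None)

    return MultiEchoImage(
        data=signal,
        echo_times=te,
        voxel_size=phantom.voxel_size,
        affine=phantom.affine,
        repetition_time=acquisition.repetition_time,
        meta={"noise_model": noise_model, "snr": snr, "sigma": sigma, "seed": seed},
    )
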