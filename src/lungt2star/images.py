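"""In-memory containers for multi-echo MRI volumes, T2* maps and lung masks.

All volumes live on a common voxel grid described by a shape, an isotropic-or-not
voxel size in millimetres and a 4x4 RAS affine. Per-voxel arithmetic always uses
the header voxel size; world coordinates are never assumed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

#: Lung mask label conventions: 0 = background, 1 = right lung, 2 = left lung.
RIGHT_LUNG = 1
LEFT_LUNG = 2
VALID_MASK_LABELS = (0, RIGHT_LUNG, LEFT_LUNG)


class FitStatus(IntEnum):
    """Per-voxel outcome of a decay fit."""

    OK = 0
    CLAMPED_LOW = 1
    CLAMPED_HIGH = 2
    FAILED = 3


def default_affine(voxel_size) -> np.ndarray:
    """RAS affine with the given voxel spacing and origin at the corner voxel."""
    dx, dy, dz = voxel_size
    aff = np.diag([dx, dy, dz, 1.0])
    return aff


def grids_match(affine_a, affine_b, shape_a, shape_b, tol: float = 1e-4) -> bool:
    return tuple(shape_a) == tuple(shape_b) and np.allclose(
        np.asarray(affine_a, float), np.asarray(affine_b, float), atol=tol
    )


@dataclass
class MultiEchoImage:
    """4-D magnitude image (x, y, z, echo) with its echo-time vector in ms."""

    data: np.ndarray
    echo_times: np.ndarray
    voxel_size: tuple[float, float, float]
    affine: np.ndarray = None
    repetition_time: float = 3000.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.affine is None:
            self.affine = default_affine(self.voxel_size)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4-D multi-echo data, got {self.data.ndim}-D")
        if self.echo_times.ndim != 1 or self.echo_times.size != self.data.shape[3]:
            raise ValueError(
                f"echo count mismatch: {self.data.shape[3]} volumes vs "
                f"{self.echo_times.size} echo times"
            )
        if np.any(self.echo_times <= 0) or np.any(np.diff(self.echo_times) <= 0):
            raise ValueError("echo_times must be strictly increasing and positive")
        if np.any(self.data < 0):
            raise ValueError("magnitude data must be non-negative")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size entries must be positive")

    @property
    def shape(self):
        return self.data.shape[:3]

    @property
    def n_echoes(self) -> int:
        return self.data.shape[3]


@dataclass
class T2StarMap:
    """Voxelwise T2* (ms), S0, R^2 and fit-status volumes on one grid."""

    t2star: np.ndarray
    s0: np.ndarray
    r_squared: np.ndarray
    status: np.ndarray
    voxel_size: tuple[float, float, float]
    affine: np.ndarray = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t2star = np.asarray(self.t2star, dtype=float)
        self.s0 = np.asarray(self.s0, dtype=float)
        self.r_squared = np.asarray(self.r_squared, dtype=float)
        self.status = np.asarray(self.status, dtype=np.uint8)
        if self.affine is None:
            self.affine = default_affine(self.voxel_size)
        self.affine = np.asarray(self.affine, dtype=float)
        shapes = {a.shape for a in (self.t2star, self.s0, self.r_squared, self.status)}
        if len(shapes) != 1:
            raise ValueError("t2star/s0/r_squared/status grids differ")
        ok = self.status != FitStatus.FAILED
        if not np.all(np.isfinite(self.t2star[ok])):
            raise ValueError("non-finite T2* at voxels not flagged as failed")

    @property
    def shape(self):
        return self.t2star.shape


@dataclass
class LungMask:
    """Integer label volume: 0 background, 1 right lung, 2 left lung."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    affine: np.ndarray = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = np.rint(self.labels)
            if not np.allclose(lab, self.labels):
                raise ValueError("mask labels must be integer valued")
            self.labels = lab.astype(np.int16)
        if self.affine is None:
            self.affine = default_affine(self.voxel_size)
        self.affine = np.asarray(self.affine, dtype=float)
        bad = sorted(int(x) for x in set(np.unique(self.labels)) - set(VALID_MASK_LABELS))
        if bad:
            raise ValueError(f"unknown mask labels {bad}; allowed labels are 0, 1, 2")

    @property
    def shape(self):
        return self.labels.shape

    def roi_selector(self, roi: str) -> np.ndarray:
        """Boolean volume for ``roi`` in {'right', 'left', 'both'} (both = union)."""
        if roi == "right":
            return self.labels == RIGHT_LUNG
        if roi == "left":
            return self.labels == LEFT_LUNG
        if roi == "both":
            return self.labels > 0
        raise ValueError(f"unknown roi {roi!r}; expected 'right', 'left' or 'both'")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))
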