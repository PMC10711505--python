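"""NIfTI-1, JSON-sidecar and CSV input/output.

Multi-echo images are stored as 4-D NIfTI-1 plus a JSON sidecar carrying the
echo times (ms), TR and simulation provenance; masks and map components are
3-D NIfTI-1 on the same affine.  Readers validate rather than silently
reinterpret: wrong dimensionality, echo-count mismatches, unknown mask labels
and affine disagreements are all errors naming the offending file.
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .images import FitStatus, LungMask, MultiEchoImage, T2StarMap, VALID_MASK_LABELS

_AFFINE_TOL = 1e-4


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_multiecho(image: MultiEchoImage, path) -> Path:
    """Write a 4-D NIfTI plus JSON sidecar; returns the image path."""
    path = Path(path)
    img = nib.Nifti1Image(image.data, image.affine)
    img.header.set_zooms(tuple(image.voxel_size) + (image.repetition_time / 1000.0,))
    nib.save(img, path)
    sidecar = {
        "EchoTimes_ms": [float(t) for t in image.echo_times],
        "RepetitionTime_ms": float(image.repetition_time),
        **{k: v for k, v in image.meta.items() if _jsonable(v)},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2), encoding="utf-8")
    return path


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def read_multiecho(path) -> MultiEchoImage:
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected 4-D multi-echo image, got {data.ndim}-D")
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"{path}: missing JSON sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text(encoding="utf-8"))
    te = np.asarray(sidecar.get("EchoTimes_ms", []), float)
    if te.size != data.shape[3]:
        raise ValueError(
            f"{path}: sidecar lists {te.size} echo times but image has "
            f"{data.shape[3]} echo volumes"
        )
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    meta = {k: v for k, v in sidecar.items() if k not in ("EchoTimes_ms", "RepetitionTime_ms")}
    return MultiEchoImage(
        data=data,
        echo_times=te,
        voxel_size=voxel_size,
        affine=img.affine,
        repetition_time=float(sidecar.get("RepetitionTime_ms", 3000.0)),
        meta=meta,
    )


def write_mask(mask: LungMask, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(mask.labels.astype(np.int16), mask.affine), path)
    return path


def read_mask(path, expected_grid: tuple | None = None) -> LungMask:
    """Read a lung label mask; ``expected_grid`` is an optional (shape, affine)."""
    path = Path(path)
    img = nib.load(path)
    labels = np.asarray(img.dataobj)
    if labels.ndim != 3:
        raise ValueError(f"{path}: expected 3-D label mask, got {labels.ndim}-D")
    if not np.allclose(labels, np.rint(labels)):
        raise ValueError(f"{path}: mask is not integer valued")
    labels = np.rint(labels).astype(np.int16)
    bad = sorted(int(x) for x in set(np.unique(labels)) - set(VALID_MASK_LABELS))
    if bad:
        raise ValueError(f"{path}: unknown mask labels {bad}; allowed labels are 0, 1, 2")
    if expected_grid is not None:
        shape, affine = expected_grid
        if tuple(shape) != labels.shape or not np.allclose(
            np.asarray(affine, float), img.affine, atol=_AFFINE_TOL
        ):
            raise ValueError(
                f"{path}: grid mismatch; mask grid {labels.shape} affine\n{img.affine}\n"
                f"vs expected grid {tuple(shape)} affine\n{np.asarray(affine, float)}"
            )
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LungMask(labels, voxel_size, img.affine)


_MAP_COMPONENTS = ("t2star", "s0", "r_squared", "status")


def write_t2star_map(t2map: T2StarMap, prefix) -> dict:
    """Write the four map components as ``<prefix>_<component>.nii.gz``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {}
    for comp in _MAP_COMPONENTS:
        arr = getattr(t2map, comp)
        dtype = np.uint8 if comp == "status" else np.float64
        p = prefix.parent / f"{prefix.name}_{comp}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=dtype), t2map.affine), p)
        paths[comp] = p
    return paths


def read_t2star_map(prefix) -> T2StarMap:
    prefix = Path(prefix)
    arrays = {}
    affine = None
    voxel_size = None
    for comp in _MAP_COMPONENTS:
        p = prefix.parent / f"{prefix.name}_{comp}.nii.gz"
        if not p.exists():
            raise FileNotFoundError(f"missing T2* map component {p}")
        img = nib.load(p)
        arrays[comp] = np.asarray(img.dataobj)
        if affine is None:
            affine = img.affine
            voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
        elif not np.allclose(affine, img.affine, atol=_AFFINE_TOL):
            raise ValueError(f"{p}: affine differs from other map components")
    status = arrays["status"].astype(np.uint8)
    for comp in ("t2star", "s0", "r_squared"):
        arrays[comp] = np.where(status == FitStatus.FAILED, np.nan, arrays[comp])
    return T2StarMap(
        t2star=arrays["t2star"],
        s0=arrays["s0"],
        r_squared=arrays["r_squared"],
        status=status,
        voxel_size=voxel_size,
        affine=affine,
    )


def write_cohort(table: pd.DataFrame, path) -> Path:
    """Comma-separated, UTF-8, header row, empty string for missing values."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, na_rep="")
    return path


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
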