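"""File I/O: 4-D NIfTI dynamic images with schedule sidecars, maps, curves.

Conventions: NIfTI volumes are written x-fastest (native voxel order) with
the frame axis last, values float64 kBq/mL; the frame schedule travels in a
JSON sidecar next to the image.  Curves are 2-column CSV
(``time_s, activity_kBq_ml``); configs and run reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .curves import SampledCurve
from .errors import ScheduleMismatchError
from .protocols import DynamicImage, FrameSchedule

CURVE_COLUMNS = ("time_s", "activity_kBq_ml")


def _sidecar_path(path) -> Path:
    p = Path(path)
    name = p.name
    for suff in (".nii.gz", ".nii"):
        if name.endswith(suff):
            return p.with_name(name[: -len(suff)] + ".json")
    return p.with_suffix(".json")


def _affine(voxel_size_mm) -> np.ndarray:
    return np.diag(list(voxel_size_mm) + [1.0])


def write_dynamic(path, dyn: DynamicImage, sidecar=None) -> Path:
    """Write a dynamic image as 4-D NIfTI plus its schedule sidecar."""
    data = np.moveaxis(dyn.values, 0, -1)  # (x, y, z, t)
    img = nib.Nifti1Image(data.astype(np.float64), _affine(dyn.voxel_size_mm))
    img.header.set_data_dtype(np.float64)
    nib.save(img, str(path))
    sidecar = Path(sidecar) if sidecar else _sidecar_path(path)
    dyn.schedule.to_json(sidecar)
    return sidecar


def read_dynamic(path, sidecar=None) -> DynamicImage:
    """Read a dynamic image; frame count must match the sidecar schedule."""
    sidecar = Path(sidecar) if sidecar else _sidecar_path(path)
    if not Path(sidecar).exists():
        raise ScheduleMismatchError(f"schedule sidecar not found: {sidecar}")
    schedule = FrameSchedule.from_json(sidecar)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ScheduleMismatchError("expected a 4-D NIfTI volume")
    if data.shape[-1] != schedule.n_frames:
        raise ScheduleMismatchError(
            f"{data.shape[-1]} frames in image vs "
            f"{schedule.n_frames} in sidecar")
    vox = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DynamicImage(np.moveaxis(data, -1, 0), schedule, vox)


def write_map(path, values: np.ndarray,
              voxel_size_mm=(3.125, 3.125, 2.89)) -> None:
    """Write a 3-D parameter map or label volume as NIfTI."""
    arr = np.asarray(values)
    dtype = np.int16 if np.issubdtype(arr.dtype, np.integer) else np.float64
    img = nib.Nifti1Image(arr.astype(dtype), _affine(voxel_size_mm))
    img.header.set_data_dtype(dtype)
    nib.save(img, str(path))


def read_map(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def write_curve(path, curve: SampledCurve) -> None:
    pd.DataFrame({CURVE_COLUMNS[0]: curve.t,
                  CURVE_COLUMNS[1]: curve.v}).to_csv(path, index=False)


def read_curve(path) -> SampledCurve:
    df = pd.read_csv(path)
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ScheduleMismatchError(
            f"curve CSV must have columns {CURVE_COLUMNS}; missing {missing}")
    return SampledCurve(df[CURVE_COLUMNS[0]].to_numpy(),
                        df[CURVE_COLUMNS[1]].to_numpy())


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
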