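"""Evaluation procedures: lesion segmentation, noise surrogate, agreement.

Lesions are segmented on the gold-standard Ki map by region growing from
the hottest voxel of a search region, admitting 26-connected voxels with
value >= 90% of the regional maximum (inclusive).  Image noise is summarized
by the coefficient of variation in a uniform region (thigh-muscle VOI in
the clinical procedure).  Method agreement is reported per lesion as the
percent difference of mean Ki on a *shared* mask, summarized
Bland-Altman-style as mean +/- SD across lesions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import MaskError


def region_grow(ki_map: np.ndarray, seed=None, search_mask=None,
                threshold_frac: float = 0.9) -> np.ndarray:
    """Segment a lesion by thresholded region growing.

    Grows a 26-connected region from the maximum voxel of the search region
    (or from ``seed`` if given), admitting voxels with
    ``value >= threshold_frac * regional max`` (inclusive).  The ratio
    threshold makes the result invariant to positive rescaling of the map.
    """
    ki_map = np.asarray(ki_map, dtype=float)
    if not np.all(np.isfinite(ki_map)):
        raise MaskError("Ki map must be finite")
    if search_mask is None:
        search_mask = np.ones(ki_map.shape, dtype=bool)
    search_mask = np.asarray(search_mask, dtype=bool)
    if search_mask.shape != ki_map.shape:
        raise MaskError("search mask shape mismatch")
    if not search_mask.any():
        raise MaskError("empty search region")
    region_vals = np.where(search_mask, ki_map, -np.inf)
    peak = np.unravel_index(np.argmax(region_vals), ki_map.shape)
    if seed is not None:
        seed = tuple(int(i) for i in seed)
        if not search_mask[seed]:
            raise MaskError("seed voxel lies outside the search region")
        peak = seed
        # regional max still defines the threshold
    vmax = float(region_vals[np.unravel_index(np.argmax(region_vals),
                                              ki_map.shape)])
    cand = (ki_map >= threshold_frac * vmax) & search_mask
    structure = np.ones((3,) * ki_map.ndim, dtype=bool)  # 26-connectivity
    labeled, _ = ndimage.label(cand, structure=structure)
    if labeled[peak] == 0:
        raise MaskError("seed voxel falls below the threshold")
    return labeled == labeled[peak]


def cov(values: np.ndarray, mask: np.ndarray) -> float:
    """Coefficient of variation (sample SD / mean) within a mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != np.shape(values):
        raise MaskError("mask shape mismatch")
    v = np.asarray(values, dtype=float)[mask]
    if v.size < 2:
        raise MaskError("CoV needs at least two voxels")
    m = v.mean()
    if m == 0:
        raise ZeroDivisionError("CoV undefined for zero-mean region")
    return float(v.std(ddof=1) / m)


def equivalent_diameter_mm(mask: np.ndarray, voxel_size_mm) -> float:
    """Diameter of the sphere with the mask's total voxel volume."""
    n = int(np.asarray(mask, dtype=bool).sum())
    vol = n * float(np.prod(voxel_size_mm))
    return float(2.0 * (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0))


def lesion_compare(ref_map: np.ndarray, test_map: np.ndarray, masks,
                   voxel_size_mm=(3.125, 3.125, 2.89)):
    """Per-lesion mean-Ki agreement on shared masks, Bland-Altman summary.

    ``masks`` is a list of boolean lesion masks (identical for both maps,
    as required for a fair comparison).  Returns ``(table, summary)`` where
    ``table`` has one row per lesion and ``summary`` is
    ``{"mean_diff_pct", "sd_diff_pct", "n_lesions"}`` (SD 0 for a single
    lesion).
    """
    rows = []
    for i, m in enumerate(masks):
        m = np.asarray(m, dtype=bool)
        if not m.any():
            raise MaskError(f"lesion mask {i} is empty")
        ref_mean = float(np.asarray(ref_map, float)[m].mean())
        test_mean = float(np.asarray(test_map, float)[m].mean())
        if ref_mean == 0:
            raise ZeroDivisionError(f"reference mean of lesion {i} is zero")
        rows.append({
            "lesion": i,
            "n_voxels": int(m.sum()),
            "equivalent_diameter_mm": equivalent_diameter_mm(m, voxel_size_mm),
            "mean_ki_ref": ref_mean,
            "mean_ki_test": test_mean,
            "percent_diff": 100.0 * (test_mean - ref_mean) / ref_mean,
        })
    table = pd.DataFrame(rows)
    diffs = table["percent_diff"].to_numpy()
    summary = {
        "mean_diff_pct": float(diffs.mean()),
        "sd_diff_pct": float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0,
        "n_lesions": int(diffs.size),
    }
    return table, summary
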