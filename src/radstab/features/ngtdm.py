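"""Neighbourhood grey-tone difference matrix (NGTDM) features.

The neighbourhood of a voxel is the in-plane Chebyshev disc of radius
``distance`` (default 3) around it, restricted to ROI voxels and
excluding the voxel itself — a 2D neighbourhood applied slice by slice
over the 3D ROI.  Voxels with no ROI neighbour do not contribute.

Degenerate inputs follow the invalid-value convention: a uniform ROI has
all tone differences zero, so Coarseness is infinite (1/0) while
Contrast is defined as 0; a single-voxel ROI has no valid neighbourhood
and every feature is non-finite.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["NGTDM_FEATURE_NAMES", "ngtdm_table", "ngtdm_features_from_table",
           "ngtdm_features"]

NGTDM_FEATURE_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")


def ngtdm_table(levels: np.ndarray, n_levels: int, distance: int = 3,
                ) -> tuple[np.ndarray, np.ndarray]:
    """Per-level counts ``n_i`` and absolute tone differences ``s_i``.

    Returns arrays of length ``n_levels`` indexed by level-1.
    """
    if distance < 1:
        raise ValueError(f"distance must be >= 1, got {distance}")
    levels = np.asarray(levels)
    mask = levels > 0
    size = 2 * distance + 1
    kernel = np.ones((size, size), dtype=np.float64)
    kernel[distance, distance] = 0.0

    n_i = np.zeros(n_levels, dtype=np.int64)
    s_i = np.zeros(n_levels, dtype=np.float64)
    for z in range(levels.shape[0]):
        m = mask[z]
        if not m.any():
            continue
        lev = levels[z].astype(np.float64) * m
        neigh_sum = ndimage.convolve(lev, kernel, mode="constant", cval=0.0)
        neigh_cnt = ndimage.convolve(m.astype(np.float64), kernel,
                                     mode="constant", cval=0.0)
        valid = m & (neigh_cnt > 0.5)
        if not valid.any():
            continue
        abar = neigh_sum[valid] / neigh_cnt[valid]
        lv = levels[z][valid]
        np.add.at(n_i, lv - 1, 1)
        np.add.at(s_i, lv - 1, np.abs(lv.astype(np.float64) - abar))
    return n_i, s_i


def ngtdm_features_from_table(n_i: np.ndarray, s_i: np.ndarray) -> dict[str, float]:
    n_i = np.asarray(n_i, dtype=np.float64)
    s_i = np.asarray(s_i, dtype=np.float64)
    n_vp = n_i.sum()
    if n_vp == 0:
        return {name: np.nan for name in NGTDM_FEATURE_NAMES}
    p = n_i / n_vp
    occupied = p > 0
    levels = np.arange(1, n_i.size + 1, dtype=np.float64)
    n_gp = int(occupied.sum())

    i_occ = levels[occupied]
    p_occ = p[occupied]
    s_occ = s_i[occupied]
    ps = float(p_occ @ s_occ)

    f: dict[str, float] = {}
    f["Coarseness"] = 1.0 / ps if ps > 0 else np.inf
    if n_gp <= 1:
        f["Contrast"] = 0.0
    else:
        spread = float(np.sum(p_occ[:, None] * p_occ[None, :]
                              * (i_occ[:, None] - i_occ[None, :]) ** 2))
        f["Contrast"] = spread / (n_gp * (n_gp - 1)) * s_i.sum() / n_vp

    ipi = i_occ * p_occ
    busy_denom = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
    f["Busyness"] = ps / busy_denom if busy_denom > 0 else np.nan

    dif = np.abs(i_occ[:, None] - i_occ[None, :])
    psum = p_occ[:, None] + p_occ[None, :]
    pssum = (p_occ * s_occ)[:, None] + (p_occ * s_occ)[None, :]
    f["Complexity"] = float(np.sum(dif * pssum / psum)) / n_vp

    s_total = s_i.sum()
    strength_num = float(np.sum(psum * (i_occ[:, None] - i_occ[None, :]) ** 2))
    if s_total > 0:
        f["Strength"] = strength_num / s_total
    else:
        f["Strength"] = np.inf if strength_num > 0 else np.nan
    return f


def ngtdm_features(levels: np.ndarray, n_levels: int, distance: int = 3,
                   ) -> dict[str, float]:
    n_i, s_i = ngtdm_table(levels, n_levels, distance)
    return ngtdm_features_from_table(n_i, s_i)
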