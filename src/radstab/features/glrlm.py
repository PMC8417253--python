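"""Grey-level run-length matrices and features.

Runs are maximal sequences of equal grey level along an in-plane
direction; a run truncates at the ROI boundary (a non-ROI voxel breaks
the run).  Counts are merged across axial slices into one matrix per
direction, and features are averaged over the four in-plane directions.
"""

from __future__ import annotations

import numpy as np

__all__ = ["GLRLM_FEATURE_NAMES", "glrlm_matrices", "glrlm_features_from_matrix",
           "glrlm_features"]

GLRLM_FEATURE_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)


def _slice_lines(slice2d: np.ndarray, angle: int) -> list[np.ndarray]:
    """All scan lines of one slice for one direction angle."""
    if angle == 0:
        return [slice2d[r] for r in range(slice2d.shape[0])]
    if angle == 90:
        return [slice2d[:, c] for c in range(slice2d.shape[1])]
    if angle == 45:
        flipped = np.fliplr(slice2d)
        return [np.diagonal(flipped, offset=k)
                for k in range(-flipped.shape[0] + 1, flipped.shape[1])]
    if angle == 135:
        return [np.diagonal(slice2d, offset=k)
                for k in range(-slice2d.shape[0] + 1, slice2d.shape[1])]
    raise ValueError(f"unsupported direction angle: {angle}")


def _line_runs(line: np.ndarray, R: np.ndarray) -> None:
    """Accumulate (level, run length) counts of one line into ``R``."""
    if line.size == 0:
        return
    boundaries = np.flatnonzero(np.diff(line) != 0)
    starts = np.concatenate(([0], boundaries + 1))
    ends = np.concatenate((boundaries + 1, [line.size]))
    for s, e in zip(starts, ends):
        level = line[s]
        if level > 0:
            R[level - 1, e - s - 1] += 1


def glrlm_matrices(levels: np.ndarray, n_levels: int,
                   directions: tuple[int, ...] = (0, 45, 90, 135),
                   ) -> dict[int, np.ndarray]:
    """Run-length matrix per in-plane direction, merged across slices.

    The matrix total equals the number of runs in that direction.
    """
    levels = np.asarray(levels)
    max_len = max(levels.shape[1], levels.shape[2])
    out: dict[int, np.ndarray] = {}
    for angle in directions:
        R = np.zeros((n_levels, max_len), dtype=np.int64)
        for z in range(levels.shape[0]):
            for line in _slice_lines(levels[z], angle):
                _line_runs(np.ascontiguousarray(line), R)
        out[angle] = R
    return out


def glrlm_features_from_matrix(R: np.ndarray, n_voxels: int) -> dict[str, float]:
    R = np.asarray(R, dtype=np.float64)
    n_runs = R.sum()
    if n_runs == 0:
        return {name: np.nan for name in GLRLM_FEATURE_NAMES}
    i = np.arange(1, R.shape[0] + 1, dtype=np.float64)  # grey level
    j = np.arange(1, R.shape[1] + 1, dtype=np.float64)  # run length
    r_i = R.sum(axis=1)  # per-level run counts
    r_j = R.sum(axis=0)  # per-length run counts

    p = R / n_runs
    p_i = r_i / n_runs
    p_j = r_j / n_runs
    mu_i = float(p_i @ i)
    mu_j = float(p_j @ j)

    f: dict[str, float] = {}
    f["ShortRunEmphasis"] = float((r_j / j ** 2).sum() / n_runs)
    f["LongRunEmphasis"] = float((r_j * j ** 2).sum() / n_runs)
    f["GrayLevelNonUniformity"] = float((r_i ** 2).sum() / n_runs)
    f["GrayLevelNonUniformityNormalized"] = float((r_i ** 2).sum() / n_runs ** 2)
    f["RunLengthNonUniformity"] = float((r_j ** 2).sum() / n_runs)
    f["RunLengthNonUniformityNormalized"] = float((r_j ** 2).sum() / n_runs ** 2)
    f["RunPercentage"] = float(n_runs / n_voxels)
    f["GrayLevelVariance"] = float(p_i @ (i - mu_i) ** 2)
    f["RunVariance"] = float(p_j @ (j - mu_j) ** 2)
    nz = p > 0
    f["RunEntropy"] = float(-np.sum(p[nz] * np.log2(p[nz])))
    f["LowGrayLevelRunEmphasis"] = float((r_i / i ** 2).sum() / n_runs)
    f["HighGrayLevelRunEmphasis"] = float((r_i * i ** 2).sum() / n_runs)
    inv_i2 = 1.0 / i ** 2
    inv_j2 = 1.0 / j ** 2
    f["ShortRunLowGrayLevelEmphasis"] = float(inv_i2 @ R @ inv_j2 / n_runs)
    f["ShortRunHighGrayLevelEmphasis"] = float((i ** 2) @ R @ inv_j2 / n_runs)
    f["LongRunLowGrayLevelEmphasis"] = float(inv_i2 @ R @ (j ** 2) / n_runs)
    f["LongRunHighGrayLevelEmphasis"] = float((i ** 2) @ R @ (j ** 2) / n_runs)
    return f


def glrlm_features(levels: np.ndarray, n_levels: int,
                   directions: tuple[int, ...] = (0, 45, 90, 135),
                   ) -> dict[str, float]:
    """Direction-averaged run-length features for a discretized ROI."""
    n_voxels = int((np.asarray(levels) > 0).sum())
    if n_voxels == 0:
        raise ValueError("empty ROI")
    mats = glrlm_matrices(levels, n_levels, directions)
    per_dir = [glrlm_features_from_matrix(R, n_voxels) for R in mats.values()]
    return {name: float(np.mean([d[name] for d in per_dir]))
            for name in GLRLM_FEATURE_NAMES}
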