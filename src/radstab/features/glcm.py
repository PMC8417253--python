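"""Grey-level co-occurrence matrices and Haralick-style features.

Co-occurrence counts are accumulated in the axial plane (fixed ``z``)
over the whole 3D ROI: pairs are collected slice by slice for each
in-plane direction and merged across slices before normalization, giving
one matrix per (direction, distance).  Both voxels of a pair must lie in
the ROI.  In asymmetric mode only the ordered pair ``(i, j)`` along the
direction is counted; in symmetric mode the transposed pair is added.

Features are computed per direction from the normalized matrix and then
averaged over directions.  Degenerate matrices (single occupied level,
zero marginal variance) yield non-finite feature values, never errors.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["GLCM_FEATURE_NAMES", "DIRECTIONS", "glcm_matrices",
           "glcm_features_from_matrix", "glcm_features"]

# In-plane direction angles and their (dy, dx) unit offsets; rows (y) grow
# downward, so 45 deg is "up-right".
DIRECTIONS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}

GLCM_FEATURE_NAMES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "InverseDifference", "InverseDifferenceMoment",
    "InverseDifferenceMomentNormalized", "InverseDifferenceNormalized",
    "InverseVariance", "MaximumProbability", "SumAverage", "SumEntropy",
    "SumSquares", "MCC", "SumVariance", "Dissimilarity",
)


def _pair_counts(levels: np.ndarray, mask: np.ndarray, n_levels: int,
                 dy: int, dx: int) -> np.ndarray:
    """Ordered co-occurrence counts for one slice and one (dy, dx) offset."""
    ny, nx = levels.shape
    y0a, y1a = max(0, -dy), min(ny, ny - dy)
    x0a, x1a = max(0, -dx), min(nx, nx - dx)
    if y0a >= y1a or x0a >= x1a:
        return np.zeros((n_levels, n_levels), dtype=np.int64)
    a = levels[y0a:y1a, x0a:x1a]
    b = levels[y0a + dy:y1a + dy, x0a + dx:x1a + dx]
    ma = mask[y0a:y1a, x0a:x1a]
    mb = mask[y0a + dy:y1a + dy, x0a + dx:x1a + dx]
    valid = ma & mb
    if not valid.any():
        return np.zeros((n_levels, n_levels), dtype=np.int64)
    flat = (a[valid] - 1) * n_levels + (b[valid] - 1)
    return np.bincount(flat, minlength=n_levels * n_levels).reshape(n_levels, n_levels)


def glcm_matrices(levels: np.ndarray, n_levels: int, distance: int,
                  symmetric: bool,
                  directions: tuple[int, ...] = (0, 45, 90, 135),
                  ) -> dict[int, np.ndarray | None]:
    """Normalized co-occurrence matrix per direction, merged across slices.

    ``levels`` is a (z, y, x) integer array with ROI voxels at 1..n_levels
    and background 0.  Directions with no valid voxel pair are flagged
    ``None`` (empty).
    """
    if distance < 1:
        raise ValueError(f"distance must be >= 1, got {distance}")
    levels = np.asarray(levels)
    mask = levels > 0
    out: dict[int, np.ndarray | None] = {}
    for angle in directions:
        dy, dx = DIRECTIONS[angle]
        dy, dx = dy * distance, dx * distance
        counts = np.zeros((n_levels, n_levels), dtype=np.int64)
        for z in range(levels.shape[0]):
            counts += _pair_counts(levels[z], mask[z], n_levels, dy, dx)
        if symmetric:
            counts = counts + counts.T
        total = counts.sum()
        out[angle] = None if total == 0 else counts / total
    return out


def glcm_features_from_matrix(P: np.ndarray) -> dict[str, float]:
    """All supported co-occurrence features from one normalized matrix."""
    n = P.shape[0]
    i = np.arange(1, n + 1, dtype=np.float64)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(px @ i)
    mu_y = float(py @ i)
    var_x = float(px @ (i - mu_x) ** 2)
    var_y = float(py @ (i - mu_y) ** 2)

    ii = i[:, None]
    jj = i[None, :]
    diff = np.abs(ii - jj)

    # p_{x-y}(k), k = 0..n-1 and p_{x+y}(k), k = 2..2n
    k_diff = np.arange(0, n, dtype=np.float64)
    p_diff = np.zeros(n)
    np.add.at(p_diff, diff.astype(np.int64).ravel(), P.ravel())
    k_sum = np.arange(2, 2 * n + 1, dtype=np.float64)
    p_sum = np.zeros(2 * n - 1)
    np.add.at(p_sum, (ii + jj).astype(np.int64).ravel() - 2, P.ravel())

    def xlog2(p: np.ndarray) -> np.ndarray:
        out = np.zeros_like(p)
        nz = p > 0
        out[nz] = p[nz] * np.log2(p[nz])
        return out

    f: dict[str, float] = {}
    f["Autocorrelation"] = float(np.sum(P * ii * jj))
    f["JointAverage"] = mu_x
    centered = ii + jj - mu_x - mu_y
    f["ClusterProminence"] = float(np.sum(P * centered ** 4))
    f["ClusterShade"] = float(np.sum(P * centered ** 3))
    f["ClusterTendency"] = float(np.sum(P * centered ** 2))
    f["Contrast"] = float(np.sum(P * (ii - jj) ** 2))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        denom = np.sqrt(var_x * var_y)
        f["Correlation"] = (
            (f["Autocorrelation"] - mu_x * mu_y) / denom if denom > 0 else np.nan
        )
    da = float(k_diff @ p_diff)
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = float(-np.sum(xlog2(p_diff)))
    f["DifferenceVariance"] = float(p_diff @ (k_diff - da) ** 2)
    f["JointEnergy"] = float(np.sum(P ** 2))
    hxy = float(-np.sum(xlog2(P)))
    f["JointEntropy"] = hxy
    hx = float(-np.sum(xlog2(px)))
    hy = float(-np.sum(xlog2(py)))
    pxpy = px[:, None] * py[None, :]
    log_pxpy = np.zeros_like(pxpy)
    nz = pxpy > 0
    log_pxpy[nz] = np.log2(pxpy[nz])
    hxy1 = float(-np.sum(P * log_pxpy))
    hxy2 = float(-np.sum(xlog2(pxpy)))
    denom = max(hx, hy)
    f["Imc1"] = (hxy - hxy1) / denom if denom > 0 else np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        f["Imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    f["InverseDifference"] = float(np.sum(P / (1.0 + diff)))
    f["InverseDifferenceMoment"] = float(np.sum(P / (1.0 + (ii - jj) ** 2)))
    f["InverseDifferenceMomentNormalized"] = float(np.sum(P / (1.0 + ((ii - jj) / n) ** 2)))
    f["InverseDifferenceNormalized"] = float(np.sum(P / (1.0 + diff / n)))
    off = diff > 0
    f["InverseVariance"] = float(np.sum(P[off] / (ii - jj)[off] ** 2))
    f["MaximumProbability"] = float(P.max())
    sa = float(k_sum @ p_sum)
    f["SumAverage"] = sa
    f["SumEntropy"] = float(-np.sum(xlog2(p_sum)))
    f["SumVariance"] = float(p_sum @ (k_sum - sa) ** 2)
    f["SumSquares"] = float(np.sum(P * (ii - mu_x) ** 2))
    f["Dissimilarity"] = float(np.sum(P * diff))
    f["MCC"] = _mcc(P, px, py)
    return f


def _mcc(P: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    """Maximal correlation coefficient: sqrt of the second-largest eigenvalue
    of Q_{ij} = sum_k P(i,k) P(j,k) / (px_i py_k), on occupied levels."""
    rows = px > 0
    cols = py > 0
    if rows.sum() <= 1 or cols.sum() <= 1:
        return 1.0
    Psub = P[np.ix_(rows, cols)]
    Q = (Psub / px[rows, None]) @ (Psub / py[cols]).T
    try:
        eig = np.linalg.eigvals(Q)
    except np.linalg.LinAlgError:  # pragma: no cover
        return np.nan
    eig = np.sort(eig.real)[::-1]
    return float(np.sqrt(max(0.0, eig[1])))


def glcm_features(matrices: dict[int, np.ndarray | None]) -> dict[str, float]:
    """Direction-averaged features from per-direction matrices.

    Empty (``None``) directions are excluded from the average; if every
    direction is empty all features are NaN.
    """
    per_dir = [glcm_features_from_matrix(P) for P in matrices.values() if P is not None]
    if not per_dir:
        return {name: np.nan for name in GLCM_FEATURE_NAMES}
    return {name: float(np.mean([d[name] for d in per_dir])) for name in GLCM_FEATURE_NAMES}
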