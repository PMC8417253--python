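"""Independent brute-force oracles for texture, intensity and similarity.

Everything here is written as plain enumeration — explicit voxel walks
and double loops over matrix entries — deliberately avoiding the
vectorized code paths of the package so the two implementations can
cross-check each other.
"""

from __future__ import annotations

import math

import numpy as np

ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix_bruteforce(levels, n_levels, distance, angle, symmetric):
    """Co-occurrence counts by walking every voxel pair explicitly."""
    levels = np.asarray(levels)
    dy, dx = ANGLE_OFFSETS[angle]
    dy, dx = dy * distance, dx * distance
    counts = np.zeros((n_levels, n_levels))
    nz, ny, nx = levels.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                a = levels[z, y, x]
                if a == 0:
                    continue
                y2, x2 = y + dy, x + dx
                if 0 <= y2 < ny and 0 <= x2 < nx:
                    b = levels[z, y2, x2]
                    if b > 0:
                        counts[a - 1, b - 1] += 1
                        if symmetric:
                            counts[b - 1, a - 1] += 1
    total = counts.sum()
    return None if total == 0 else counts / total


def glcm_features_bruteforce(P):
    """Every co-occurrence feature by explicit double loops."""
    n = P.shape[0]
    px = [sum(P[i][j] for j in range(n)) for i in range(n)]
    py = [sum(P[i][j] for i in range(n)) for j in range(n)]
    mu_x = sum((i + 1) * px[i] for i in range(n))
    mu_y = sum((j + 1) * py[j] for j in range(n))
    var_x = sum(px[i] * (i + 1 - mu_x) ** 2 for i in range(n))
    var_y = sum(py[j] * (j + 1 - mu_y) ** 2 for j in range(n))

    p_diff = [0.0] * n
    p_sum = [0.0] * (2 * n - 1)
    for i in range(n):
        for j in range(n):
            p_diff[abs(i - j)] += P[i][j]
            p_sum[i + j] += P[i][j]

    f = {}
    f["Autocorrelation"] = sum(P[i][j] * (i + 1) * (j + 1)
                               for i in range(n) for j in range(n))
    f["JointAverage"] = mu_x
    for name, power in (("ClusterTendency", 2), ("ClusterShade", 3),
                        ("ClusterProminence", 4)):
        f[name] = sum(P[i][j] * (i + j + 2 - mu_x - mu_y) ** power
                      for i in range(n) for j in range(n))
    f["Contrast"] = sum(P[i][j] * (i - j) ** 2 for i in range(n) for j in range(n))
    denom = math.sqrt(var_x * var_y)
    f["Correlation"] = ((f["Autocorrelation"] - mu_x * mu_y) / denom
                        if denom > 0 else np.nan)
    da = sum(k * p_diff[k] for k in range(n))
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = -sum(p * math.log2(p) for p in p_diff if p > 0)
    f["DifferenceVariance"] = sum(p_diff[k] * (k - da) ** 2 for k in range(n))
    f["JointEnergy"] = sum(P[i][j] ** 2 for i in range(n) for j in range(n))
    hxy = -sum(P[i][j] * math.log2(P[i][j])
               for i in range(n) for j in range(n) if P[i][j] > 0)
    f["JointEntropy"] = hxy
    hx = -sum(p * math.log2(p) for p in px if p > 0)
    hy = -sum(p * math.log2(p) for p in py if p > 0)
    hxy1 = -sum(P[i][j] * math.log2(px[i] * py[j])
                for i in range(n) for j in range(n)
                if P[i][j] > 0 and px[i] * py[j] > 0)
    hxy2 = -sum(px[i] * py[j] * math.log2(px[i] * py[j])
                for i in range(n) for j in range(n) if px[i] * py[j] > 0)
    f["Imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else np.nan
    f["Imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    f["InverseDifference"] = sum(P[i][j] / (1 + abs(i - j))
                                 for i in range(n) for j in range(n))
    f["InverseDifferenceMoment"] = sum(P[i][j] / (1 + (i - j) ** 2)
                                       for i in range(n) for j in range(n))
    f["InverseDifferenceMomentNormalized"] = sum(
        P[i][j] / (1 + ((i - j) / n) ** 2) for i in range(n) for j in range(n))
    f["InverseDifferenceNormalized"] = sum(
        P[i][j] / (1 + abs(i - j) / n) for i in range(n) for j in range(n))
    f["InverseVariance"] = sum(P[i][j] / (i - j) ** 2
                               for i in range(n) for j in range(n) if i != j)
    f["MaximumProbability"] = max(P[i][j] for i in range(n) for j in range(n))
    sa = sum((k + 2) * p_sum[k] for k in range(2 * n - 1))
    f["SumAverage"] = sa
    f["SumEntropy"] = -sum(p * math.log2(p) for p in p_sum if p > 0)
    f["SumVariance"] = sum(p_sum[k] * (k + 2 - sa) ** 2 for k in range(2 * n - 1))
    f["SumSquares"] = sum(P[i][j] * (i + 1 - mu_x) ** 2
                          for i in range(n) for j in range(n))
    f["Dissimilarity"] = sum(P[i][j] * abs(i - j) for i in range(n) for j in range(n))

    rows = [i for i in range(n) if px[i] > 0]
    cols = [k for k in range(n) if py[k] > 0]
    if len(rows) <= 1 or len(cols) <= 1:
        f["MCC"] = 1.0
    else:
        Q = np.zeros((len(rows), len(rows)))
        for a, i in enumerate(rows):
            for b, j in enumerate(rows):
                Q[a, b] = sum(P[i][k] * P[j][k] / (px[i] * py[k]) for k in cols)
        eig = sorted(np.linalg.eigvals(Q).real, reverse=True)
        f["MCC"] = math.sqrt(max(0.0, eig[1]))
    return f


# ---------------------------------------------------------------------------
# GLRLM


def glrlm_matrix_bruteforce(levels, n_levels, angle):
    """Run-length counts by walking each scan line voxel by voxel."""
    levels = np.asarray(levels)
    nz, ny, nx = levels.shape
    dy, dx = ANGLE_OFFSETS[angle]
    max_len = max(ny, nx)
    R = np.zeros((n_levels, max_len))
    for z in range(nz):
        # starting points: voxels with no predecessor along (dy, dx)
        for y in range(ny):
            for x in range(nx):
                py_, px_ = y - dy, x - dx
                if 0 <= py_ < ny and 0 <= px_ < nx:
                    continue  # has a predecessor: not a line start
                # walk the line
                run_level, run_len = 0, 0
                cy, cx = y, x
                while 0 <= cy < ny and 0 <= cx < nx:
                    v = levels[z, cy, cx]
                    if v == run_level and v > 0:
                        run_len += 1
                    else:
                        if run_level > 0:
                            R[run_level - 1, run_len - 1] += 1
                        run_level, run_len = v, (1 if v > 0 else 0)
                    cy, cx = cy + dy, cx + dx
                if run_level > 0:
                    R[run_level - 1, run_len - 1] += 1
    return R


def glrlm_features_bruteforce(R, n_voxels):
    n_levels, max_len = R.shape
    n_runs = R.sum()
    if n_runs == 0:
        return None
    f = {}
    f["ShortRunEmphasis"] = sum(R[i][j] / (j + 1) ** 2
                                for i in range(n_levels) for j in range(max_len)) / n_runs
    f["LongRunEmphasis"] = sum(R[i][j] * (j + 1) ** 2
                               for i in range(n_levels) for j in range(max_len)) / n_runs
    r_i = [sum(R[i][j] for j in range(max_len)) for i in range(n_levels)]
    r_j = [sum(R[i][j] for i in range(n_levels)) for j in range(max_len)]
    f["GrayLevelNonUniformity"] = sum(v ** 2 for v in r_i) / n_runs
    f["GrayLevelNonUniformityNormalized"] = sum(v ** 2 for v in r_i) / n_runs ** 2
    f["RunLengthNonUniformity"] = sum(v ** 2 for v in r_j) / n_runs
    f["RunLengthNonUniformityNormalized"] = sum(v ** 2 for v in r_j) / n_runs ** 2
    f["RunPercentage"] = n_runs / n_voxels
    mu_i = sum((i + 1) * r_i[i] for i in range(n_levels)) / n_runs
    mu_j = sum((j + 1) * r_j[j] for j in range(max_len)) / n_runs
    f["GrayLevelVariance"] = sum(r_i[i] * (i + 1 - mu_i) ** 2
                                 for i in range(n_levels)) / n_runs
    f["RunVariance"] = sum(r_j[j] * (j + 1 - mu_j) ** 2
                           for j in range(max_len)) / n_runs
    f["RunEntropy"] = -sum((R[i][j] / n_runs) * math.log2(R[i][j] / n_runs)
                           for i in range(n_levels) for j in range(max_len)
                           if R[i][j] > 0)
    f["LowGrayLevelRunEmphasis"] = sum(r_i[i] / (i + 1) ** 2
                                       for i in range(n_levels)) / n_runs
    f["HighGrayLevelRunEmphasis"] = sum(r_i[i] * (i + 1) ** 2
                                        for i in range(n_levels)) / n_runs
    f["ShortRunLowGrayLevelEmphasis"] = sum(
        R[i][j] / ((i + 1) ** 2 * (j + 1) ** 2)
        for i in range(n_levels) for j in range(max_len)) / n_runs
    f["ShortRunHighGrayLevelEmphasis"] = sum(
        R[i][j] * (i + 1) ** 2 / (j + 1) ** 2
        for i in range(n_levels) for j in range(max_len)) / n_runs
    f["LongRunLowGrayLevelEmphasis"] = sum(
        R[i][j] * (j + 1) ** 2 / (i + 1) ** 2
        for i in range(n_levels) for j in range(max_len)) / n_runs
    f["LongRunHighGrayLevelEmphasis"] = sum(
        R[i][j] * (i + 1) ** 2 * (j + 1) ** 2
        for i in range(n_levels) for j in range(max_len)) / n_runs
    return f


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_features_bruteforce(levels, n_levels, distance=3):
    """Per-voxel neighbourhood enumeration and explicit feature loops."""
    levels = np.asarray(levels)
    nz, ny, nx = levels.shape
    n_i = [0] * n_levels
    s_i = [0.0] * n_levels
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                v = levels[z, y, x]
                if v == 0:
                    continue
                neigh = []
                for dy in range(-distance, distance + 1):
                    for dx in range(-distance, distance + 1):
                        if dy == 0 and dx == 0:
                            continue
                        y2, x2 = y + dy, x + dx
                        if 0 <= y2 < ny and 0 <= x2 < nx and levels[z, y2, x2] > 0:
                            neigh.append(levels[z, y2, x2])
                if not neigh:
                    continue
                n_i[v - 1] += 1
                s_i[v - 1] += abs(v - sum(neigh) / len(neigh))

    n_vp = sum(n_i)
    if n_vp == 0:
        return {k: np.nan for k in
                ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")}
    p = [c / n_vp for c in n_i]
    occ = [i for i in range(n_levels) if p[i] > 0]
    n_gp = len(occ)
    ps = sum(p[i] * s_i[i] for i in occ)

    f = {}
    f["Coarseness"] = 1.0 / ps if ps > 0 else np.inf
    if n_gp <= 1:
        f["Contrast"] = 0.0
    else:
        spread = sum(p[i] * p[j] * (i - j) ** 2 for i in occ for j in occ)
        f["Contrast"] = spread / (n_gp * (n_gp - 1)) * sum(s_i) / n_vp
    busy_denom = sum(abs((i + 1) * p[i] - (j + 1) * p[j]) for i in occ for j in occ)
    f["Busyness"] = ps / busy_denom if busy_denom > 0 else np.nan
    f["Complexity"] = sum(abs(i - j) * (p[i] * s_i[i] + p[j] * s_i[j])
                          / (p[i] + p[j]) for i in occ for j in occ) / n_vp
    s_total = sum(s_i)
    num = sum((p[i] + p[j]) * (i - j) ** 2 for i in occ for j in occ)
    if s_total > 0:
        f["Strength"] = num / s_total
    else:
        f["Strength"] = np.inf if num > 0 else np.nan
    return f


# ---------------------------------------------------------------------------
# intensity and similarity


def intensity_moments_bruteforce(values):
    """Naive two-pass mean/variance/skewness/kurtosis."""
    x = list(map(float, values))
    n = len(x)
    mu = sum(x) / n
    m2 = sum((v - mu) ** 2 for v in x) / n
    if m2 == 0:
        return mu, 0.0, np.nan, np.nan
    m3 = sum((v - mu) ** 3 for v in x) / n
    m4 = sum((v - mu) ** 4 for v in x) / n
    return mu, m2, m3 / m2 ** 1.5, m4 / m2 ** 2


def similarity_bruteforce(groups_ref: dict[str, str], groups_alt: dict[str, str]):
    """The printed similarity equation evaluated term by term."""
    patients = sorted(groups_ref)
    n = len(patients)
    direct = sum(1 for p in patients if groups_ref[p] == groups_alt[p])
    swap = {"A": "B", "B": "A"}
    swapped = sum(1 for p in patients if groups_ref[p] == swap[groups_alt[p]])
    return max(direct, swapped) / n * 100.0
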