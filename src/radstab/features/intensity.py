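"""First-order intensity-histogram features.

Moment and percentile statistics are computed on the raw ROI intensities;
histogram statistics (Entropy, Uniformity, Mode and the ``Discretized*``
family) use the discretized grey levels.  Moments use population
denominators.  A zero-variance ROI yields non-finite skewness/kurtosis
and zero histogram entropy.
"""

from __future__ import annotations

import numpy as np

from .discretization import DiscretizationSpec

__all__ = ["INTENSITY_FEATURE_NAMES", "intensity_features"]

INTENSITY_FEATURE_NAMES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "Percentile10",
    "Percentile90", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
    "Percentile25", "Percentile75", "GlobalStandardDeviation",
    "MedianAbsoluteDeviation", "CoefficientOfVariation", "Mode",
    "Percentile1", "Percentile50", "Percentile99", "DiscretizedMean",
    "DiscretizedVariance", "DiscretizedSkewness", "DiscretizedKurtosis",
    "DiscretizedEntropy",
)


def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, population variance, skewness, Pearson kurtosis)."""
    mu = float(x.mean())
    d = x - mu
    m2 = float(np.mean(d ** 2))
    if m2 == 0:
        return mu, 0.0, np.nan, np.nan
    m3 = float(np.mean(d ** 3))
    m4 = float(np.mean(d ** 4))
    return mu, m2, m3 / m2 ** 1.5, m4 / m2 ** 2


def intensity_features(values: np.ndarray, levels: np.ndarray,
                       spec: DiscretizationSpec, voxel_volume: float,
                       policy: str = "fixed-anchor") -> dict[str, float]:
    """All supported first-order features of one ROI.

    ``values`` are the raw ROI intensities, ``levels`` the matching
    1-based discretized grey levels.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    g = np.asarray(levels, dtype=np.int64).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")

    counts = np.bincount(g - 1, minlength=spec.n_bins).astype(np.float64)
    p = counts / counts.sum()
    nz = p > 0
    entropy = float(-np.sum(p[nz] * np.log2(p[nz])))
    uniformity = float(np.sum(p ** 2))

    mu, var, skew, kurt = _moments(x)
    p1, p10, p25, p50, p75, p90, p99 = np.percentile(x, [1, 10, 25, 50, 75, 90, 99])

    f: dict[str, float] = {}
    f["Energy"] = float(np.sum(x ** 2))
    f["TotalEnergy"] = f["Energy"] * voxel_volume
    f["Entropy"] = entropy
    f["Minimum"] = float(x.min())
    f["Percentile10"] = float(p10)
    f["Percentile90"] = float(p90)
    f["Maximum"] = float(x.max())
    f["Mean"] = mu
    f["Median"] = float(np.median(x))
    f["InterquartileRange"] = float(p75 - p25)
    f["Range"] = float(x.max() - x.min())
    f["MeanAbsoluteDeviation"] = float(np.mean(np.abs(x - mu)))
    mid = x[(x >= p10) & (x <= p90)]
    f["RobustMeanAbsoluteDeviation"] = (
        float(np.mean(np.abs(mid - mid.mean()))) if mid.size else np.nan
    )
    f["RootMeanSquared"] = float(np.sqrt(np.mean(x ** 2)))
    f["Skewness"] = skew
    f["Kurtosis"] = kurt
    f["Variance"] = var
    f["Uniformity"] = uniformity
    f["Percentile25"] = float(p25)
    f["Percentile75"] = float(p75)
    f["GlobalStandardDeviation"] = float(np.sqrt(var))
    med = float(np.median(x))
    f["MedianAbsoluteDeviation"] = float(np.median(np.abs(x - med)))
    f["CoefficientOfVariation"] = np.sqrt(var) / mu if mu != 0 else np.nan
    mode_level = int(np.argmax(counts)) + 1
    if policy == "fixed-anchor":
        f["Mode"] = spec.range_anchor + (mode_level - 0.5) * spec.bin_width
    else:
        f["Mode"] = float(mode_level)
    f["Percentile1"] = float(p1)
    f["Percentile50"] = float(p50)
    f["Percentile99"] = float(p99)
    gmu, gvar, gskew, gkurt = _moments(g.astype(np.float64))
    f["DiscretizedMean"] = gmu
    f["DiscretizedVariance"] = gvar
    f["DiscretizedSkewness"] = gskew
    f["DiscretizedKurtosis"] = gkurt
    f["DiscretizedEntropy"] = entropy
    return f
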