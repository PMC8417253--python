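"""Grey-level discretization of ROI intensities.

Two policies are supported:

* ``fixed-anchor``: bin ``l`` (1-based) of value ``v`` is
  ``floor((v - range_anchor) / bin_width)`` clamped to ``[0, n_bins - 1]``,
  then reported 1-based.  With 256 bins of width 16 anchored at 0 this
  covers the full 0..4095 ADC range.
* ``full-observed-range``: the observed ROI minimum..maximum is divided
  into ``n_bins`` equal bins, emulating software in which a fixed
  intensity range cannot be configured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiscretizationSpec", "discretize", "discretize_values"]


@dataclass(frozen=True)
class DiscretizationSpec:
    n_bins: int
    bin_width: float
    range_anchor: float = 0.0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")
        if self.bin_width <= 0:
            raise ValueError(f"bin_width must be > 0, got {self.bin_width}")


def discretize_values(values: np.ndarray, spec: DiscretizationSpec,
                      policy: str = "fixed-anchor") -> np.ndarray:
    """Map intensities to integer grey levels ``1..n_bins``."""
    values = np.asarray(values, dtype=np.float64)
    if policy == "fixed-anchor":
        idx = np.floor((values - spec.range_anchor) / spec.bin_width)
    elif policy == "full-observed-range":
        vmin = values.min()
        vmax = values.max()
        if vmax == vmin:
            return np.ones(values.shape, dtype=np.int64)
        width = (vmax - vmin) / spec.n_bins
        idx = np.floor((values - vmin) / width)
    else:
        raise ValueError(f"unknown intensity-range policy: {policy!r}")
    idx = np.clip(idx, 0, spec.n_bins - 1).astype(np.int64)
    return idx + 1


def discretize(image, mask, spec: DiscretizationSpec,
               policy: str = "fixed-anchor") -> np.ndarray:
    """Discretize the ROI of ``image``; non-ROI voxels are set to level 0.

    Returns an integer array of the image's shape where ROI voxels carry
    levels ``1..n_bins`` and background voxels are 0.
    """
    m = np.asarray(mask.values) > 0
    if not m.any():
        raise ValueError("empty ROI: nothing to discretize")
    out = np.zeros(image.values.shape, dtype=np.int64)
    out[m] = discretize_values(image.values[m], spec, policy=policy)
    return out
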