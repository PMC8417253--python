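"""Synthetic longitudinal ADC-like phantom cohorts and paired feature tables.

The generator emulates a radiotherapy imaging study: each patient has a
tumour-like ellipsoidal region of interest imaged at 8 time points
(baseline TP0, six on-treatment weeks TP1-TP6, post-treatment TP7) on a
quantitative map with ADC-like units (1e-6 mm^2/s, clipped to 0..4095).
Two latent patient groups follow different trajectories of ROI mean
intensity, intensity spread and ROI radius: a "responding" group whose
ADC rises and whose tumour shrinks through therapy, and a slowly
changing group.  Ground-truth group labels are retained so downstream
clustering can be validated.

Voxel values are a deterministic radial texture standardized to the
configured spread, plus additive Gaussian noise; with ``noise_sd = 0``
the ROI mean equals the configured trajectory mean exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .image_io import FeatureId, FeatureTable, ROIMask, VolumetricImage, write_volume

__all__ = ["GroupTrajectory", "CohortConfig", "LongitudinalCase",
           "PairedSimSpec", "generate_cohort", "generate_paired_features",
           "paired_registry", "make_phantom_roi", "write_cohort"]

N_TIMEPOINTS_DEFAULT = 8


@dataclass(frozen=True)
class GroupTrajectory:
    """Per-timepoint ROI mean intensity, intensity spread and radius (mm)."""

    mean: tuple[float, ...]
    spread: tuple[float, ...]
    radius_mm: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.mean)
        if not (len(self.spread) == n and len(self.radius_mm) == n):
            raise ValueError("trajectory fields must have equal length")
        if any(r <= 0 for r in self.radius_mm):
            raise ValueError("radii must be positive")


def _default_trajectories() -> dict[str, GroupTrajectory]:
    # Group A: ADC rises ~50% through therapy and the tumour shrinks
    # (a typical responder pattern); group B changes slowly.
    return {
        "A": GroupTrajectory(
            mean=(1100.0, 1180.0, 1270.0, 1360.0, 1450.0, 1540.0, 1630.0, 1750.0),
            spread=(180.0, 185.0, 190.0, 195.0, 200.0, 205.0, 210.0, 220.0),
            radius_mm=(14.0, 13.2, 12.4, 11.6, 10.8, 10.0, 9.2, 8.0),
        ),
        "B": GroupTrajectory(
            mean=(1100.0, 1115.0, 1130.0, 1140.0, 1150.0, 1160.0, 1170.0, 1180.0),
            spread=(180.0,) * 8,
            radius_mm=(14.0, 13.8, 13.6, 13.4, 13.2, 13.0, 12.8, 12.6),
        ),
    }


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 36
    n_timepoints: int = N_TIMEPOINTS_DEFAULT
    grid_shape: tuple[int, int, int] = (12, 48, 48)  # (z, y, x) voxels
    voxel_spacing: tuple[float, float, float] = (4.0, 2.0, 2.0)  # mm
    intensity_range: tuple[float, float] = (0.0, 4095.0)
    group_fractions: tuple[float, float] = (0.5, 0.5)
    trajectory_params: dict[str, GroupTrajectory] = field(
        default_factory=_default_trajectories)
    # aspect of the ellipsoid radii (z, y, x) relative to radius_mm
    roi_aspect: tuple[float, float, float] = (0.6, 1.0, 1.0)
    noise_sd: float = 60.0  # additive Gaussian voxel noise, map units
    rician: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if abs(sum(self.group_fractions) - 1.0) > 1e-9:
            raise ValueError(f"group_fractions must sum to 1: {self.group_fractions}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel spacing must be positive: {self.voxel_spacing}")
        adapted = {}
        for label, traj in self.trajectory_params.items():
            if len(traj.mean) < self.n_timepoints:
                raise ValueError(
                    f"group {label!r} trajectory length {len(traj.mean)} "
                    f"< n_timepoints {self.n_timepoints}")
            # longer trajectories (e.g. the 8-point defaults) truncate to
            # the requested study length
            n = self.n_timepoints
            traj = GroupTrajectory(mean=traj.mean[:n], spread=traj.spread[:n],
                                   radius_mm=traj.radius_mm[:n])
            adapted[label] = traj
        object.__setattr__(self, "trajectory_params", adapted)
        for label, traj in adapted.items():
            for r in traj.radius_mm:
                radii_vox = [r * a / s for a, s in
                             zip(self.roi_aspect, self.voxel_spacing)]
                if any(2 * rv + 3 > g for rv, g in zip(radii_vox, self.grid_shape)):
                    raise ValueError(
                        f"grid {self.grid_shape} too small for ROI radius {r} mm "
                        f"(group {label!r})")


@dataclass
class LongitudinalCase:
    patient_id: str
    group_label: str  # latent ground truth, synthetic only
    series: list[tuple[int, VolumetricImage, ROIMask]]


def _ellipsoid_mask(shape, spacing, center_mm, radii_mm) -> np.ndarray:
    grids = np.meshgrid(*(np.arange(n) * s for n, s in zip(shape, spacing)),
                        indexing="ij")
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center_mm, radii_mm))
    return q <= 1.0


def generate_cohort(config: CohortConfig) -> list[LongitudinalCase]:
    """Generate the phantom cohort; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    labels = sorted(config.trajectory_params)
    n_a = int(round(config.group_fractions[0] * config.n_patients))
    assignment = [labels[0]] * n_a + [labels[1]] * (config.n_patients - n_a)
    rng.shuffle(assignment)

    shape = config.grid_shape
    spacing = config.voxel_spacing
    center_mm = tuple((n - 1) / 2.0 * s for n, s in zip(shape, spacing))
    lo, hi = config.intensity_range

    cases: list[LongitudinalCase] = []
    for i in range(config.n_patients):
        label = assignment[i]
        traj = config.trajectory_params[label]
        # patient-level biological variability scales with the noise level
        mean_offset = rng.normal(0.0, config.noise_sd)
        radius_jitter = rng.normal(0.0, config.noise_sd / 120.0)
        series: list[tuple[int, VolumetricImage, ROIMask]] = []
        for t in range(config.n_timepoints):
            radius = max(traj.radius_mm[t] + radius_jitter, 2.0 * max(spacing))
            radii = tuple(radius * a for a in config.roi_aspect)
            mask = _ellipsoid_mask(shape, spacing, center_mm, radii)

            grids = np.meshgrid(*(np.arange(n) * s for n, s in zip(shape, spacing)),
                                indexing="ij")
            rnorm = np.sqrt(sum(((g - c) / r) ** 2
                                for g, c, r in zip(grids, center_mm, radii)))
            pattern = rnorm[mask]
            pattern = pattern - pattern.mean()
            sd = pattern.std(ddof=0)
            if sd > 0:
                pattern = pattern / sd

            values = np.full(shape, lo, dtype=np.float64)
            mu = traj.mean[t] + mean_offset
            voxels = mu + traj.spread[t] * pattern
            if config.noise_sd > 0:
                noise = rng.normal(0.0, config.noise_sd, size=voxels.shape)
                if config.rician:
                    noise2 = rng.normal(0.0, config.noise_sd, size=voxels.shape)
                    voxels = np.sqrt((voxels + noise) ** 2 + noise2 ** 2)
                else:
                    voxels = voxels + noise
            values[mask] = np.clip(voxels, lo, hi)

            image = VolumetricImage(values=values, spacing=spacing)
            roi = ROIMask(values=mask, spacing=spacing)
            series.append((t, image, roi))
        cases.append(LongitudinalCase(patient_id=f"P{i:03d}",
                                      group_label=label, series=series))
    return cases


# ---------------------------------------------------------------------------
# paired feature-table simulation


@dataclass(frozen=True)
class PairedSimSpec:
    """Simulated outputs of two software packages for the same features.

    Column ``j`` of the two tables is bivariate normal with correlation
    ``target_r[j]``; the second table is affinely distorted by
    ``slope``/``intercept`` and a fraction of its observations replaced
    with non-finite sentinels.
    """

    n_observations: int
    target_r: tuple[float, ...]
    slope: tuple[float, ...] | float = 1.0
    intercept: tuple[float, ...] | float = 0.0
    invalid_fraction: float = 0.0

    def __post_init__(self) -> None:
        if any(abs(r) > 1 for r in self.target_r):
            raise ValueError(f"|target_r| must be <= 1: {self.target_r}")
        if not (0 <= self.invalid_fraction < 1):
            raise ValueError(f"invalid_fraction must be in [0, 1): {self.invalid_fraction}")

    def _per_feature(self, value, j: int) -> float:
        return float(value[j]) if np.ndim(value) else float(value)


def generate_paired_features(spec: PairedSimSpec, seed: int,
                             ) -> tuple[FeatureTable, FeatureTable]:
    rng = np.random.default_rng(seed)
    n = spec.n_observations
    k = len(spec.target_r)
    a = np.empty((n, k))
    b = np.empty((n, k))
    for j, r in enumerate(spec.target_r):
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        x = z1
        y = r * z1 + np.sqrt(max(0.0, 1.0 - r * r)) * z2
        slope = spec._per_feature(spec.slope, j)
        intercept = spec._per_feature(spec.intercept, j)
        a[:, j] = x
        b[:, j] = slope * y + intercept
    n_invalid = int(np.floor(spec.invalid_fraction * n))
    if n_invalid:
        for j in range(k):
            rows = rng.choice(n, size=n_invalid, replace=False)
            b[rows, j] = np.inf

    index = pd.MultiIndex.from_tuples([(f"P{i:04d}", 0) for i in range(n)],
                                      names=["patient_id", "timepoint"])
    cols_a = [str(FeatureId("sim-a", "SIM", f"f{j}")) for j in range(k)]
    cols_b = [str(FeatureId("sim-b", "SIM", f"f{j}")) for j in range(k)]
    return (FeatureTable(pd.DataFrame(a, index=index, columns=cols_a)),
            FeatureTable(pd.DataFrame(b, index=index.copy(), columns=cols_b)))


def paired_registry(spec: PairedSimSpec):
    """Shared-feature pairs matching the columns of a paired simulation."""
    from .harmonization import SharedFeaturePair

    return [SharedFeaturePair(
        feature_a=str(FeatureId("sim-a", "SIM", f"f{j}")),
        feature_b=str(FeatureId("sim-b", "SIM", f"f{j}")),
        klass="SIM", match_basis="identical-name")
        for j in range(len(spec.target_r))]


# ---------------------------------------------------------------------------
# deterministic phantoms for texture oracles


def make_phantom_roi(pattern: str, shape: tuple[int, int, int] = (1, 4, 4),
                     spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                     value: float = 100.0, low: float = 1.0, high: float = 2.0,
                     axis: int = 2, values: np.ndarray | None = None,
                     ) -> tuple[VolumetricImage, ROIMask]:
    """Small deterministic phantoms with a full-coverage mask.

    Patterns: ``uniform`` (constant ``value``), ``checker`` (alternating
    ``low``/``high``), ``gradient`` (strictly increasing along ``axis``),
    ``listed`` (explicit ``values``, promoted to 3D if given as a slice).
    """
    if pattern == "listed":
        if values is None:
            raise ValueError("listed pattern requires explicit values")
        arr = np.asarray(values, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[None, :, :]
        if arr.ndim != 3:
            raise ValueError("listed values must be a 2D slice or 3D array")
    else:
        if any(n <= 0 for n in shape):
            raise ValueError(f"shape must be positive: {shape}")
        if pattern == "uniform":
            arr = np.full(shape, float(value))
        elif pattern == "checker":
            idx = np.indices(shape).sum(axis=0)
            arr = np.where(idx % 2 == 0, float(low), float(high))
        elif pattern == "gradient":
            ramp = np.arange(shape[axis], dtype=np.float64)
            arr = np.broadcast_to(
                ramp.reshape([-1 if a == axis else 1 for a in range(3)]),
                shape).copy() + float(low)
        else:
            raise ValueError(f"unknown phantom pattern: {pattern!r}")
    image = VolumetricImage(values=arr, spacing=spacing)
    mask = ROIMask(values=np.ones(arr.shape, dtype=np.uint8), spacing=spacing)
    return image, mask


# ---------------------------------------------------------------------------
# on-disk cohorts


def write_cohort(cases: list[LongitudinalCase], out_dir: str | Path,
                 fmt: str = "nii.gz") -> pd.DataFrame:
    """Write one volume + mask per (patient, timepoint) and a manifest CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        for t, image, mask in case.series:
            img_path = out / f"{case.patient_id}_tp{t}_adc.{fmt}"
            msk_path = out / f"{case.patient_id}_tp{t}_mask.{fmt}"
            write_volume(image, img_path)
            write_volume(mask, msk_path)
            rows.append({"patient_id": case.patient_id, "timepoint": t,
                         "group_label": case.group_label,
                         "image": img_path.name, "mask": msk_path.name})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
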