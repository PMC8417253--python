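"""Volume, mask and feature-table I/O with explicit geometry contracts.

Internal conventions
--------------------
* voxel arrays are indexed ``(z, y, x)`` with 0-based indices; the "axial
  plane" is a fixed ``z`` slice,
* ``spacing`` and ``origin`` are ``(z, y, x)`` triples in millimetres,
* geometry is never silently resampled: any grid disagreement between an
  image and its mask is an error.

NIfTI (``.nii`` / ``.nii.gz``) and NRRD volumes are read and written
through SimpleITK, whose array view is already ``(z, y, x)``.

Feature tables are CSV files with columns ``patient_id, timepoint`` followed
by one column per feature id.  Feature ids are strings of the form
``flavor/class/name`` with an optional ``/d=<distance>`` suffix for
co-occurrence features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk

__all__ = [
    "VolumetricImage",
    "ROIMask",
    "FeatureId",
    "FeatureTable",
    "read_volume",
    "write_volume",
    "read_mask",
    "read_feature_table",
    "write_feature_table",
]

FEATURE_CLASSES = ("IHIST", "SHAPE", "GLCM", "GLRLM", "NGTDM")


@dataclass(frozen=True)
class VolumetricImage:
    """A 3D scalar map (e.g. an ADC map in 1e-6 mm^2/s) with grid metadata."""

    values: np.ndarray  # (z, y, x) float64
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # mm, (z, y, x)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm, (z, y, x)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(f"non-3D data: expected a 3D array, got ndim={values.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive on all axes, got {self.spacing}")
        bad = ~np.isfinite(values)
        if bad.any():
            idx = tuple(int(i) for i in np.argwhere(bad)[0])
            raise ValueError(f"non-finite voxel at index (z,y,x)={idx}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class ROIMask:
    """Binary region of interest on the same grid as its image."""

    values: np.ndarray  # (z, y, x) uint8 in {0, 1}
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"non-3D mask: ndim={values.ndim}")
        values = (values > 0).astype(np.uint8)
        if not values.any():
            raise ValueError("empty ROI: mask has no foreground voxels")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


def _grids_match(a, b, atol: float = 1e-6) -> bool:
    return a.shape == b.shape and np.allclose(a.spacing, b.spacing, atol=atol)


# ---------------------------------------------------------------------------
# volumes


def write_volume(image: VolumetricImage | ROIMask, path: str | Path) -> None:
    img = sitk.GetImageFromArray(np.asarray(image.values))
    img.SetSpacing(tuple(reversed(image.spacing)))  # sitk wants (x, y, z)
    img.SetOrigin(tuple(reversed(image.origin)))
    sitk.WriteImage(img, str(path))


def read_volume(path: str | Path) -> VolumetricImage:
    """Read a NIfTI or NRRD scalar volume.

    Raises ``ValueError`` for non-3D data or non-finite voxels and
    ``RuntimeError`` (from SimpleITK) for unreadable files.
    """
    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img)
    if values.ndim != 3:
        raise ValueError(f"non-3D data in {path}: ndim={values.ndim}")
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    return VolumetricImage(values=np.asarray(values, dtype=np.float64),
                           spacing=spacing, origin=origin)


def read_mask(path: str | Path, reference: VolumetricImage) -> ROIMask:
    """Read a label map and coerce it to a binary ROI on ``reference``'s grid.

    Any positive label is foreground.  The mask grid must match the
    reference grid exactly; disagreement raises with both geometries named.
    """
    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img)
    if values.ndim != 3:
        raise ValueError(f"non-3D mask in {path}: ndim={values.ndim}")
    spacing = tuple(reversed(img.GetSpacing()))
    if values.shape != reference.shape or not np.allclose(spacing, reference.spacing, atol=1e-6):
        raise ValueError(
            "grid mismatch between mask and image: "
            f"mask shape={values.shape} spacing={tuple(round(s, 6) for s in spacing)} vs "
            f"image shape={reference.shape} spacing={reference.spacing}"
        )
    if not (values > 0).any():
        raise ValueError(f"empty ROI in {path}: mask has no foreground voxels")
    return ROIMask(values=values, spacing=reference.spacing, origin=reference.origin)


# ---------------------------------------------------------------------------
# feature identities and tables


@dataclass(frozen=True, order=True)
class FeatureId:
    """Structured identity of one feature column: flavor, class, name, distance."""

    flavor: str
    klass: str
    name: str
    distance: int | None = None

    def __str__(self) -> str:
        base = f"{self.flavor}/{self.klass}/{self.name}"
        return base if self.distance is None else f"{base}/d={self.distance}"

    @classmethod
    def parse(cls, text: str) -> "FeatureId":
        parts = text.split("/")
        if len(parts) == 3:
            flavor, klass, name = parts
            distance = None
        elif len(parts) == 4 and parts[3].startswith("d="):
            flavor, klass, name = parts[:3]
            try:
                distance = int(parts[3][2:])
            except ValueError:
                raise ValueError(f"malformed feature identity: {text!r}") from None
        else:
            raise ValueError(f"malformed feature identity: {text!r}")
        if not (flavor and klass and name):
            raise ValueError(f"malformed feature identity: {text!r}")
        return cls(flavor=flavor, klass=klass, name=name, distance=distance)


@dataclass
class FeatureTable:
    """(patient, timepoint) x feature matrix with feature identity metadata.

    ``data`` is a DataFrame whose index is a (patient_id, timepoint)
    MultiIndex and whose columns are feature id strings.  Non-finite
    values (the "invalid value" sentinel of degenerate features) are
    first-class and survive round-trips.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.MultiIndex) or self.data.index.nlevels != 2:
            raise ValueError("FeatureTable index must be (patient_id, timepoint)")
        dup = self.data.index.duplicated()
        if dup.any():
            keys = list(self.data.index[dup][:5])
            raise ValueError(f"duplicate (patient, timepoint) row keys: {keys}")
        self.data.index = self.data.index.set_names(["patient_id", "timepoint"])
        # validate feature ids eagerly so malformed columns fail at construction
        for c in self.data.columns:
            FeatureId.parse(str(c))

    @property
    def feature_ids(self) -> list[FeatureId]:
        return [FeatureId.parse(str(c)) for c in self.data.columns]

    @property
    def patients(self) -> list[str]:
        return list(dict.fromkeys(self.data.index.get_level_values(0)))

    @property
    def timepoints(self) -> list[int]:
        return sorted(set(int(t) for t in self.data.index.get_level_values(1)))


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    out = table.data.copy()
    out.insert(0, "timepoint", out.index.get_level_values(1))
    out.insert(0, "patient_id", out.index.get_level_values(0))
    out.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path)
    if "patient_id" not in df.columns or "timepoint" not in df.columns:
        raise ValueError(f"feature table {path} lacks patient_id/timepoint columns")
    df["timepoint"] = df["timepoint"].astype(int)
    df = df.set_index(["patient_id", "timepoint"])
    df = df.astype(np.float64)
    return FeatureTable(data=df)
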