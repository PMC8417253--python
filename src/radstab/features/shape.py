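"""Morphological (shape) features of a binary ROI.

Volume and surface area are available by two methods, mirroring a known
cross-software divergence:

* ``voxel``: volume is voxel count x voxel volume; surface is the total
  area of exposed voxel faces,
* ``mesh``: a triangulated isosurface (marching cubes at level 0.5 on the
  zero-padded mask) gives the surface area and, via the divergence
  theorem, the enclosed volume.

Derived quantities (Sphericity, SurfaceVolumeRatio, compactness family)
use the primitives selected by the caller, so two flavors can disagree
on exactly the documented methodological axes.  Axis lengths use the
eigenvalues of the (population) covariance of the physical voxel-centre
coordinates.  A single-voxel mask makes the principal-axis ratios 0/0
and they are reported non-finite.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

__all__ = ["SHAPE_FEATURE_NAMES", "shape_features"]

SHAPE_FEATURE_NAMES = (
    "Volume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Compactness1", "Compactness2", "SphericalDisproportion",
    "Maximum3DDiameter", "MajorAxisLength", "MinorAxisLength",
    "LeastAxisLength", "Elongation", "Flatness", "NumberOfVoxels",
    "NumberOfSlices", "BoundingBoxVolume", "BoundingBoxExtentX",
    "BoundingBoxExtentY", "BoundingBoxExtentZ", "ConvexHullVolume",
    "Convexity", "EquivalentSphereDiameter", "MaxSliceArea", "MeanSliceArea",
    "Orientation", "Eccentricity", "Extent", "EquivalentDiscDiameter",
    "PrincipalMoment1", "PrincipalMoment2", "PrincipalMoment3",
    "PlanarAnisotropy", "LinearAnisotropy", "CentroidOffsetZ",
)


def _voxel_surface(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Total area of voxel faces exposed to the background."""
    sz, sy, sx = spacing
    face_area = (sy * sx, sz * sx, sz * sy)  # faces normal to z, y, x
    padded = np.pad(mask.astype(np.int8), 1)
    total = 0.0
    for axis, area in enumerate(face_area):
        total += float(np.abs(np.diff(padded, axis=axis)).sum()) * area
    return total


def _mesh(mask: np.ndarray, spacing: tuple[float, float, float]):
    padded = np.pad(mask.astype(np.float64), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    return verts, faces


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return float(abs(np.einsum("ij,ij->", v0, np.cross(v1, v2))) / 6.0)


def _max_diameter(points: np.ndarray) -> float:
    """Largest pairwise Euclidean distance between voxel centres (mm)."""
    if points.shape[0] < 2:
        return 0.0
    try:
        hull = ConvexHull(points)
        pts = points[hull.vertices]
    except QhullError:  # flat/collinear ROI: fall back to all points
        pts = points
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def shape_features(mask: np.ndarray, spacing: tuple[float, float, float],
                   volume_method: str = "mesh",
                   surface_method: str = "mesh") -> dict[str, float]:
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("empty ROI")
    sz, sy, sx = (float(s) for s in spacing)
    n_vox = int(mask.sum())
    voxel_volume = n_vox * sz * sy * sx

    coords_vox = np.argwhere(mask).astype(np.float64)
    points = coords_vox * np.array([sz, sy, sx])

    surf_voxel = _voxel_surface(mask, (sz, sy, sx))
    verts, faces = _mesh(mask, (sz, sy, sx))
    surf_mesh = float(measure.mesh_surface_area(verts, faces))
    vol_mesh = _mesh_volume(verts, faces)

    if volume_method == "mesh":
        V = vol_mesh
    elif volume_method == "voxel":
        V = voxel_volume
    else:
        raise ValueError(f"unknown volume method: {volume_method!r}")
    if surface_method == "mesh":
        A = surf_mesh
    elif surface_method in ("voxel", "voxel-faces"):
        A = surf_voxel
    else:
        raise ValueError(f"unknown surface method: {surface_method!r}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cov = np.cov(points, rowvar=False, ddof=0) if n_vox > 1 else np.zeros((3, 3))
    lam = np.sort(np.clip(np.linalg.eigvalsh(np.atleast_2d(cov)), 0, None))[::-1]
    l1, l2, l3 = (float(v) for v in lam[:3])

    zs, ys, xs = coords_vox[:, 0], coords_vox[:, 1], coords_vox[:, 2]
    bbox_z = (zs.max() - zs.min() + 1) * sz
    bbox_y = (ys.max() - ys.min() + 1) * sy
    bbox_x = (xs.max() - xs.min() + 1) * sx
    slice_counts = np.bincount(zs.astype(np.int64))
    occupied = slice_counts[slice_counts > 0]
    max_slice_area = float(occupied.max()) * sy * sx
    mean_slice_area = float(occupied.mean()) * sy * sx

    try:
        hull_volume = float(ConvexHull(points).volume)
    except QhullError:
        hull_volume = np.nan

    # in-plane second moments for Orientation / Eccentricity
    xy = points[:, 1:]  # physical (y, x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cov2 = np.cov(xy, rowvar=False, ddof=0) if n_vox > 1 else np.zeros((2, 2))
    lam2 = np.sort(np.clip(np.linalg.eigvalsh(cov2), 0, None))[::-1]
    la, lb = float(lam2[0]), float(lam2[1])

    def safe_div(a: float, b: float) -> float:
        return a / b if b != 0 else np.nan

    f: dict[str, float] = {}
    f["Volume"] = V
    f["VoxelVolume"] = voxel_volume
    f["SurfaceArea"] = A
    f["SurfaceVolumeRatio"] = safe_div(A, V)
    f["Sphericity"] = safe_div((36.0 * np.pi * V ** 2) ** (1.0 / 3.0), A)
    f["Compactness1"] = safe_div(V, np.sqrt(np.pi) * A ** 1.5)
    f["Compactness2"] = safe_div(36.0 * np.pi * V ** 2, A ** 3)
    r_eq = (3.0 * V / (4.0 * np.pi)) ** (1.0 / 3.0)
    f["SphericalDisproportion"] = safe_div(A, 4.0 * np.pi * r_eq ** 2)
    f["Maximum3DDiameter"] = _max_diameter(points)
    f["MajorAxisLength"] = 4.0 * np.sqrt(l1)
    f["MinorAxisLength"] = 4.0 * np.sqrt(l2)
    f["LeastAxisLength"] = 4.0 * np.sqrt(l3)
    f["Elongation"] = np.sqrt(safe_div(l2, l1))
    f["Flatness"] = np.sqrt(safe_div(l3, l1))
    f["NumberOfVoxels"] = float(n_vox)
    f["NumberOfSlices"] = float(occupied.size)
    f["BoundingBoxVolume"] = bbox_z * bbox_y * bbox_x
    f["BoundingBoxExtentX"] = bbox_x
    f["BoundingBoxExtentY"] = bbox_y
    f["BoundingBoxExtentZ"] = bbox_z
    f["ConvexHullVolume"] = hull_volume
    f["Convexity"] = safe_div(voxel_volume, hull_volume) if np.isfinite(hull_volume) else np.nan
    f["EquivalentSphereDiameter"] = 2.0 * (3.0 * voxel_volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    f["MaxSliceArea"] = max_slice_area
    f["MeanSliceArea"] = mean_slice_area
    cxx = float(cov2[1, 1]) if n_vox > 1 else 0.0
    cyy = float(cov2[0, 0]) if n_vox > 1 else 0.0
    cxy = float(cov2[0, 1]) if n_vox > 1 else 0.0
    f["Orientation"] = float(np.degrees(0.5 * np.arctan2(2.0 * cxy, cxx - cyy)))
    f["Eccentricity"] = np.sqrt(1.0 - safe_div(lb, la)) if la > 0 else np.nan
    f["Extent"] = safe_div(voxel_volume, f["BoundingBoxVolume"])
    f["EquivalentDiscDiameter"] = 2.0 * np.sqrt(max_slice_area / np.pi)
    f["PrincipalMoment1"] = l1
    f["PrincipalMoment2"] = l2
    f["PrincipalMoment3"] = l3
    f["PlanarAnisotropy"] = safe_div(l2 - l3, l1)
    f["LinearAnisotropy"] = safe_div(l1 - l2, l1)
    centroid_z = float(points[:, 0].mean())
    bbox_center_z = float((zs.max() + zs.min()) / 2.0 * sz)
    f["CentroidOffsetZ"] = abs(centroid_z - bbox_center_z)
    return f
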