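import numpy as np
import pytest

import radstab as rs
from radstab.features.intensity import intensity_features
from radstab.features.shape import shape_features

from .oracles import intensity_moments_bruteforce

SPEC = rs.DiscretizationSpec(256, 16.0)


def _features(values, voxel_volume=1.0):
    values = np.asarray(values, dtype=np.float64)
    from radstab.features.discretization import discretize_values
    levels = discretize_values(values, SPEC)
    return intensity_features(values, levels, SPEC, voxel_volume)


def test_two_value_roi():
    f = _features([2.0, 4.0])
    assert f["Mean"] == 3.0
    assert f["Range"] == 2.0
    assert f["Minimum"] == 2.0 and f["Maximum"] == 4.0


def test_uniform_roi_degenerate_statistics():
    f = _features([500.0] * 20)
    assert f["Variance"] == 0.0
    assert f["Entropy"] == 0.0
    assert f["Uniformity"] == 1.0
    assert np.isnan(f["Skewness"]) and np.isnan(f["Kurtosis"])


def test_moments_match_two_pass_oracle():
    rng = np.random.default_rng(8)
    values = rng.uniform(0, 4095, size=1000)
    f = _features(values)
    mu, var, skew, kurt = intensity_moments_bruteforce(values)
    assert f["Mean"] == pytest.approx(mu, rel=1e-10)
    assert f["Variance"] == pytest.approx(var, rel=1e-10)
    assert f["Skewness"] == pytest.approx(skew, rel=1e-10)
    assert f["Kurtosis"] == pytest.approx(kurt, rel=1e-10)
    assert f["GlobalStandardDeviation"] == pytest.approx(np.sqrt(var), rel=1e-10)
    assert f["RootMeanSquared"] == pytest.approx(np.sqrt(np.mean(values ** 2)),
                                                 rel=1e-10)


def test_total_energy_scales_with_voxel_volume():
    f1 = _features([1.0, 2.0, 3.0], voxel_volume=1.0)
    f2 = _features([1.0, 2.0, 3.0], voxel_volume=16.0)
    assert f2["TotalEnergy"] == pytest.approx(16.0 * f1["TotalEnergy"])
    assert f2["Energy"] == f1["Energy"]


# ---------------------------------------------------------------------------
# shape


def test_single_voxel_voxel_method():
    mask = np.zeros((3, 3, 3), bool)
    mask[1, 1, 1] = True
    f = shape_features(mask, (1.0, 1.0, 1.0), volume_method="voxel",
                       surface_method="voxel-faces")
    assert f["Volume"] == 1.0
    assert f["SurfaceArea"] == 6.0
    assert np.isnan(f["Elongation"]) and np.isnan(f["Flatness"])


def test_cube_face_counting():
    mask = np.zeros((4, 4, 4), bool)
    mask[1:3, 1:3, 1:3] = True
    f = shape_features(mask, (1.0, 1.0, 1.0), volume_method="voxel",
                       surface_method="voxel-faces")
    assert f["Volume"] == 8.0
    assert f["SurfaceArea"] == 24.0
    assert f["NumberOfVoxels"] == 8
    assert f["BoundingBoxVolume"] == 8.0


def test_digitized_sphere_matches_analytic_solid():
    r = 10.0
    n = 27
    coords = np.arange(n) - (n - 1) / 2
    zz, yy, xx = np.meshgrid(coords, coords, coords, indexing="ij")
    mask = zz ** 2 + yy ** 2 + xx ** 2 <= r ** 2
    f = shape_features(mask, (1.0, 1.0, 1.0))
    analytic_volume = 4.0 / 3.0 * np.pi * r ** 3
    analytic_surface = 4.0 * np.pi * r ** 2
    assert f["Volume"] == pytest.approx(analytic_volume, rel=0.02)
    # the midpoint isosurface of a binary mask facets the sphere and
    # overestimates the smooth surface by several percent
    assert f["SurfaceArea"] == pytest.approx(analytic_surface, rel=0.12)
    assert f["SurfaceArea"] > analytic_surface
    assert 0.85 < f["Sphericity"] <= 1.0
    assert f["Maximum3DDiameter"] == pytest.approx(2 * r, rel=0.03)
    assert f["Flatness"] == pytest.approx(1.0, rel=0.02)
    # voxel-based surface systematically exceeds the smooth surface
    f_vox = shape_features(mask, (1.0, 1.0, 1.0), volume_method="voxel",
                           surface_method="voxel-faces")
    assert f_vox["SurfaceArea"] > f["SurfaceArea"]
    assert f_vox["Volume"] == pytest.approx(analytic_volume, rel=0.05)


def test_anisotropic_spacing_respected():
    # a 2x2x2 voxel block with spacing (4, 2, 1) mm is an 8x4x2 mm box
    mask = np.ones((2, 2, 2), bool)
    f = shape_features(mask, (4.0, 2.0, 1.0), volume_method="voxel",
                       surface_method="voxel-faces")
    assert f["Volume"] == pytest.approx(8.0 * 4.0 * 2.0)
    assert f["SurfaceArea"] == pytest.approx(2 * (4 * 2 + 8 * 2 + 8 * 4))
    assert f["BoundingBoxExtentZ"] == 8.0
    assert f["BoundingBoxExtentY"] == 4.0
    assert f["BoundingBoxExtentX"] == 2.0
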