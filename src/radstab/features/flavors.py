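"""Software "flavors": named feature-extraction configurations.

A flavor bundles the feature roster per class with the algorithmic
variants that are documented to differ between radiomics packages:
co-occurrence symmetry, mesh- versus voxel-based volume and surface,
and the intensity-range policy of the texture discretization.  Three
flavors ship with the package:

``reference``
    An IBSI-style extractor: asymmetric co-occurrence matrices,
    mesh-based volume/surface, fixed-anchor discretization (256 bins of
    width 16 for intensity/NGTDM features, 100 bins of width 21 for
    GLCM/GLRLM).  Emits 125 features per map: 18 intensity-histogram,
    14 shape, 24 GLCM at each of three distances, 16 GLRLM, 5 NGTDM.
``ibex-emulation``
    Asymmetric matrices like the reference but voxel-based volume and
    exposed-face surface.  Several of its feature names carry different
    equations than the same names in the reference (for example its
    ``JointEnergy`` is the cluster-tendency equation), reproducing
    documented naming divergences.  110 features per map.
``mazda-emulation``
    Symmetric co-occurrence matrices (compensating a reduced direction
    set) and full-observed-range texture binning (64 bins), emulating
    software in which a fixed intensity range cannot be configured.
    No NGTDM class.  79 features per map.

Display names are per-flavor; each maps onto a canonical computation in
the extraction modules.  The curated alias table in
:mod:`radstab.harmonization` links display names across flavors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..image_io import FeatureId, ROIMask, VolumetricImage
from .discretization import DiscretizationSpec, discretize
from .glcm import glcm_features, glcm_matrices
from .glrlm import glrlm_features
from .intensity import intensity_features
from .ngtdm import ngtdm_features
from .shape import shape_features

__all__ = ["TextureSpec", "FlavorConfig", "FeatureVector", "SHIPPED_FLAVORS",
           "get_flavor", "extract_features", "features_to_table"]


@dataclass(frozen=True)
class TextureSpec:
    distances: tuple[int, ...] = (1, 4, 7)
    directions: tuple[int, ...] = (0, 45, 90, 135)

    def __post_init__(self) -> None:
        if not self.directions:
            raise ValueError("directions must be non-empty")
        if any(d < 1 for d in self.distances):
            raise ValueError(f"distances must be positive integers: {self.distances}")


@dataclass(frozen=True)
class FlavorConfig:
    flavor_name: str
    feature_lists: dict[str, tuple[str, ...]]
    compute_map: dict[tuple[str, str], str] = field(default_factory=dict)
    ihist_spec: DiscretizationSpec = DiscretizationSpec(256, 16.0)
    ngtdm_spec: DiscretizationSpec = DiscretizationSpec(256, 16.0)
    texture_disc: DiscretizationSpec = DiscretizationSpec(100, 21.0)
    texture_spec: TextureSpec = TextureSpec()
    glcm_symmetric: bool = False
    shape_volume_method: str = "mesh"
    shape_surface_method: str = "mesh"
    intensity_range_policy: str = "fixed-anchor"
    ngtdm_distance: int = 3

    def compute_name(self, klass: str, display: str) -> str:
        return self.compute_map.get((klass, display), display)

    @property
    def n_features(self) -> int:
        total = 0
        for klass, names in self.feature_lists.items():
            mult = len(self.texture_spec.distances) if klass == "GLCM" else 1
            total += len(names) * mult
        return total

    def feature_ids(self) -> list[FeatureId]:
        ids: list[FeatureId] = []
        for klass in ("IHIST", "SHAPE", "GLCM", "GLRLM", "NGTDM"):
            names = self.feature_lists.get(klass, ())
            if klass == "GLCM":
                for d in self.texture_spec.distances:
                    ids.extend(FeatureId(self.flavor_name, klass, n, d) for n in names)
            else:
                ids.extend(FeatureId(self.flavor_name, klass, n) for n in names)
        return ids


# ---------------------------------------------------------------------------
# shipped rosters

_REF_IHIST = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "Percentile10",
    "Percentile90", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)  # 18

_REF_SHAPE = (
    "Volume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Compactness1", "Compactness2", "SphericalDisproportion",
    "Maximum3DDiameter", "MajorAxisLength", "MinorAxisLength",
    "LeastAxisLength", "Elongation", "Flatness",
)  # 14

_REF_GLCM = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "InverseDifference", "InverseDifferenceMoment",
    "InverseDifferenceMomentNormalized", "InverseDifferenceNormalized",
    "InverseVariance", "MaximumProbability", "SumAverage", "SumEntropy",
    "SumSquares", "MCC",
)  # 24 per distance

_REF_GLRLM = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)  # 16

_NGTDM = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")  # 5

_IBEX_IHIST = (
    "Mean", "Median", "Minimum", "Maximum", "Range", "Skewness", "Kurtosis",
    "Percentile25", "Percentile75", "GlobalStandardDeviation",
    "MedianAbsoluteDeviation", "CoefficientOfVariation", "Mode",
)  # 13 (7 shared by identical name)

_IBEX_SHAPE = (
    "Roundness", "Area", "VoxelSize", "Perimeter", "SurfaceAreaDensity",
    "FerretDiameter",
    "NumberOfVoxels", "NumberOfSlices", "BoundingBoxVolume",
    "BoundingBoxExtentX", "BoundingBoxExtentY", "BoundingBoxExtentZ",
    "ConvexHullVolume", "Convexity", "EquivalentSphereDiameter",
    "MaxAxialArea", "MeanAxialArea", "Orientation",
)  # 18 (6 shared via curated aliases)

_IBEX_GLCM = (
    "AngularSecondMoment", "JointEnergy", "Homogeneity1", "Homogeneity2",
    "Variance",
    "Autocorrelation", "ClusterProminence", "ClusterShade", "Contrast",
    "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "JointEntropy", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy",
    "InformationMeasureCorr1", "InformationMeasureCorr2", "Dissimilarity",
)  # 21 per distance (18 shared)

_IBEX_GLRLM = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "RunLengthNonUniformity", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis", "Fraction",
)  # 11, all shared

_MAZDA_IHIST = (
    "Mean", "Variance", "Skewness", "Kurtosis", "Percentile10", "Percentile90",
    "Percentile1", "Percentile50", "Percentile99", "DiscretizedMean",
    "DiscretizedVariance", "DiscretizedSkewness", "DiscretizedKurtosis",
    "DiscretizedEntropy",
)  # 14 (6 shared)

_MAZDA_SHAPE = (
    "Roundness", "Area", "VoxelSize", "Perimeter", "SurfaceAreaDensity",
    "FerretDiameter",
    "Eccentricity", "Extent", "EquivalentDiscDiameter", "MaxSliceArea",
    "MeanSliceArea", "SliceCount", "BoundingBoxExtentX", "BoundingBoxExtentY",
    "BoundingBoxExtentZ", "BoundingBoxVolume", "PrincipalMoment1",
    "PrincipalMoment2", "PrincipalMoment3", "PlanarAnisotropy",
    "LinearAnisotropy", "CentroidOffsetZ",
)  # 22 (6 shared via curated aliases)

_MAZDA_GLCM = (
    "AngularSecondMoment", "Variance", "Homogeneity2",
    "Contrast", "Correlation", "SumAverage", "SumEntropy", "JointEntropy",
    "DifferenceVariance", "DifferenceEntropy",
    "SumVariance", "Dissimilarity",
)  # 12 per distance (10 shared)

_MAZDA_GLRLM = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "RunLengthNonUniformity", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "Fraction",
)  # 7, all shared

_SHAPE_ALIAS_COMPUTE = {
    ("SHAPE", "Roundness"): "Flatness",
    ("SHAPE", "Area"): "Volume",
    ("SHAPE", "VoxelSize"): "VoxelVolume",
    ("SHAPE", "Perimeter"): "SurfaceArea",
    ("SHAPE", "SurfaceAreaDensity"): "SurfaceVolumeRatio",
    ("SHAPE", "FerretDiameter"): "Maximum3DDiameter",
}

_IBEX_COMPUTE = {
    **_SHAPE_ALIAS_COMPUTE,
    ("SHAPE", "MaxAxialArea"): "MaxSliceArea",
    ("SHAPE", "MeanAxialArea"): "MeanSliceArea",
    # documented naming quirk: the name "JointEnergy" carries the
    # cluster-tendency equation in this flavor
    ("GLCM", "AngularSecondMoment"): "JointEnergy",
    ("GLCM", "JointEnergy"): "ClusterTendency",
    ("GLCM", "Homogeneity1"): "InverseDifference",
    ("GLCM", "Homogeneity2"): "InverseDifferenceMoment",
    ("GLCM", "Variance"): "SumSquares",
    ("GLCM", "InformationMeasureCorr1"): "Imc1",
    ("GLCM", "InformationMeasureCorr2"): "Imc2",
    ("GLRLM", "Fraction"): "RunPercentage",
}

_MAZDA_COMPUTE = {
    **_SHAPE_ALIAS_COMPUTE,
    ("SHAPE", "SliceCount"): "NumberOfSlices",
    ("GLCM", "AngularSecondMoment"): "JointEnergy",
    ("GLCM", "Variance"): "SumSquares",
    ("GLCM", "Homogeneity2"): "InverseDifferenceMoment",
    ("GLRLM", "Fraction"): "RunPercentage",
}

REFERENCE_FLAVOR = FlavorConfig(
    flavor_name="reference",
    feature_lists={"IHIST": _REF_IHIST, "SHAPE": _REF_SHAPE, "GLCM": _REF_GLCM,
                   "GLRLM": _REF_GLRLM, "NGTDM": _NGTDM},
)

IBEX_FLAVOR = FlavorConfig(
    flavor_name="ibex-emulation",
    feature_lists={"IHIST": _IBEX_IHIST, "SHAPE": _IBEX_SHAPE,
                   "GLCM": _IBEX_GLCM, "GLRLM": _IBEX_GLRLM, "NGTDM": _NGTDM},
    compute_map=_IBEX_COMPUTE,
    shape_volume_method="voxel",
    shape_surface_method="voxel-faces",
)

MAZDA_FLAVOR = FlavorConfig(
    flavor_name="mazda-emulation",
    feature_lists={"IHIST": _MAZDA_IHIST, "SHAPE": _MAZDA_SHAPE,
                   "GLCM": _MAZDA_GLCM, "GLRLM": _MAZDA_GLRLM, "NGTDM": ()},
    compute_map=_MAZDA_COMPUTE,
    texture_disc=DiscretizationSpec(64, 64.0),
    glcm_symmetric=True,
    shape_volume_method="voxel",
    shape_surface_method="voxel-faces",
    intensity_range_policy="full-observed-range",
)

SHIPPED_FLAVORS: dict[str, FlavorConfig] = {
    f.flavor_name: f for f in (REFERENCE_FLAVOR, IBEX_FLAVOR, MAZDA_FLAVOR)
}


def get_flavor(name: str) -> FlavorConfig:
    try:
        return SHIPPED_FLAVORS[name]
    except KeyError:
        raise KeyError(
            f"unknown flavor {name!r}; shipped flavors: {sorted(SHIPPED_FLAVORS)}"
        ) from None


# ---------------------------------------------------------------------------
# extraction


@dataclass
class FeatureVector:
    """One map's feature values, keyed by feature id string."""

    values: dict[str, float]
    patient_id: str | None = None
    timepoint: int | None = None


def _crop_to_roi(image: VolumetricImage, mask: ROIMask,
                 margin: int = 1) -> tuple[np.ndarray, np.ndarray]:
    m = mask.values > 0
    zs, ys, xs = np.nonzero(m)
    sl = tuple(
        slice(max(0, int(c.min()) - margin), int(c.max()) + 1 + margin)
        for c in (zs, ys, xs)
    )
    return image.values[sl], m[sl]


def extract_features(image: VolumetricImage, mask: ROIMask,
                     flavor: FlavorConfig) -> FeatureVector:
    """Extract the flavor's full feature roster from one image/ROI pair.

    Emits exactly the flavor's enumerated feature ids; degenerate
    features carry non-finite values but are never dropped.
    """
    if image.shape != mask.shape or not np.allclose(image.spacing, mask.spacing):
        raise ValueError(
            f"image/mask grid mismatch: image shape={image.shape} "
            f"spacing={image.spacing} vs mask shape={mask.shape} spacing={mask.spacing}"
        )
    vals, m = _crop_to_roi(image, mask)
    roi_values = vals[m]

    sub_img = VolumetricImage(values=vals, spacing=image.spacing)
    sub_mask = ROIMask(values=m, spacing=image.spacing)

    ihist_levels = discretize(sub_img, sub_mask, flavor.ihist_spec,
                              policy="fixed-anchor")
    texture_levels = discretize(sub_img, sub_mask, flavor.texture_disc,
                                policy=flavor.intensity_range_policy)

    out: dict[str, float] = {}

    names = flavor.feature_lists.get("IHIST", ())
    if names:
        ih = intensity_features(roi_values, ihist_levels[m], flavor.ihist_spec,
                                image.voxel_volume, policy="fixed-anchor")
        for n in names:
            out[str(FeatureId(flavor.flavor_name, "IHIST", n))] = ih[flavor.compute_name("IHIST", n)]

    names = flavor.feature_lists.get("SHAPE", ())
    if names:
        sh = shape_features(m, image.spacing,
                            volume_method=flavor.shape_volume_method,
                            surface_method=flavor.shape_surface_method)
        for n in names:
            out[str(FeatureId(flavor.flavor_name, "SHAPE", n))] = sh[flavor.compute_name("SHAPE", n)]

    names = flavor.feature_lists.get("GLCM", ())
    if names:
        for d in flavor.texture_spec.distances:
            mats = glcm_matrices(texture_levels, flavor.texture_disc.n_bins, d,
                                 symmetric=flavor.glcm_symmetric,
                                 directions=flavor.texture_spec.directions)
            gf = glcm_features(mats)
            for n in names:
                out[str(FeatureId(flavor.flavor_name, "GLCM", n, d))] = gf[flavor.compute_name("GLCM", n)]

    names = flavor.feature_lists.get("GLRLM", ())
    if names:
        rf = glrlm_features(texture_levels, flavor.texture_disc.n_bins,
                            directions=flavor.texture_spec.directions)
        for n in names:
            out[str(FeatureId(flavor.flavor_name, "GLRLM", n))] = rf[flavor.compute_name("GLRLM", n)]

    names = flavor.feature_lists.get("NGTDM", ())
    if names:
        nf = ngtdm_features(ihist_levels, flavor.ngtdm_spec.n_bins,
                            distance=flavor.ngtdm_distance)
        for n in names:
            out[str(FeatureId(flavor.flavor_name, "NGTDM", n))] = nf[flavor.compute_name("NGTDM", n)]

    return FeatureVector(values=out)


def features_to_table(rows: list[tuple[str, int, FeatureVector]]):
    """Assemble extracted vectors into a FeatureTable."""
    import pandas as pd

    from ..image_io import FeatureTable

    index = pd.MultiIndex.from_tuples([(p, t) for p, t, _ in rows],
                                      names=["patient_id", "timepoint"])
    df = pd.DataFrame([fv.values for _, _, fv in rows], index=index)
    return FeatureTable(data=df)
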