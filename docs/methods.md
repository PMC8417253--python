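# Methods

## Scope and model

`radstab` implements a reproducibility analysis for radiomics features
computed by different software packages on quantitative MRI maps, together
with the synthetic data needed to exercise it. Three stages compose the
analysis: feature extraction under configurable algorithmic variants
("flavors"), cross-flavor harmonization by per-feature linear correlation,
and a patient-clustering stability analysis as a function of the
reproducibility threshold.

## Coordinate and geometry conventions

Voxel arrays are `(z, y, x)` with 0-based indices; the axial plane is a
fixed `z` slice. Spacing and origin are `(z, y, x)` millimetre triples.
NIfTI and NRRD I/O goes through SimpleITK, whose array view already follows
this convention. Geometry is a hard contract: an image and its mask must
share shape and spacing exactly, and nothing is ever resampled silently.
Any positive mask label is foreground (single-ROI analyses only).

## Discretization

Intensities are binned to 1-based grey levels with
`level = clamp(floor((v − anchor) / width), 0, n_bins − 1) + 1`.

* IHIST and NGTDM features: 256 bins of width 16, anchored at 0 — covering
  an ADC-like 0..4095 range in units of 1e-6 mm²/s.
* GLCM and GLRLM features: 100 bins of width 21 (a reduced data range).
* The MaZda emulation cannot anchor its texture range (the emulated package
  exposes no such setting) and instead bins the observed ROI min..max into
  64 equal bins — 64 being that package's historical 6-bit default. The bin
  count here is a package choice, as the emulated default is not documented
  numerically.

## Texture features

Texture matrices are built in-plane and merged across all axial slices of
the 3D ROI before normalization — one matrix per direction (and per
distance for GLCM). Both voxels of a co-occurrence pair, all voxels of a
run, and every neighbourhood member must lie inside the ROI. Directions are
the four unique in-plane angles {0°, 45°, 90°, 135°}; features are computed
per direction and then averaged over directions. Empty directions (no valid
pair) are excluded from the average.

* **GLCM**: distances {1, 4, 7} interpreted as inter-voxel offset in voxels.
  Asymmetric mode counts ordered pairs only; symmetric mode adds the
  transpose. Feature definitions follow the standard Haralick/IBSI forms;
  the maximal correlation coefficient uses the second-largest eigenvalue of
  the Q matrix restricted to occupied levels.
* **GLRLM**: runs are maximal same-level sequences along a direction,
  truncating at the ROI boundary; the matrix total equals the number of
  runs.
* **NGTDM**: the neighbourhood is the in-plane Chebyshev disc of radius 3
  (an interpretation of "neighbourhood of three"; a plain 3×3 window would
  be radius 1 and is available by passing `distance=1`). Voxels with no ROI
  neighbour do not contribute.

Degenerate inputs never raise: a uniform ROI yields Contrast 0 and infinite
Coarseness (1/0); a single-voxel ROI has no valid neighbourhood and all
NGTDM features are non-finite; a zero-variance matrix margin makes
Correlation undefined (NaN). Non-finite values propagate into feature
tables as first-class sentinels.

## Shape features

Volume and surface are computed by two methods: voxel (count × voxel
volume; exposed-face area) and mesh (marching-cubes isosurface at level 0.5
on the zero-padded mask; divergence-theorem volume). Derived quantities
(SurfaceVolumeRatio, Sphericity, compactness family) use whichever
primitives the flavor selects, so mesh-based and voxel-based flavors
disagree exactly where real packages do. Note that the midpoint isosurface
of a binary mask facets a smooth boundary and overestimates a sphere's
surface area by several percent; mesh volume is accurate to ~1–2% at radius
10 voxels. Axis lengths derive from the population covariance eigenvalues
of physical voxel-centre coordinates (MajorAxisLength = 4√λ₁, Elongation =
√(λ₂/λ₁), Flatness = √(λ₃/λ₁)); the maximum 3D diameter is the largest
pairwise distance between voxel centres (via the convex hull).

## Flavors

A flavor bundles per-class feature rosters with the algorithmic switches:
co-occurrence symmetry, volume/surface method, and texture intensity-range
policy. The shipped rosters reproduce the three packages' published
compositions — reference: 18 IHIST + 14 shape + 24 GLCM per distance + 16
GLRLM + 5 NGTDM = 125; IBEX emulation: 13 + 18 + 21×3 + 11 + 5 = 110; MaZda
emulation: 14 + 22 + 12×3 + 7 (no NGTDM) = 79. Emulation flavors capture
*documented* divergences, not bit-level legacy behaviour: the IBEX
emulation is asymmetric like the reference but voxel-based in shape, and
several of its names carry different equations (its `JointEnergy` is the
cluster-tendency equation, its `AngularSecondMoment` the joint-energy
equation — the naming quirk that motivates the curated alias pairs); the
MaZda emulation is symmetric (compensating a reduced direction set) with
full-observed-range binning. With all switches set equal, shared features
of two flavors agree exactly — divergence is fully explained by the
switches.

## Harmonization

The shared-feature registry is data independent. Curated dissimilar-name
aliases are applied first (Flatness↔Roundness, Volume↔Area,
VoxelVolume↔VoxelSize, SurfaceArea↔Perimeter,
SurfaceVolumeRatio↔SurfaceAreaDensity, Maximum3DDiameter↔FerretDiameter,
SumSquares↔Variance, InverseDifference↔Homogeneity1,
InverseDifferenceMoment↔Homogeneity2, JointEnergy↔AngularSecondMoment,
ClusterTendency↔JointEnergy, RunPercentage↔Fraction); remaining features
pair by identical name; GLCM pairs replicate per distance. Aliases fire
only across genuinely different vocabularies — when both flavors carry both
names (e.g. a flavor against itself) identical-name matching wins, so a
self-registry is pure identity. Alias ordering before identity matching is
deliberate: the reference carries both `ClusterTendency` and `JointEnergy`,
and identity-first matching would make the curated
ClusterTendency↔JointEnergy pair unreachable.

Per pair, ordinary least squares across all (patient, timepoint) rows gives
slope, intercept and Pearson r; rows with a non-finite value on either side
are excluded pairwise and counted. Records with fewer than 3 usable rows or
a constant column are flagged undefined, reported, and never selected.
Selection keeps finite r **strictly** greater than the threshold, so ties
at exactly 0.901 are excluded and the kept set is monotone non-increasing
in the threshold.

## Clustering stability

Signatures stack z-scored per-(feature, timepoint) columns over patients
with complete timepoint coverage; a delta mode (per-timepoint differences
from baseline) is provided because the published analysis is ambiguous
between the two readings — stacked is the default, neither is asserted as
canonical. Features with any non-finite value across the cohort are dropped
before scaling. Z-scoring uses the population (n) denominator so both
flavors are scaled identically; constant columns become all-zero rather
than NaN.

Ward's minimum-variance linkage on Euclidean distances is cut at exactly
its two top-level clusters (the reproducible reading of "no more than two
clusters"); all-identical rows collapse to a single group, which the
similarity stage handles. SciPy's deterministic agglomeration gives
identical sweeps across runs and platforms. The similarity statistic is the
percentage of patients placed in matching groups, maximized over the two
label pairings (unsupervised clusters have arbitrary order); it is 100
exactly when the partitions agree up to a label swap. The threshold sweep
re-selects features at each grid point (default 0.000–0.999, step 0.001),
assembles both signatures on the same surviving pairs — each flavor
contributing its own values — clusters each side and records similarity and
per-class composition. Zero-surviving-feature thresholds record a NaN
similarity sentinel rather than erroring, so sweeps always complete.

## Synthetic cohort

The generator emulates a longitudinal radiotherapy imaging study: per
patient, an axis-aligned ellipsoidal ROI (analytic geometry, so shape
features have closed-form checks) on a 12×48×48 grid with (4, 2, 2) mm
voxels, 8 time points, values clipped to 0..4095. Two latent groups follow
different trajectories: a responder-like group whose ROI mean rises from
1100 to 1750 (units 1e-6 mm²/s) while the radius shrinks from 14 to 8 mm,
and a slow group (1100→1180; 14→12.6 mm). These effect sizes are a package
choice — plausible for ADC response in head-and-neck tumours — not
calibrated to any trial, because no patient-level effect sizes are
published for the study the generator emulates. Within-ROI texture is a
deterministic radial gradient standardized to the configured spread;
additive Gaussian voxel noise (default sd 60) and noise-scaled patient-level
offsets sit on top, so `noise_sd = 0` makes the ROI mean exactly equal the
configured trajectory (a tested contract). A Rician noise option exists,
default off. The phantoms deliberately omit MRI physics, anatomical
background, segmentation variability and scanner drift — passing tests
demonstrate the *pipeline's* correctness and the qualitative
threshold-sweep behaviour, not performance on real patient data.

The paired-feature simulator draws per-feature bivariate normal columns at
specified correlations, applies an affine distortion and injects non-finite
sentinels — a direct test harness for the correlation machinery, validated
against the Fisher-z distribution.

## The distractor experiment

`distractor_sweep_experiment` reproduces the qualitative effect of
non-reproducible features on patient modelling. On top of the two flavors'
real feature tables it appends a block of distractor features per side;
each side's block shares one latent bimodal patient factor (mutually
correlated features encoding a *fake* grouping, independent between
flavors) plus a weak positive cross-flavor coupling (~0.3) so the
distractors survive permissive thresholds but sit far below 0.901. At
threshold 0 each flavor's signature is dominated by its own fake grouping
and the clusterings disagree; at 0.901 only well-correlated real features
survive and the clusterings coincide. The within-block correlation is the
realistic ingredient: features inside one texture class are strongly
inter-correlated, so a non-reproducible class acts as a coherent block, not
as independent noise (independent distractor columns average out and leave
clustering untouched).

## Numerical choices

* Feature agreement between vectorized implementations and brute-force
  enumerations is asserted to 1e-10 relative tolerance.
* Correlation symmetry r(a,b) = r(b,a) holds to 1e-12.
* Ward tie-breaks follow SciPy's deterministic merge order; row-order
  invariance is asserted on separated data (exact ties can permute).
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; the pipeline derives stage behaviour from a
  single master seed.
* Acceptance-scale problem sizes: 36 patients × 8 time points (288 maps per
  flavor), 100 random ≤16×16×3 ROIs for oracle equivalence, 100 replicates
  × n = 334 for correlation recovery, 1000-point threshold sweeps.

## Known limitations

* Emulation flavors model documented divergences only; they are not
  bit-compatible reimplementations of the legacy packages, and per-feature
  correlation values on real patient data are out of reach without the
  original images.
* No DICOM/RTSTRUCT input, no resampling or registration, no filtered
  (wavelet/LoG) features, no 3D (26-neighbour) texture aggregation, no
  GLSZM/GLDM classes, no supervised outcome modelling.
* The mesh surface area of digitized masks carries the marching-cubes
  faceting bias noted above; comparisons between flavors are consistent
  because both sides see the same masks.
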