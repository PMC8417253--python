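"""Patient-clustering stability under a reproducibility threshold.

Patients with complete longitudinal data are stratified into at most two
groups by Ward's minimum-variance hierarchical clustering on a z-scored
feature signature (features x timepoints, stacked or as deltas from
baseline).  Two flavors' clusterings are compared with the similarity
statistic

    Similarity (%) = max over the two label pairings of
        (|A_ref ∩ A_alt| + |B_ref ∩ B_alt|) / |A_ref ∪ B_ref| * 100,

the label-swap maximum accounting for the arbitrary order of
unsupervised clusters.  A threshold sweep repeats feature selection,
signature assembly and clustering for every reproducibility cutoff on a
grid (default 0.000 to 0.999 in steps of 0.001) and records the
similarity and surviving-feature composition at each.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .harmonization import CorrelationRecord, SharedFeaturePair
from .image_io import FeatureTable

__all__ = ["SignatureMatrix", "ClusterAssignment", "SimilarityResult",
           "SweepResult", "default_threshold_grid", "assemble_signature",
           "ward_two_groups", "clustering_similarity", "threshold_sweep"]


def default_threshold_grid() -> np.ndarray:
    """The sweep grid: thresholds 0.000, 0.001, ..., 0.999."""
    return np.round(np.arange(0, 1000) / 1000.0, 3)


@dataclass
class SignatureMatrix:
    """Patients x (feature, timepoint) matrix, z-scored per column."""

    values: np.ndarray
    patients: list[str]
    columns: list[tuple[str, int]]  # (feature id, timepoint)
    mode: str
    dropped_features: list[str] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return len({c[0] for c in self.columns})


@dataclass
class ClusterAssignment:
    """Partition of the patient set into at most two groups A and B."""

    groups: dict[str, str]  # patient_id -> "A" | "B"

    @property
    def patients(self) -> set[str]:
        return set(self.groups)

    def members(self, label: str) -> set[str]:
        return {p for p, g in self.groups.items() if g == label}


@dataclass
class SimilarityResult:
    threshold: float
    similarity_percent: float  # NaN when no feature survives
    n_features: int
    composition: dict[str, int]


@dataclass
class SweepResult:
    results: list[SimilarityResult]

    def to_frame(self) -> pd.DataFrame:
        classes = sorted({k for r in self.results for k in r.composition})
        rows = []
        for r in self.results:
            row = {"threshold": r.threshold, "n_features": r.n_features,
                   "similarity_percent": r.similarity_percent}
            for k in classes:
                row[f"n_{k}"] = r.composition.get(k, 0)
            rows.append(row)
        return pd.DataFrame(rows)


def _zscore(matrix: np.ndarray) -> np.ndarray:
    """Column-wise z-score with population (n) denominator."""
    mu = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0  # constant columns become all-zero, not NaN
    return (matrix - mu) / sd


def assemble_signature(table: FeatureTable, patients: list[str],
                       features: list[str], mode: str = "stacked",
                       ) -> SignatureMatrix:
    """Build the z-scored longitudinal signature for the given patients.

    ``mode='stacked'`` uses one column per (feature, timepoint);
    ``mode='delta'`` uses per-timepoint differences from the baseline
    timepoint.  Features with any non-finite value across the cohort are
    dropped (and reported in ``dropped_features``); patients missing a
    timepoint are excluded with a warning.
    """
    if mode not in ("stacked", "delta"):
        raise ValueError(f"unknown signature mode: {mode!r}")
    timepoints = table.timepoints
    if len(timepoints) < 2:
        raise ValueError("need at least two timepoints for a longitudinal signature")

    data = table.data
    keep_patients: list[str] = []
    for p in patients:
        have = set(data.loc[p].index) if p in data.index.get_level_values(0) else set()
        if set(timepoints) <= {int(t) for t in have}:
            keep_patients.append(p)
        else:
            warnings.warn(f"patient {p!r} lacks complete timepoint coverage; excluded")
    if len(keep_patients) < 2:
        raise ValueError("fewer than 2 patients with complete timepoint coverage")

    # patients x timepoints x features cube
    cube = np.empty((len(keep_patients), len(timepoints), len(features)))
    for pi, p in enumerate(keep_patients):
        block = data.loc[p].reindex(timepoints)
        cube[pi] = block[features].to_numpy(dtype=np.float64)

    if mode == "delta":
        cube = cube[:, 1:, :] - cube[:, :1, :]
        used_tps = timepoints[1:]
    else:
        used_tps = timepoints

    finite = np.isfinite(cube).all(axis=(0, 1))
    dropped = [f for f, ok in zip(features, finite) if not ok]
    kept = [f for f, ok in zip(features, finite) if ok]
    if not kept:
        raise ValueError("zero features survive the non-finite exclusion rule")
    cube = cube[:, :, finite]

    columns = [(f, int(t)) for f in kept for t in used_tps]
    flat = np.concatenate([cube[:, :, j] for j in range(cube.shape[2])], axis=1)
    return SignatureMatrix(values=_zscore(flat), patients=keep_patients,
                           columns=columns, mode=mode, dropped_features=dropped)


def ward_two_groups(signature: SignatureMatrix) -> ClusterAssignment:
    """Cut the Ward dendrogram at its two top-level clusters.

    All-identical rows collapse to a single group.  The group containing
    the first patient is labelled "A" so the output is deterministic.
    """
    X = np.asarray(signature.values, dtype=np.float64)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 patients to cluster")
    if np.allclose(X, X[0]):
        return ClusterAssignment(groups={p: "A" for p in signature.patients})
    Z = linkage(X, method="ward")
    labels = fcluster(Z, t=2, criterion="maxclust")
    first = labels[0]
    groups = {p: ("A" if l == first else "B")
              for p, l in zip(signature.patients, labels)}
    return ClusterAssignment(groups=groups)


def clustering_similarity(ref: ClusterAssignment, alt: ClusterAssignment) -> float:
    """Percentage of patients placed in matching groups, maximized over
    the two possible group-label pairings."""
    if ref.patients != alt.patients:
        raise ValueError("cluster assignments cover different patient sets")
    a_ref, b_ref = ref.members("A"), ref.members("B")
    a_alt, b_alt = alt.members("A"), alt.members("B")
    n = len(a_ref | b_ref)
    direct = len(a_ref & a_alt) + len(b_ref & b_alt)
    swapped = len(a_ref & b_alt) + len(b_ref & a_alt)
    return max(direct, swapped) / n * 100.0


def threshold_sweep(table_ref: FeatureTable, table_alt: FeatureTable,
                    records: list[CorrelationRecord], patients: list[str],
                    grid: np.ndarray | None = None, mode: str = "stacked",
                    ) -> SweepResult:
    """Clustering similarity and feature composition over a threshold grid.

    At each threshold, pairs with finite r strictly above it are kept;
    both signatures are assembled on the same surviving pairs (each
    flavor contributing its own values), clustered, and compared.
    Thresholds where no feature survives are recorded with NaN
    similarity.  Pairs with a non-finite value for any cohort row in
    either table are excluded up front, mirroring the complete-case
    modelling rule.
    """
    if grid is None:
        grid = default_threshold_grid()
    grid = np.asarray(grid, dtype=np.float64)
    if grid.size == 0:
        raise ValueError("empty threshold grid")

    fitted = [rec for rec in records if np.isfinite(rec.r)]
    feats_ref = [rec.pair.feature_a for rec in fitted]
    feats_alt = [rec.pair.feature_b for rec in fitted]

    sig_ref = assemble_signature(table_ref, patients, feats_ref, mode=mode)
    sig_alt = assemble_signature(table_alt, patients, feats_alt, mode=mode)
    ok = [rec for rec in fitted
          if rec.pair.feature_a not in set(sig_ref.dropped_features)
          and rec.pair.feature_b not in set(sig_alt.dropped_features)]

    # column lookup per surviving pair
    col_ref = {f: [] for f in feats_ref}
    for j, (f, _) in enumerate(sig_ref.columns):
        col_ref.setdefault(f, []).append(j)
    col_alt = {f: [] for f in feats_alt}
    for j, (f, _) in enumerate(sig_alt.columns):
        col_alt.setdefault(f, []).append(j)

    r_values = np.array([rec.r for rec in ok])
    results: list[SimilarityResult] = []
    for thr in grid:
        keep = r_values > thr
        n_kept = int(keep.sum())
        comp: dict[str, int] = {}
        for rec, k in zip(ok, keep):
            if k:
                key = (f"GLCM({rec.pair.distance})" if rec.pair.klass == "GLCM"
                       else rec.pair.klass)
                comp[key] = comp.get(key, 0) + 1
        if n_kept == 0:
            results.append(SimilarityResult(float(thr), np.nan, 0, comp))
            continue
        idx_ref = np.concatenate([col_ref[rec.pair.feature_a]
                                  for rec, k in zip(ok, keep) if k])
        idx_alt = np.concatenate([col_alt[rec.pair.feature_b]
                                  for rec, k in zip(ok, keep) if k])
        sub_ref = SignatureMatrix(sig_ref.values[:, idx_ref], sig_ref.patients,
                                  [sig_ref.columns[j] for j in idx_ref], mode)
        sub_alt = SignatureMatrix(sig_alt.values[:, idx_alt], sig_alt.patients,
                                  [sig_alt.columns[j] for j in idx_alt], mode)
        sim = clustering_similarity(ward_two_groups(sub_ref),
                                    ward_two_groups(sub_alt))
        results.append(SimilarityResult(float(thr), sim, n_kept, comp))
    return SweepResult(results=results)
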